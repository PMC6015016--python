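"""Exception hierarchy for the glucocest package.

All package-specific errors derive from :class:`GlucoCESTError`, so callers
can catch one base class at pipeline boundaries.  Validation-type errors also
derive from :class:`ValueError` where that is the natural Python idiom.
"""


class GlucoCESTError(Exception):
    """Base class for all glucocest errors."""


class InvalidParameterError(GlucoCESTError, ValueError):
    """A model parameter is outside its admissible domain (e.g. FWHM <= 0)."""


class MissingOffsetError(GlucoCESTError, KeyError):
    """A required saturation offset is absent from the schedule."""


class InvalidSignalError(GlucoCESTError, ValueError):
    """A signal value makes the requested computation meaningless (e.g. S0 <= 0)."""


class InvalidInputError(GlucoCESTError, ValueError):
    """Input data contain NaN/inf or have inconsistent shapes."""


class UnderdeterminedError(GlucoCESTError, ValueError):
    """Fewer usable samples than free parameters for a fit."""


class FitFailureError(GlucoCESTError, RuntimeError):
    """A nonlinear fit did not converge; carries the failing stage name."""

    def __init__(self, message: str, stage: str = ""):
        super().__init__(message)
        self.stage = stage


class OffsetRangeError(GlucoCESTError, ValueError):
    """A requested offset or window falls outside the sampled/evaluated range."""


class UndefinedBaselineError(GlucoCESTError, ValueError):
    """Baseline quantity is zero or negative, so a relative change is undefined."""


class DesignError(GlucoCESTError, ValueError):
    """The experimental design implied by the inputs violates the protocol
    (wrong number of baseline acquisitions, too few frames, empty window, ...)."""


class EmptyROIError(GlucoCESTError, ValueError):
    """A region-of-interest label selects no valid voxels."""


class UnbalancedDesignError(GlucoCESTError, ValueError):
    """The factorial table has missing cells or too few levels for the ANOVA."""


class InvalidPValueError(GlucoCESTError, ValueError):
    """A p value outside (0, 1] was passed to a multiple-comparison routine."""


class ConfigError(GlucoCESTError, ValueError):
    """A run configuration or sidecar file is missing or malformed."""


class GeometryError(GlucoCESTError, ValueError):
    """Image grids of supposedly co-registered volumes disagree."""


class NegativeSignalWarning(UserWarning):
    """The model parameters predict negative signal at some offset."""
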