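"""Continuous single-offset (dynamic) CEST analysis.

Instead of a full Z-spectrum (~8 min each), the dynamic protocol parks the
saturation pulse on the hydroxyl resonance (1.2 ppm) and images every 9 s for
90 frames (13.5 min total), injecting the 2DG bolus during the acquisition
after 15 baseline frames.  The per-frame relative signal drop

    (S_baseline - S(t_n)) / S_baseline

is summed over the post-infusion window (110-700 s by default) to give
AUC_Dyn, a surrogate for glucose delivery.  No B0/B1 correction is applied to
dynamic data — with a single offset there is nothing to correct against.

Frame timestamps are end-of-frame times ``t_n = 9 n`` s, n = 1..90.  Note the
printed window bounds (110-700 s) overlap the tail of the 15-frame baseline
(9-135 s); the window is applied literally and an explicit baseline override
is available for analyses that need the two decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DesignError, InvalidInputError

__all__ = [
    "FRAME_INTERVAL_S",
    "N_FRAMES",
    "N_BASELINE_FRAMES",
    "DYN_WINDOW_S",
    "DynamicSeries",
    "baseline_signal",
    "signal_change",
    "auc_dyn",
]

FRAME_INTERVAL_S = 9.0
N_FRAMES = 90
N_BASELINE_FRAMES = 15
DYN_WINDOW_S = (110.0, 700.0)


@dataclass
class DynamicSeries:
    """A single-offset dynamic acquisition: frame times (s) and signals."""

    frame_times_s: np.ndarray
    signals: np.ndarray

    def __post_init__(self):
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.frame_times_s.shape != self.signals.shape or self.signals.ndim != 1:
            raise InvalidInputError("frame_times_s and signals must be matching 1-D arrays")

    @classmethod
    def from_protocol(cls, signals) -> "DynamicSeries":
        """Wrap protocol-conform signals: t_n = 9 n s, n = 1..len(signals)."""
        signals = np.asarray(signals, dtype=float)
        t = FRAME_INTERVAL_S * np.arange(1, signals.size + 1)
        return cls(t, signals)

    @property
    def n_frames(self) -> int:
        return self.signals.size


def baseline_signal(series: DynamicSeries, n_baseline: int = N_BASELINE_FRAMES) -> float:
    """Arithmetic mean of the first ``n_baseline`` (default 15) frames."""
    if series.n_frames < n_baseline:
        raise DesignError(
            f"need >= {n_baseline} frames for the baseline, got {series.n_frames}"
        )
    return float(np.mean(series.signals[:n_baseline]))


def signal_change(series: DynamicSeries, n: int, s_baseline: float | None = None) -> float:
    """Relative drop of frame ``n`` (0-based) below baseline.

    Positive when the signal falls below baseline (CEST effect), negative on
    a rise.
    """
    if not 0 <= n < series.n_frames:
        raise DesignError(f"frame index {n} out of range 0..{series.n_frames - 1}")
    if s_baseline is None:
        s_baseline = baseline_signal(series)
    if s_baseline <= 0:
        raise InvalidInputError(f"baseline must be > 0, got {s_baseline}")
    return float((s_baseline - series.signals[n]) / s_baseline)


def auc_dyn(
    series: DynamicSeries,
    window_s: tuple[float, float] = DYN_WINDOW_S,
    s_baseline: float | None = None,
) -> float:
    """AUC_Dyn: summed relative signal drop over the post-infusion window.

    Sums ``(S_baseline - S(t_n)) / S_baseline`` over every frame whose
    timestamp falls in ``window_s`` (inclusive on both ends).  The window
    must lie within the acquisition span.
    """
    lo, hi = window_s
    t = series.frame_times_s
    if lo >= hi:
        raise DesignError(f"empty window [{lo}, {hi}]")
    if lo < t.min() - FRAME_INTERVAL_S or hi > t.max():
        raise DesignError(
            f"window [{lo}, {hi}] s outside acquisition span [{t.min()}, {t.max()}] s"
        )
    if s_baseline is None:
        s_baseline = baseline_signal(series)
    if s_baseline <= 0:
        raise InvalidInputError(f"baseline must be > 0, got {s_baseline}")
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise DesignError(f"no frames inside window [{lo}, {hi}] s")
    return float(np.sum((s_baseline - series.signals[mask]) / s_baseline))
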