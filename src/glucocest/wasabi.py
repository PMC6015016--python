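"""WASABI simultaneous B0/B1 field mapping.

WASABI (water shift and B1) applies a short, strong rectangular saturation
pulse and samples the resulting Rabi-oscillation pattern at many offsets close
to water.  The analytic rect-pulse signal model is::

    S(dw) = | c - d * sin^2(atan(g*B1 / df)) * sin^2(pi * tp * sqrt((g*B1)^2 + df^2)) |

with ``df = (dw - dB0) * field * 42.577`` Hz the off-resonance in Hz,
``g*B1 = 42.577 * B1[uT]`` Hz the pulse amplitude, ``tp`` the pulse duration
and ``c``, ``d`` envelope parameters absorbing relaxation.  The oscillation
frequency encodes B1 and the symmetry centre encodes the B0 offset, so a
single scan yields both maps.  The protocol here uses B1 = 3.7 uT, tp = 5 ms
and 43 offsets within +/-1.5 ppm at 7 T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidParameterError, UnderdeterminedError

__all__ = [
    "GAMMA_HZ_PER_UT",
    "WasabiScan",
    "WasabiFit",
    "FieldMaps",
    "wasabi_model",
    "fit_wasabi",
    "fit_wasabi_map",
    "wasabi_offsets",
]

#: proton gyromagnetic ratio, 42.577 MHz/T == Hz per uT
GAMMA_HZ_PER_UT = 42.577


def wasabi_offsets(n: int = 43, span_ppm: float = 1.5) -> np.ndarray:
    """The protocol's WASABI offset axis: ``n`` points within +/-span ppm."""
    return np.linspace(-span_ppm, span_ppm, n)


@dataclass(frozen=True)
class WasabiScan:
    """One WASABI acquisition (normalised signal per offset)."""

    offsets_ppm: np.ndarray
    signals: np.ndarray
    b1_nominal_uT: float = 3.7
    tp_s: float = 0.005
    field_T: float = 7.0

    def __post_init__(self):
        offs = np.asarray(self.offsets_ppm, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        if offs.shape != sig.shape or offs.ndim != 1:
            raise InvalidParameterError("offsets and signals must be matching 1-D arrays")
        if np.any(np.abs(offs) > 1.5 + 1e-9):
            raise InvalidParameterError("WASABI offsets must lie within +/-1.5 ppm")
        if np.any(sig < 0):
            raise InvalidParameterError("WASABI signals must be non-negative")
        object.__setattr__(self, "offsets_ppm", offs)
        object.__setattr__(self, "signals", sig)


def wasabi_model(dw, b1_uT, db0_ppm, c, d, tp_s=0.005, field_T=7.0):
    """Analytic rect-pulse WASABI signal at offset(s) ``dw`` (ppm).

    Limits: ``d == 0`` gives the constant ``c``; on resonance
    (``dw == db0``) the first sin^2 factor is 1; far off resonance the
    signal tends to ``c``.
    """
    if tp_s <= 0:
        raise InvalidParameterError("tp_s must be > 0")
    if field_T <= 0:
        raise InvalidParameterError("field_T must be > 0")
    dw = np.asarray(dw, dtype=float)
    df = (dw - db0_ppm) * field_T * GAMMA_HZ_PER_UT
    gb1 = GAMMA_HZ_PER_UT * b1_uT
    with np.errstate(divide="ignore"):
        angle = np.arctan2(gb1, df) if gb1 else np.zeros_like(df)
    # arctan2 keeps the on-resonance limit (df -> 0 => angle -> pi/2) exact;
    # sin^2 is insensitive to the branch for df < 0.
    env = np.sin(angle) ** 2
    rabi = np.sin(np.pi * tp_s * np.sqrt(gb1 * gb1 + df * df)) ** 2
    return np.abs(c - d * env * rabi)


@dataclass(frozen=True)
class WasabiFit:
    """Per-voxel WASABI fit: B0 offset, relative B1 and envelope params."""

    db0_ppm: float
    rel_b1: float
    c: float
    d: float
    status: str = "ok"  # "ok" | "degenerate" | "failed"
    cost: float = np.nan

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def fit_wasabi(scan: WasabiScan, db0_grid=(-0.5, 0.0, 0.5)) -> WasabiFit:
    """Invert the WASABI model for one voxel/ROI.

    Bounded least squares over (db0, B1, c, d) with multi-start over the
    ``db0_grid`` initialisations; ``rel_b1`` is the fitted B1 divided by the
    nominal pulse amplitude.  A flat signal (no oscillation to lock onto)
    returns a ``degenerate`` status with ``rel_b1`` marked missing (NaN).
    """
    x, y = scan.offsets_ppm, scan.signals
    good = np.isfinite(y)
    if good.sum() < 10:
        raise UnderdeterminedError(f"only {int(good.sum())} valid WASABI samples")
    x, y = x[good], y[good]
    if np.ptp(y) < 1e-6:
        return WasabiFit(np.nan, np.nan, float(np.mean(y)), 0.0, status="degenerate")

    b1n = scan.b1_nominal_uT

    def resid(p):
        return wasabi_model(x, p[1], p[0], p[2], p[3], scan.tp_s, scan.field_T) - y

    lb = np.array([-1.0, 0.2 * b1n, 0.0, 0.0])
    ub = np.array([1.0, 2.0 * b1n, 2.0, 2.0])
    c0 = float(np.percentile(y, 90))
    d0 = float(np.clip(2.0 * np.ptp(y), 0.1, 2.0))
    best = None
    for db0_0 in db0_grid:
        p0 = np.clip(np.array([db0_0, b1n, c0, d0]), lb, ub)
        res = least_squares(resid, p0, bounds=(lb, ub), method="trf",
                            ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=2000)
        if best is None or res.cost < best.cost:
            best = res
    if not best.success and best.status != 0:
        return WasabiFit(np.nan, np.nan, np.nan, np.nan, status="failed", cost=best.cost)
    db0, b1, c, d = best.x
    if d < 1e-4:
        return WasabiFit(np.nan, np.nan, float(c), float(d), status="degenerate",
                         cost=float(best.cost))
    return WasabiFit(float(db0), float(b1 / b1n), float(c), float(d),
                     status="ok", cost=float(best.cost))


@dataclass
class FieldMaps:
    """Voxelwise B0 (ppm) and relative B1 maps plus fit status.

    ``status`` codes: 0 = ok, 1 = degenerate/failed (fell back to
    dB0 = 0, rel_b1 = 1), 2 = outside mask (not fitted).
    """

    b0_ppm: np.ndarray
    rel_b1: np.ndarray
    status: np.ndarray
    c: np.ndarray = None
    d: np.ndarray = None


def fit_wasabi_map(
    stack: np.ndarray,
    mask: np.ndarray | None = None,
    b1_nominal_uT: float = 3.7,
    tp_s: float = 0.005,
    field_T: float = 7.0,
    offsets_ppm: np.ndarray | None = None,
) -> FieldMaps:
    """Fit the WASABI model at every in-mask voxel of a (x, y, offset) stack.

    Voxels whose fit is degenerate or fails fall back to dB0 = 0 and
    rel_b1 = 1 and are flagged in the status map.
    """
    if offsets_ppm is None:
        offsets_ppm = wasabi_offsets(stack.shape[-1])
    nx, ny = stack.shape[:2]
    if mask is None:
        mask = np.ones((nx, ny), dtype=bool)
    b0 = np.zeros((nx, ny))
    rb1 = np.ones((nx, ny))
    status = np.full((nx, ny), 2, dtype=np.int8)
    c = np.full((nx, ny), np.nan)
    d = np.full((nx, ny), np.nan)
    for i, j in zip(*np.nonzero(mask)):
        scan = WasabiScan(offsets_ppm, stack[i, j], b1_nominal_uT, tp_s, field_T)
        fit = fit_wasabi(scan)
        if fit.ok:
            b0[i, j], rb1[i, j] = fit.db0_ppm, fit.rel_b1
            c[i, j], d[i, j] = fit.c, fit.d
            status[i, j] = 0
        else:
            status[i, j] = 1
    return FieldMaps(b0_ppm=b0, rel_b1=rb1, status=status, c=c, d=d)
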