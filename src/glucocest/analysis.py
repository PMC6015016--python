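"""Subject- and cohort-level glucoCEST analysis.

Couples the per-module primitives into the study workflow:

    WASABI -> B0/B1 -> five-pool fit per timepoint -> LD -> AUC_LD -> GCE
    dynamic series -> baseline -> AUC_Dyn

Two scopes are offered.  ROI scope averages the Z-spectra over a region
before fitting — one fit per region and timepoint, cheap and low-noise, and
what the cohort statistics consume.  Voxel scope fits every in-mask voxel
and produces parameter/GCE maps for voxelwise inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamic import DYN_WINDOW_S, DynamicSeries, auc_dyn
from .errors import EmptyROIError, UndefinedBaselineError
from .gce import GCE_WINDOW_PPM, auc_ld, gce_timecourse
from .phantom import LABELS
from .stats import ROI_NAMES
from .wasabi import WasabiFit, WasabiScan, fit_wasabi
from .zspec import FitResult, OffsetSchedule, ZSpectrum, fit_multipool, lorentzian_difference

__all__ = [
    "SubjectData",
    "roi_mask",
    "roi_wasabi",
    "subject_roi_fits",
    "subject_gce_rois",
    "auc_dyn_map",
    "subject_auc_dyn_rois",
    "cohort_gce_table",
    "cohort_auc_dyn_table",
    "voxel_fit_maps",
    "gce_maps",
]


@dataclass
class SubjectData:
    """One subject's acquisitions, in memory (simulated or loaded from disk)."""

    subject_id: str
    genotype: str
    labels: np.ndarray
    schedule: OffsetSchedule
    zstack_times_min: tuple[float, ...]
    zstacks: list[np.ndarray]
    wasabi_offsets_ppm: np.ndarray
    wasabi_stack: np.ndarray
    frame_times_s: np.ndarray
    dynamic_stack: np.ndarray
    wasabi_b1_nominal_uT: float = 3.7
    wasabi_tp_s: float = 0.005
    field_T: float = 7.0

    @classmethod
    def from_sim(cls, sim) -> "SubjectData":
        cfg = sim.truth.config
        return cls(
            subject_id=sim.subject_id, genotype=sim.genotype,
            labels=sim.truth.labels, schedule=sim.schedule,
            zstack_times_min=tuple(sim.zstack_times_min), zstacks=sim.zstacks,
            wasabi_offsets_ppm=sim.wasabi_offsets_ppm,
            wasabi_stack=sim.wasabi_stack, frame_times_s=sim.frame_times_s,
            dynamic_stack=sim.dynamic_stack,
            wasabi_b1_nominal_uT=cfg.wasabi_b1_uT, wasabi_tp_s=cfg.wasabi_tp_s,
            field_T=cfg.field_T,
        )

    def roi_zspectrum(self, roi: str, t_min: float) -> ZSpectrum:
        k = self.zstack_times_min.index(t_min)
        mask = roi_mask(self.labels, roi)
        z = self.zstacks[k][mask].mean(axis=0)
        return ZSpectrum(self.schedule, z, voxel_or_roi_id=roi, timepoint_s=t_min * 60.0)


def roi_mask(labels: np.ndarray, roi: str) -> np.ndarray:
    if roi == "whole_brain":
        mask = labels > 0
    else:
        mask = labels == LABELS[roi]
    if not mask.any():
        raise EmptyROIError(f"ROI {roi!r} is empty")
    return mask


def roi_wasabi(subject: SubjectData, roi: str) -> WasabiFit:
    """WASABI fit of the ROI-mean signal; degenerate fits fall back to
    (dB0 = 0, rel_b1 = 1)."""
    mask = roi_mask(subject.labels, roi)
    sig = subject.wasabi_stack[mask].mean(axis=0)
    fit = fit_wasabi(
        WasabiScan(subject.wasabi_offsets_ppm, np.abs(sig),
                   subject.wasabi_b1_nominal_uT, subject.wasabi_tp_s,
                   subject.field_T)
    )
    if not fit.ok:
        return WasabiFit(0.0, 1.0, fit.c, fit.d, status=fit.status)
    return fit


def subject_roi_fits(
    subject: SubjectData,
    rois: Sequence[str] = ROI_NAMES,
    **fit_kwargs,
) -> dict[str, tuple[WasabiFit, list[FitResult]]]:
    """WASABI fit plus one five-pool fit per timepoint, for each ROI."""
    out = {}
    for roi in rois:
        wf = roi_wasabi(subject, roi)
        fits = [
            fit_multipool(subject.roi_zspectrum(roi, t), b0_init=wf.db0_ppm,
                          rel_b1=wf.rel_b1, **fit_kwargs)
            for t in subject.zstack_times_min
        ]
        out[roi] = (wf, fits)
    return out


def subject_gce_rois(
    subject: SubjectData,
    rois: Sequence[str] = ROI_NAMES,
    *,
    window_ppm: tuple[float, float] = GCE_WINDOW_PPM,
    b1_correction_mode: str = "multiply",
    grid_step: float = 0.01,
    roi_fits: dict | None = None,
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """GCE time course per ROI of one subject.

    Returns a tidy table (subject_id, genotype, roi, timepoint_min, gce) with
    one row per post-injection timepoint, and a QC dict recording the WASABI
    status and fit residuals per ROI.  Pass precomputed ``roi_fits`` (from
    :func:`subject_roi_fits`) to avoid refitting.
    """
    rows = []
    qc = {}
    times = subject.zstack_times_min
    if roi_fits is None:
        roi_fits = subject_roi_fits(subject, rois, **fit_kwargs)
    for roi in rois:
        wf, fits = roi_fits[roi]
        series = gce_timecourse(
            fits, [t * 60.0 for t in times], window_ppm=window_ppm,
            grid_step=grid_step, b1_correction_mode=b1_correction_mode,
        )
        qc[roi] = {
            "wasabi_status": wf.status,
            "db0_ppm": wf.db0_ppm,
            "rel_b1": wf.rel_b1,
            "max_residual_rms": float(max(f.residual_rms for f in fits)),
            "auc_baseline": series.auc_baseline,
        }
        for t_s, g in zip(series.timepoints_s, series.gce):
            rows.append({
                "subject_id": subject.subject_id, "genotype": subject.genotype,
                "roi": roi, "timepoint_min": t_s / 60.0, "gce": float(g),
            })
    return pd.DataFrame(rows), qc


def subject_auc_dyn_rois(
    subject: SubjectData,
    rois: Sequence[str] = ROI_NAMES,
    window_s: tuple[float, float] = DYN_WINDOW_S,
) -> pd.DataFrame:
    """AUC_Dyn of the ROI-mean dynamic signal, per ROI."""
    rows = []
    for roi in rois:
        mask = roi_mask(subject.labels, roi)
        sig = subject.dynamic_stack[mask].mean(axis=0)
        series = DynamicSeries(subject.frame_times_s, sig)
        rows.append({
            "subject_id": subject.subject_id, "genotype": subject.genotype,
            "roi": roi, "auc_dyn": auc_dyn(series, window_s),
        })
    return pd.DataFrame(rows)


def cohort_gce_table(subjects: Iterable[SubjectData],
                     rois: Sequence[str] = ROI_NAMES, **kwargs) -> pd.DataFrame:
    """Concatenated ROI GCE table over a cohort (the RoiTable of the stats)."""
    tables = [subject_gce_rois(s, rois, **kwargs)[0] for s in subjects]
    return pd.concat(tables, ignore_index=True)


def cohort_auc_dyn_table(subjects: Iterable[SubjectData],
                         rois: Sequence[str] = ROI_NAMES,
                         window_s: tuple[float, float] = DYN_WINDOW_S) -> pd.DataFrame:
    return pd.concat(
        [subject_auc_dyn_rois(s, rois, window_s) for s in subjects],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# voxelwise maps
# ---------------------------------------------------------------------------

FIT_MAP_NAMES = tuple(
    f"{pool}_{param}"
    for pool in ("water", "noe", "amine", "amide", "hydroxyl")
    for param in ("amplitude", "fwhm", "center")
) + ("mt", "residual_rms", "recentering_shift", "auc_ld")


def voxel_fit_maps(
    stack: np.ndarray,
    schedule: OffsetSchedule,
    mask: np.ndarray,
    b0_map: np.ndarray | None = None,
    rel_b1_map: np.ndarray | None = None,
    *,
    window_ppm: tuple[float, float] = GCE_WINDOW_PPM,
    b1_correction_mode: str = "multiply",
    grid_step: float = 0.01,
    **fit_kwargs,
) -> dict[str, np.ndarray]:
    """Five-pool fit of every in-mask voxel of one Z-spectrum stack.

    Returns float maps for every pool parameter, MT, the residual RMS, the
    re-centring shift and the hydroxyl-window AUC_LD (NaN outside the mask).
    """
    shape = stack.shape[:2]
    out = {name: np.full(shape, np.nan) for name in FIT_MAP_NAMES}
    if b0_map is None:
        b0_map = np.zeros(shape)
    if rel_b1_map is None:
        rel_b1_map = np.ones(shape)
    for i, j in zip(*np.nonzero(mask)):
        zs = ZSpectrum(schedule, stack[i, j], voxel_or_roi_id=(i, j))
        fit = fit_multipool(zs, b0_init=float(b0_map[i, j]),
                            rel_b1=float(rel_b1_map[i, j]), **fit_kwargs)
        for pool, p in fit.pools.as_dict().items():
            out[f"{pool}_amplitude"][i, j] = p.amplitude
            out[f"{pool}_fwhm"][i, j] = p.fwhm
            out[f"{pool}_center"][i, j] = p.center
        out["mt"][i, j] = fit.mt
        out["residual_rms"][i, j] = fit.residual_rms
        out["recentering_shift"][i, j] = fit.recentering_shift_ppm
        ld = lorentzian_difference(fit, grid_step,
                                   b1_correction_mode=b1_correction_mode)
        out["auc_ld"][i, j] = auc_ld(ld, *window_ppm)
    return out


def auc_dyn_map(dynamic_stack: np.ndarray, frame_times_s: np.ndarray,
                mask: np.ndarray,
                window_s: tuple[float, float] = DYN_WINDOW_S,
                n_baseline: int = 15) -> np.ndarray:
    """Voxelwise AUC_Dyn map (vectorised; NaN outside the mask)."""
    t = np.asarray(frame_times_s, dtype=float)
    base = dynamic_stack[..., :n_baseline].mean(axis=-1)
    sel = (t >= window_s[0]) & (t <= window_s[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        drops = (base[..., None] - dynamic_stack[..., sel]) / base[..., None]
    out = drops.sum(axis=-1)
    out = np.where(mask, out, np.nan)
    return out


def gce_maps(auc_maps: Sequence[np.ndarray], times_min: Sequence[float]
             ) -> tuple[dict[float, np.ndarray], np.ndarray]:
    """Voxelwise GCE maps from per-timepoint AUC_LD maps.

    The baseline is the voxelwise mean of the maps at negative times (must be
    exactly 3).  Voxels with non-positive baseline are masked (NaN) and
    returned in the exclusion mask.
    """
    times = np.asarray(times_min, dtype=float)
    base = times < 0
    if base.sum() != 3:
        raise UndefinedBaselineError(
            f"expected exactly 3 baseline maps, got {int(base.sum())}"
        )
    stack = np.stack(auc_maps)
    auc_base = stack[base].mean(axis=0)
    bad = ~(auc_base > 0)
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for t, amap in zip(times[~base], stack[~base]):
            g = (amap - auc_base) / auc_base
            g[bad] = np.nan
            out[float(t)] = g
    return out, bad
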