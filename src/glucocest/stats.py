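"""ROI summaries and group statistics for GCE cohorts.

Three layers mirror the study's analysis: per-ROI mean/SEM summaries, a
two-way fixed-effects ANOVA (genotype x time, with interaction) per ROI with
a Hochberg step-up correction across ROIs, and a voxelwise two-sample
permutation t-test (a native replacement for FSL ``randomise``), one-sided
WT > TG by default.

Subjects are treated as independent observations within each genotype x time
cell; repeated measures across time are NOT modelled (the source analysis did
the same).  A mixed model would be the statistically cautious alternative —
interpret the time and interaction p values accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .errors import (
    DesignError,
    EmptyROIError,
    InvalidInputError,
    InvalidPValueError,
    UnbalancedDesignError,
)

__all__ = [
    "ROI_NAMES",
    "AnovaResult",
    "PermTTestResult",
    "roi_stats",
    "anova_genotype_time",
    "anova_all_rois",
    "hochberg",
    "perm_ttest",
]

ROI_NAMES = ("whole_brain", "cortex", "hippocampus", "thalamus", "ventricles")
ROI_TABLE_COLUMNS = ("subject_id", "genotype", "roi", "timepoint_min", "gce")


def roi_stats(image: np.ndarray, labels: np.ndarray, label) -> tuple[float, float, int]:
    """Mean, SEM and voxel count of ``image`` over ``labels == label``.

    Non-finite voxels are excluded; an empty selection raises
    :class:`EmptyROIError`.  SEM uses the n-1 sample standard deviation and
    is 0 for a single voxel.
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise InvalidInputError("image and label volumes must share a grid")
    sel = (labels == label) & np.isfinite(image)
    vals = image[sel]
    if vals.size == 0:
        raise EmptyROIError(f"label {label!r} selects no valid voxels")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return mean, sem, int(vals.size)


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA of one ROI: F and p per effect, optional adjusted p."""

    roi: str
    f: dict            # effect -> F statistic
    p: dict            # effect -> raw p value
    p_adjusted: dict = field(default_factory=dict)   # effect -> Hochberg-adjusted p

    EFFECTS = ("genotype", "time", "genotype_x_time")


def _validate_roi_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ROI_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"ROI table missing columns {missing}")
    return table


def anova_genotype_time(table: pd.DataFrame, roi: str) -> AnovaResult:
    """Fixed-effects two-way ANOVA (genotype x time, with interaction) on GCE.

    Requires >= 2 subjects per genotype, >= 2 timepoints, and every
    genotype x time cell populated (no imputation is attempted).
    """
    _validate_roi_table(table)
    sub = table[table["roi"] == roi]
    if sub.empty:
        raise EmptyROIError(f"no rows for ROI {roi!r}")
    genos = sub["genotype"].unique()
    times = sub["timepoint_min"].unique()
    if len(genos) < 2:
        raise UnbalancedDesignError("need two genotypes")
    if len(times) < 2:
        raise UnbalancedDesignError("need >= 2 timepoints for a genotype x time ANOVA")
    counts = sub.groupby(["genotype", "timepoint_min"], observed=True).size()
    if len(counts) < len(genos) * len(times):
        raise UnbalancedDesignError("missing genotype x time cells")
    for g in genos:
        if sub[sub["genotype"] == g]["subject_id"].nunique() < 2:
            raise UnbalancedDesignError(f"genotype {g} has < 2 subjects")

    model = smf.ols(
        "gce ~ C(genotype) * C(timepoint_min)", data=sub
    ).fit()
    tab = anova_lm(model, typ=2)
    key = {
        "genotype": "C(genotype)",
        "time": "C(timepoint_min)",
        "genotype_x_time": "C(genotype):C(timepoint_min)",
    }
    f = {e: float(tab.loc[k, "F"]) for e, k in key.items()}
    p = {e: float(tab.loc[k, "PR(>F)"]) for e, k in key.items()}
    return AnovaResult(roi=roi, f=f, p=p)


def hochberg(pvals) -> np.ndarray:
    """Hochberg step-up adjusted p values (order-preserving, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidPValueError("pvals must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InvalidPValueError("all p values must lie in (0, 1]")
    return multipletests(p, method="simes-hochberg")[1]


def anova_all_rois(table: pd.DataFrame, rois=None) -> list[AnovaResult]:
    """Run the two-way ANOVA per ROI and Hochberg-adjust across ROIs.

    The multiplicity family is, for each effect, the set of ROIs tested.
    """
    _validate_roi_table(table)
    if rois is None:
        rois = [r for r in ROI_NAMES if r in set(table["roi"])]
    results = [anova_genotype_time(table, roi) for roi in rois]
    adjusted = {}
    for eff in AnovaResult.EFFECTS:
        adj = hochberg([r.p[eff] for r in results])
        for r, a in zip(results, adj):
            adjusted.setdefault(r.roi, {})[eff] = float(a)
    return [
        AnovaResult(roi=r.roi, f=r.f, p=r.p, p_adjusted=adjusted[r.roi])
        for r in results
    ]


@dataclass(frozen=True)
class PermTTestResult:
    """Voxelwise permutation t-test output."""

    t: np.ndarray             # observed two-sample t per voxel
    p: np.ndarray             # permutation p per voxel (NaN outside mask)
    n_perm: int               # number of relabelings used (incl. observed)
    exhaustive: bool
    degenerate: np.ndarray    # voxels with zero pooled variance (masked)
    p_fwe: np.ndarray | None = None   # max-t familywise-corrected p

    def significance_mask(self, alpha: float = 0.05, fwe: bool = False) -> np.ndarray:
        p = self.p_fwe if fwe else self.p
        return np.where(np.isfinite(p), p < alpha, False)


def _tstat(a_sum, a_sq, b_sum, b_sq, na, nb):
    """Pooled-variance two-sample t from per-group sums and sums of squares."""
    ma, mb = a_sum / na, b_sum / nb
    ssa = a_sq - na * ma * ma
    ssb = b_sq - nb * mb * mb
    sp2 = (ssa + ssb) / (na + nb - 2)
    sp2 = np.maximum(sp2, 0.0)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return t


def perm_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "greater",
    mask: np.ndarray | None = None,
    max_t_correction: bool = False,
) -> PermTTestResult:
    """Voxelwise two-sample t-test with group-label permutation p values.

    Parameters
    ----------
    group_a, group_b
        Stacks of co-registered maps, shape (n_subjects, *image_shape).
    n_perm
        Permutation budget.  When the total number of distinct relabelings
        C(nA+nB, nA) does not exceed it, the distribution is enumerated
        exhaustively (the observed labeling is then one of the relabelings
        and p >= 1/total by construction); otherwise ``n_perm`` seeded random
        relabelings are drawn and the observed labeling is added.
    alternative
        "greater" (A > B, the default, matching the WT > TG contrast),
        "less", or "two-sided".
    max_t_correction
        Also return familywise-corrected p values from the permutation
        distribution of the image-wise maximum t.

    Voxels with zero pooled variance and equal means are degenerate: they get
    t = 0, p = 1 and are flagged in ``degenerate``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[1:] != b.shape[1:]:
        raise InvalidInputError("group maps must share an image grid")
    na, nb = a.shape[0], b.shape[0]
    if na < 3 or nb < 3:
        raise DesignError(f"need >= 3 maps per group, got {na} and {nb}")
    if alternative not in ("greater", "less", "two-sided"):
        raise InvalidInputError(f"unknown alternative {alternative!r}")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} < 100 gives very coarse p values",
                      stacklevel=2)

    shape = a.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    av = a.reshape(na, -1)[:, mask.ravel()]
    bv = b.reshape(nb, -1)[:, mask.ravel()]
    data = np.vstack([av, bv])          # (n, V)
    n = na + nb

    def score(t):
        if alternative == "greater":
            return t
        if alternative == "less":
            return -t
        return np.abs(t)

    tot_sum = data.sum(axis=0)
    tot_sq = (data * data).sum(axis=0)

    def t_for(idx_a):
        a_sum = data[idx_a].sum(axis=0)
        a_sq = (data[idx_a] ** 2).sum(axis=0)
        return _tstat(a_sum, a_sq, tot_sum - a_sum, tot_sq - a_sq, na, nb)

    obs_idx = np.arange(na)
    t_obs = t_for(obs_idx)
    degenerate = ~np.isfinite(t_obs)
    t_obs = np.where(degenerate, 0.0, t_obs)
    s_obs = score(t_obs)

    total = comb(n, na)
    exhaustive = total <= n_perm
    count = np.zeros(t_obs.shape)
    max_count = np.zeros(t_obs.shape)
    if exhaustive:
        n_used = total
        for idx in combinations(range(n), na):
            t = t_for(np.array(idx))
            t = np.where(np.isfinite(t), t, 0.0)
            s = score(t)
            count += s >= s_obs - 1e-12
            if max_t_correction:
                max_count += np.nanmax(s) >= s_obs - 1e-12
        p = count / total
        p_fwe = max_count / total if max_t_correction else None
    else:
        rng = np.random.default_rng(seed)
        n_used = n_perm + 1
        for _ in range(n_perm):
            idx = rng.permutation(n)[:na]
            t = t_for(idx)
            t = np.where(np.isfinite(t), t, 0.0)
            s = score(t)
            count += s >= s_obs - 1e-12
            if max_t_correction:
                max_count += np.nanmax(s) >= s_obs - 1e-12
        p = (count + 1.0) / (n_perm + 1.0)
        p_fwe = (max_count + 1.0) / (n_perm + 1.0) if max_t_correction else None

    p = np.where(degenerate, 1.0, p)
    t_img = np.full(shape, np.nan)
    p_img = np.full(shape, np.nan)
    deg_img = np.zeros(shape, dtype=bool)
    t_img[mask] = t_obs
    p_img[mask] = p
    deg_img[mask] = degenerate
    fwe_img = None
    if p_fwe is not None:
        fwe_img = np.full(shape, np.nan)
        fwe_img[mask] = np.where(degenerate, 1.0, p_fwe)
    return PermTTestResult(
        t=t_img, p=p_img, n_perm=n_used, exhaustive=exhaustive,
        degenerate=deg_img, p_fwe=fwe_img,
    )
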