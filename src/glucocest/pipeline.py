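"""Subject- and cohort-level pipeline orchestration.

``run_subject`` turns a subject directory of raw stacks into derived outputs
(field maps, fit maps or ROI tables, GCE, AUC_Dyn, QC report);
``run_group`` collects the per-subject ROI tables into the cohort statistics
(two-way ANOVA with Hochberg correction, voxelwise permutation t maps).
Everything is deterministic given (inputs, config, seeds), and each run
writes its resolved configuration next to its outputs.

Times are handled in seconds internally; minutes appear only in tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, io
from .dynamic import DYN_WINDOW_S
from .errors import ConfigError, DesignError
from .gce import GCE_WINDOW_PPM
from .phantom import PhantomConfig, UptakeModel, simulate_cohort
from .stats import ROI_NAMES, anova_all_rois, perm_ttest
from .wasabi import fit_wasabi_map

__all__ = ["RunConfig", "run_subject", "run_group", "simulate_to_dir"]

_STAGES = ("fieldmap", "fit", "gce", "dynamic")


@dataclass
class RunConfig:
    """Validated options of a pipeline run."""

    fit_scope: str = "roi"                       # "roi" | "voxel"
    rois: tuple[str, ...] = ROI_NAMES
    b1_correction_mode: str = "multiply"
    window_ppm: tuple[float, float] = GCE_WINDOW_PPM
    dyn_window_s: tuple[float, float] = DYN_WINDOW_S
    n_perm: int = 1000
    seed: int = 0
    alternative: str = "greater"
    alpha: float = 0.05
    phantom: dict = field(default_factory=dict)   # PhantomConfig overrides
    n_wt: int = 7
    n_tg: int = 7

    def __post_init__(self):
        if self.fit_scope not in ("roi", "voxel"):
            raise ConfigError(f"fit_scope must be roi|voxel, got {self.fit_scope!r}")
        if self.b1_correction_mode not in (
            "multiply", "divide", "none"
        ):
            raise ConfigError(f"unknown b1_correction_mode {self.b1_correction_mode!r}")
        if self.alternative not in ("greater", "less", "two-sided"):
            raise ConfigError(f"unknown alternative {self.alternative!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        self.rois = tuple(self.rois)
        self.window_ppm = tuple(self.window_ppm)
        self.dyn_window_s = tuple(self.dyn_window_s)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(d)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def phantom_config(self) -> PhantomConfig:
        """PhantomConfig with this run's overrides applied.

        Override keys mirror :class:`PhantomConfig` fields; additionally
        ``tg_scaling`` sets the transgenic genotype factor and ``delta_a_max``
        replaces the per-region uptake increments.
        """
        d = dict(self.phantom)
        uptake_kw = {}
        if "tg_scaling" in d:
            uptake_kw["genotype_scaling"] = {"WT": 1.0, "TG": float(d.pop("tg_scaling"))}
        for key in ("a_oh_baseline", "delta_a_max", "tau_min", "vent_delta"):
            if key in d:
                uptake_kw[key] = d.pop(key)
        known = {f.name for f in dataclasses.fields(PhantomConfig)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown phantom keys {sorted(unknown)}")
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if uptake_kw:
            d["uptake_model"] = UptakeModel(**uptake_kw)
        return PhantomConfig(**d)


def _write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=float)


def simulate_to_dir(config: RunConfig, out_dir, seed: int | None = None) -> Path:
    """Simulate the configured cohort and write it in the directory dialect."""
    seed = config.seed if seed is None else seed
    cohort = simulate_cohort(config.n_wt, config.n_tg,
                             config.phantom_config(), seed=seed)
    out = io.write_cohort(cohort, out_dir)
    _write_json(out / "run_config.json", config.resolved())
    return out


def run_subject(subject_dir, out_dir, config: RunConfig | None = None,
                stages=_STAGES) -> dict:
    """Analyse one subject directory; returns a dict of written paths.

    ROI scope writes ``roi_gce.csv``, ``roi_fit_params.csv``,
    ``roi_auc_dyn.csv`` and ``qc.json``.  Voxel scope additionally fits
    every in-brain voxel and writes field maps, per-parameter fit maps, GCE
    maps and the AUC_Dyn map.
    """
    config = config or RunConfig()
    sub = io.read_subject(subject_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    brain = sub.labels > 0
    written = {}

    fieldmaps = None
    if config.fit_scope == "voxel" and "fieldmap" in stages:
        fieldmaps = fit_wasabi_map(
            sub.wasabi_stack, mask=brain,
            b1_nominal_uT=sub.wasabi_b1_nominal_uT,
            tp_s=sub.wasabi_tp_s, field_T=sub.field_T,
            offsets_ppm=sub.wasabi_offsets_ppm,
        )
        for name, arr in (("b0_ppm", fieldmaps.b0_ppm),
                          ("rel_b1", fieldmaps.rel_b1),
                          ("wasabi_status", fieldmaps.status.astype(float))):
            written[name] = io.save_map(out / f"{name}.nii.gz", arr)

    qc = {"subject_id": sub.subject_id, "fit_scope": config.fit_scope}

    if {"fit", "gce"} & set(stages):
        if config.fit_scope == "roi":
            roi_fits = analysis.subject_roi_fits(sub, config.rois)
            rows = []
            for roi, (wf, fits) in roi_fits.items():
                for t_min, f in zip(sub.zstack_times_min, fits):
                    row = {"subject_id": sub.subject_id, "genotype": sub.genotype,
                           "roi": roi, "timepoint_min": t_min,
                           "mt": f.mt, "residual_rms": f.residual_rms,
                           "recentering_shift_ppm": f.recentering_shift_ppm,
                           "rel_b1": f.relative_b1}
                    for pool, p in f.pools.as_dict().items():
                        row[f"{pool}_amplitude"] = p.amplitude
                        row[f"{pool}_fwhm"] = p.fwhm
                        row[f"{pool}_center"] = p.center
                    rows.append(row)
            fit_df = pd.DataFrame(rows)
            fit_df.to_csv(out / "roi_fit_params.csv", index=False)
            written["roi_fit_params"] = out / "roi_fit_params.csv"
            if "gce" in stages:
                table, roi_qc = analysis.subject_gce_rois(
                    sub, config.rois, window_ppm=config.window_ppm,
                    b1_correction_mode=config.b1_correction_mode,
                    roi_fits=roi_fits,
                )
                table.to_csv(out / "roi_gce.csv", index=False)
                written["roi_gce"] = out / "roi_gce.csv"
                qc["rois"] = roi_qc
        else:
            b0_map = fieldmaps.b0_ppm if fieldmaps is not None else None
            rb1_map = fieldmaps.rel_b1 if fieldmaps is not None else None
            auc_maps = []
            for k, (t_min, stack) in enumerate(zip(sub.zstack_times_min, sub.zstacks)):
                maps = analysis.voxel_fit_maps(
                    stack, sub.schedule, brain, b0_map, rb1_map,
                    window_ppm=config.window_ppm,
                    b1_correction_mode=config.b1_correction_mode,
                )
                auc_maps.append(maps["auc_ld"])
                for name, arr in maps.items():
                    written[f"{name}_t{k:02d}"] = io.save_map(
                        out / f"{name}_t{k:02d}.nii.gz", arr)
            if "gce" in stages:
                gmaps, excluded = analysis.gce_maps(auc_maps, sub.zstack_times_min)
                for t_min, arr in gmaps.items():
                    written[f"gce_t{t_min:g}"] = io.save_map(
                        out / f"gce_t{t_min:g}min.nii.gz", arr)
                qc["n_excluded_baseline_voxels"] = int(excluded[brain].sum())

    if "dynamic" in stages:
        dyn_map = analysis.auc_dyn_map(sub.dynamic_stack, sub.frame_times_s,
                                       brain, config.dyn_window_s)
        written["auc_dyn_map"] = io.save_map(out / "auc_dyn.nii.gz", dyn_map)
        dyn_df = analysis.subject_auc_dyn_rois(sub, config.rois, config.dyn_window_s)
        dyn_df.to_csv(out / "roi_auc_dyn.csv", index=False)
        written["roi_auc_dyn"] = out / "roi_auc_dyn.csv"

    _write_json(out / "qc.json", qc)
    _write_json(out / "run_config.json", config.resolved())
    written["qc"] = out / "qc.json"
    return written


def run_group(cohort_dir, out_dir, config: RunConfig | None = None) -> dict:
    """Cohort statistics: ROI ANOVA with Hochberg correction plus voxelwise
    permutation t maps on the AUC_Dyn maps (and on GCE maps in voxel scope).

    Requires at least two subjects per genotype with consistent grids.
    """
    config = config or RunConfig()
    subjects = io.read_cohort(cohort_dir)
    genos = {"WT": [], "TG": []}
    for s in subjects:
        genos.setdefault(s.genotype, []).append(s)
    if len(genos["WT"]) < 2 or len(genos["TG"]) < 2:
        raise DesignError("need >= 2 subjects per genotype for group statistics")
    shapes = {s.labels.shape for s in subjects}
    if len(shapes) > 1:
        from .errors import GeometryError
        raise GeometryError(f"subject grids differ: {sorted(shapes)}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    table = analysis.cohort_gce_table(
        subjects, config.rois, window_ppm=config.window_ppm,
        b1_correction_mode=config.b1_correction_mode,
    )
    table.to_csv(out / "roi_gce.csv", index=False)
    written["roi_gce"] = out / "roi_gce.csv"

    results = anova_all_rois(table, list(config.rois))
    anova_df = pd.DataFrame([
        {"roi": r.roi, "effect": eff, "F": r.f[eff], "p": r.p[eff],
         "p_hochberg": r.p_adjusted[eff]}
        for r in results for eff in r.f
    ])
    anova_df.to_csv(out / "anova.csv", index=False)
    written["anova"] = out / "anova.csv"

    # voxelwise permutation t-test on the AUC_Dyn maps (cheap, no fitting);
    # the permutation machinery needs >= 3 maps per group
    seeds_info = {"perm_seed": config.seed}
    if len(genos["WT"]) >= 3 and len(genos["TG"]) >= 3:
        brain = subjects[0].labels > 0
        stacks = {
            g: np.stack([
                analysis.auc_dyn_map(s.dynamic_stack, s.frame_times_s, brain,
                                     config.dyn_window_s)
                for s in genos[g]
            ])
            for g in ("WT", "TG")
        }
        res = perm_ttest(stacks["WT"], stacks["TG"], n_perm=config.n_perm,
                         seed=config.seed, alternative=config.alternative,
                         mask=brain)
        written["auc_dyn_t"] = io.save_map(out / "auc_dyn_tmap.nii.gz", res.t)
        written["auc_dyn_p"] = io.save_map(out / "auc_dyn_pmap.nii.gz", res.p)
        written["auc_dyn_sig"] = io.save_map(
            out / "auc_dyn_sig.nii.gz",
            res.significance_mask(config.alpha).astype(float))
        seeds_info.update({"n_perm": res.n_perm, "exhaustive": res.exhaustive})
    else:
        seeds_info["perm_test"] = "skipped: < 3 subjects in a genotype"

    _write_json(out / "run_config.json", config.resolved())
    _write_json(out / "group_seeds.json", seeds_info)
    return written
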