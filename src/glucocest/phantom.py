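"""Digital brain-slice phantom and simulated glucoCEST acquisitions.

The phantom is a labelled 2-D slice (default 45 x 45 voxels, 16 mm field of
view — the acquisition geometry of the study protocol) with four named
regions: cortex, hippocampus, thalamus and ventricles.  Each region carries
the five-pool Z-spectrum parameters; the hydroxyl amplitude follows a
2DG-uptake model after a simulated bolus:

* tissue regions: saturating exponential rise
  ``A_OH(t) = A0 + g * dA_max * (1 - exp(-t / tau))`` — 2DG6P is trapped
  intracellularly, so the signal accumulates and persists;
* ventricles: a fast transient that washes out
  (``(1 - exp(-t/tau_rise)) * exp(-t/tau_washout)``) — CSF sees the blood
  bolus but accumulates nothing.  The transient is genotype-independent.

The genotype scaling ``g`` (transgenic relative to wild type, default 0.6)
makes the uptake deficit of the disease model.  Smooth low-order B0 and
relative-B1 fields emulate scanner inhomogeneity; the forward simulation
shifts every pool centre by the local B0 and scales the exchange-mediated
pool amplitudes by the local relative B1, which is also what the WASABI and
LD corrections of the analysis side assume.

Everything is reproducible from ``(config, seed)``; noiseless simulations
equal the forward model bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .wasabi import wasabi_model, wasabi_offsets
from .zspec import OffsetSchedule, Pool, PoolParams, ZSpectrum

__all__ = [
    "LABELS",
    "TISSUE_REGIONS",
    "UptakeModel",
    "PhantomConfig",
    "PhantomTruth",
    "SubjectSim",
    "Cohort",
    "default_pools",
    "build_phantom",
    "uptake",
    "simulate_subject",
    "simulate_cohort",
]

LABELS = {"background": 0, "cortex": 1, "hippocampus": 2, "thalamus": 3, "ventricles": 4}
TISSUE_REGIONS = ("cortex", "hippocampus", "thalamus")
REGIONS = ("cortex", "hippocampus", "thalamus", "ventricles")


def default_pools() -> PoolParams:
    """Baseline five-pool truth: literature-plausible amplitudes at 7 T."""
    return PoolParams(
        water=Pool(0.85, 1.4, 0.0),
        noe=Pool(0.10, 3.5, -3.5),
        amine=Pool(0.03, 1.5, 2.0),
        amide=Pool(0.05, 1.5, 3.5),
        hydroxyl=Pool(0.02, 1.0, 1.2),
    )


@dataclass(frozen=True)
class UptakeModel:
    """Time course of the hydroxyl amplitude after the 2DG bolus."""

    a_oh_baseline: float = 0.02
    delta_a_max: Mapping[str, float] = field(
        default_factory=lambda: {"cortex": 0.015, "hippocampus": 0.012, "thalamus": 0.010}
    )
    tau_min: float = 15.0
    genotype_scaling: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "TG": 0.6}
    )
    vent_delta: float = 0.010
    vent_rise_min: float = 0.5
    vent_washout_min: float = 3.0

    def __post_init__(self):
        if any(v < 0 for v in self.delta_a_max.values()) or self.vent_delta < 0:
            raise ConfigError("uptake increments must be >= 0")
        if any(not 0 <= g <= 1 for g in self.genotype_scaling.values()):
            raise ConfigError("genotype scaling must lie in [0, 1]")

    def scaled(self, factor: float) -> "UptakeModel":
        """Between-subject variant: all uptake increments scaled by ``factor``."""
        return replace(
            self,
            delta_a_max={k: v * factor for k, v in self.delta_a_max.items()},
            vent_delta=self.vent_delta * factor,
        )


def uptake(t_min: float, region: str, genotype: str, model: UptakeModel) -> float:
    """Hydroxyl amplitude A_OH at ``t_min`` minutes post-injection.

    Baseline before the bolus; saturating rise (scaled by the genotype
    factor) in tissue; genotype-independent transient with washout in the
    ventricles.
    """
    if t_min < 0:
        return model.a_oh_baseline
    if region == "ventricles":
        pulse = (1.0 - np.exp(-t_min / model.vent_rise_min)) * np.exp(
            -t_min / model.vent_washout_min
        )
        return model.a_oh_baseline + model.vent_delta * float(pulse)
    g = model.genotype_scaling[genotype]
    da = model.delta_a_max.get(region, 0.0)
    return model.a_oh_baseline + g * da * float(1.0 - np.exp(-t_min / model.tau_min))


@dataclass(frozen=True)
class PhantomConfig:
    """Study-condition constants of the simulated acquisition."""

    shape: tuple[int, int] = (45, 45)
    fov_mm: float = 16.0
    b0_range_ppm: tuple[float, float] = (-0.1, 0.1)
    rel_b1_range: tuple[float, float] = (0.9, 1.1)
    pools: PoolParams = field(default_factory=default_pools)
    mt: float = 0.05
    uptake_model: UptakeModel = field(default_factory=UptakeModel)
    noise_sd: float = 0.005
    noise_model: str = "gaussian"           # "gaussian" | "rician"
    baseline_times_min: tuple[float, ...] = (-24.0, -16.0, -8.0)
    post_times_min: tuple[float, ...] = (14.0, 22.0, 30.0, 38.0, 46.0, 54.0)
    # WASABI truth envelope
    wasabi_c: float = 0.9
    wasabi_d: float = 0.8
    wasabi_b1_uT: float = 3.7
    wasabi_tp_s: float = 0.005
    field_T: float = 7.0
    # dynamic protocol
    n_frames: int = 90
    frame_interval_s: float = 9.0
    n_baseline_frames: int = 15
    infusion_duration_s: float = 90.0
    dyn_offset_ppm: float = 1.2
    # cohort
    subject_cv: float = 0.2

    @property
    def voxel_mm(self) -> float:
        return self.fov_mm / self.shape[0]

    @property
    def timepoints_min(self) -> tuple[float, ...]:
        return tuple(self.baseline_times_min) + tuple(self.post_times_min)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of one simulated subject (shared anatomical space)."""

    labels: np.ndarray
    b0_ppm: np.ndarray
    rel_b1: np.ndarray
    genotype: str
    seed: int
    config: PhantomConfig
    uptake_model: UptakeModel

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == LABELS[region]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def pools_at(self, region: str, t_min: float) -> tuple[PoolParams, float]:
        """Region pools (with the uptake-driven hydroxyl amplitude) and MT."""
        cfg = self.config
        a_oh = uptake(t_min, region, self.genotype, self.uptake_model)
        pools = replace(
            cfg.pools, hydroxyl=replace(cfg.pools.hydroxyl, amplitude=a_oh)
        )
        return pools, cfg.mt

    def effective_pools(self, i: int, j: int, t_min: float) -> tuple[PoolParams, float]:
        """What voxel (i, j) actually contains at ``t_min``: region pools with
        centres shifted by the local B0 and exchange-pool amplitudes scaled by
        the local relative B1."""
        region = {v: k for k, v in LABELS.items()}[int(self.labels[i, j])]
        if region == "background":
            raise ConfigError("background voxels carry no pools")
        pools, mt = self.pools_at(region, t_min)
        b0 = float(self.b0_ppm[i, j])
        rb1 = float(self.rel_b1[i, j])
        new = {}
        for name, p in pools.as_dict().items():
            amp = p.amplitude if name == "water" else p.amplitude * rb1
            new[name] = Pool(amp, p.fwhm, p.center + b0)
        return PoolParams(**new), mt


def _smooth_field(shape, rng, lo, hi):
    """Seeded smooth low-order field mapped linearly onto [lo, hi]."""
    nx, ny = shape
    x = (np.arange(nx) - (nx - 1) / 2) / (nx / 2)
    y = (np.arange(ny) - (ny - 1) / 2) / (ny / 2)
    X, Y = np.meshgrid(x, y, indexing="ij")
    c = rng.standard_normal(5)
    f = c[0] * X + c[1] * Y + c[2] * X * Y + c[3] * (X * X - Y * Y) + c[4] * (X * X + Y * Y)
    if hi == lo or np.ptp(f) < 1e-12:
        return np.full(shape, (lo + hi) / 2)
    return lo + (f - f.min()) / np.ptp(f) * (hi - lo)


def build_phantom(config: PhantomConfig, seed: int, genotype: str = "WT",
                  uptake_model: UptakeModel | None = None) -> PhantomTruth:
    """Deterministic labelled slice plus smooth B0/B1 fields for one subject.

    Raises :class:`ConfigError` if the grid is too small to hold all four
    regions.
    """
    nx, ny = config.shape
    if nx < 16 or ny < 16:
        raise ConfigError(f"grid {config.shape} too small for the region layout")
    cx, cy = (nx - 1) / 2, (ny - 1) / 2
    rx, ry = 0.40 * nx, 0.33 * ny
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r2 = ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2

    vi = np.abs(ii - cx)
    vent = (
        (np.abs(vi - 0.09 * nx) <= max(0.5, 0.02 * nx))
        & (np.abs(jj - cy) <= 0.18 * ny)
        & (r2 <= 0.3)
    )
    labels = np.zeros((nx, ny), dtype=np.int16)
    labels[(r2 <= 1.0)] = LABELS["cortex"]
    labels[(r2 <= 0.62) & ~vent] = LABELS["hippocampus"]
    labels[(r2 <= 0.15) & ~vent] = LABELS["thalamus"]
    labels[vent & (r2 <= 1.0)] = LABELS["ventricles"]

    for region, code in LABELS.items():
        if region != "background" and not np.any(labels == code):
            raise ConfigError(f"region {region} empty on grid {config.shape}")

    rng = np.random.default_rng(seed)
    b0 = _smooth_field(config.shape, rng, *config.b0_range_ppm)
    rb1 = _smooth_field(config.shape, rng, *config.rel_b1_range)
    return PhantomTruth(
        labels=labels, b0_ppm=b0, rel_b1=rb1, genotype=genotype,
        seed=int(seed), config=config,
        uptake_model=uptake_model or config.uptake_model,
    )


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _region_z(truth: PhantomTruth, region: str, t_min: float,
              offsets: np.ndarray) -> np.ndarray:
    """Noiseless Z of every voxel of ``region``, shape (n_voxels, n_offsets)."""
    mask = truth.region_mask(region)
    b0v = truth.b0_ppm[mask]
    rb1v = truth.rel_b1[mask]
    pools, mt = truth.pools_at(region, t_min)
    z = np.full((b0v.size, offsets.size), 1.0 - mt)
    for name, p in pools.as_dict().items():
        amp = p.amplitude if name == "water" else p.amplitude * rb1v[:, None]
        u = (offsets[None, :] - (p.center + b0v[:, None])) / (0.5 * p.fwhm)
        z -= amp / (1.0 + u * u)
    return z


def _apply_noise(s: np.ndarray, sd: float, rng, model: str) -> np.ndarray:
    if sd == 0:
        return s
    if model == "gaussian":
        return s + rng.normal(0.0, sd, s.shape)
    if model == "rician":
        return np.sqrt((s + rng.normal(0.0, sd, s.shape)) ** 2
                       + rng.normal(0.0, sd, s.shape) ** 2)
    raise ConfigError(f"unknown noise model {model!r}")


@dataclass
class SubjectSim:
    """All simulated acquisitions of one subject."""

    subject_id: str
    genotype: str
    truth: PhantomTruth
    schedule: OffsetSchedule
    zstack_times_min: tuple[float, ...]
    zstacks: list[np.ndarray]            # each (nx, ny, n_offsets)
    wasabi_offsets_ppm: np.ndarray
    wasabi_stack: np.ndarray             # (nx, ny, 43)
    frame_times_s: np.ndarray
    dynamic_stack: np.ndarray            # (nx, ny, n_frames)

    def roi_zspectrum(self, region: str, t_min: float) -> ZSpectrum:
        """ROI-mean Z-spectrum of one region at one acquisition time."""
        k = self.zstack_times_min.index(t_min)
        mask = (self.truth.labels > 0) if region == "whole_brain" \
            else self.truth.region_mask(region)
        z = self.zstacks[k][mask].mean(axis=0)
        return ZSpectrum(self.schedule, z, voxel_or_roi_id=region,
                         timepoint_s=t_min * 60.0)


def simulate_subject(truth: PhantomTruth, config: PhantomConfig | None = None,
                     noise_sd: float | None = None, seed: int = 0,
                     subject_id: str = "sub") -> SubjectSim:
    """Simulate the full protocol for one subject.

    Nine Z-spectrum stacks (3 baseline, 6 post-injection), one WASABI stack
    and one 90-frame dynamic series, all with seeded additive noise and the
    normalisation frame renormalised to 1 as the analysis assumes.  With
    ``noise_sd = 0`` every voxel equals the forward model exactly.
    """
    cfg = config or truth.config
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    if sd < 0:
        raise ConfigError(f"noise_sd must be >= 0, got {sd}")
    rng = np.random.default_rng(seed)
    nx, ny = cfg.shape
    schedule = OffsetSchedule.steady_state()
    offs = schedule.offsets

    zstacks = []
    for t_min in cfg.timepoints_min:
        stack = np.ones((nx, ny, offs.size))
        for region in REGIONS:
            mask = truth.region_mask(region)
            z = _region_z(truth, region, t_min, offs)
            z[:, schedule.s0_index] = 1.0
            stack[mask] = z
        stack = _apply_noise(stack, sd, rng, cfg.noise_model)
        stack /= stack[..., schedule.s0_index][..., None]
        zstacks.append(stack)

    woffs = wasabi_offsets()
    wstack = np.full((nx, ny, woffs.size), cfg.wasabi_c)
    bmask = truth.brain_mask
    for i, j in zip(*np.nonzero(bmask)):
        wstack[i, j] = wasabi_model(
            woffs, cfg.wasabi_b1_uT * truth.rel_b1[i, j], truth.b0_ppm[i, j],
            cfg.wasabi_c, cfg.wasabi_d, cfg.wasabi_tp_s, cfg.field_T,
        )
    wstack = np.abs(_apply_noise(wstack, sd, rng, cfg.noise_model))

    frame_times = cfg.frame_interval_s * np.arange(1, cfg.n_frames + 1)
    t_inject_s = cfg.frame_interval_s * cfg.n_baseline_frames
    dyn = np.ones((nx, ny, cfg.n_frames))
    for k, t_s in enumerate(frame_times):
        t_min = (t_s - t_inject_s) / 60.0
        for region in REGIONS:
            mask = truth.region_mask(region)
            z = _region_z(truth, region, t_min, np.array([cfg.dyn_offset_ppm]))
            dyn[mask, k] = z[:, 0]
    dyn = _apply_noise(dyn, sd, rng, cfg.noise_model)

    return SubjectSim(
        subject_id=subject_id, genotype=truth.genotype, truth=truth,
        schedule=schedule, zstack_times_min=cfg.timepoints_min,
        zstacks=zstacks, wasabi_offsets_ppm=woffs, wasabi_stack=wstack,
        frame_times_s=frame_times, dynamic_stack=dyn,
    )


@dataclass
class Cohort:
    """A simulated two-genotype cohort in a shared space."""

    subjects: list[SubjectSim]
    config: PhantomConfig
    seed: int

    def by_genotype(self, genotype: str) -> list[SubjectSim]:
        return [s for s in self.subjects if s.genotype == genotype]


def simulate_cohort(n_wt: int, n_tg: int, config: PhantomConfig | None = None,
                    seed: int = 0) -> Cohort:
    """Simulate ``n_wt`` wild-type and ``n_tg`` transgenic subjects.

    Per-subject seeds derive from the master seed; between-subject biological
    variability multiplies every uptake increment by a unit-mean lognormal
    factor with coefficient of variation ``config.subject_cv``.
    """
    if n_wt < 1 or n_tg < 1:
        raise ConfigError("need at least one subject per genotype")
    cfg = config or PhantomConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_wt + n_tg)
    sigma = float(np.sqrt(np.log(1.0 + cfg.subject_cv**2)))
    subjects = []
    genotypes = ["WT"] * n_wt + ["TG"] * n_tg
    for k, (genotype, child) in enumerate(zip(genotypes, children)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        factor = 1.0 if sigma == 0 else float(rng.lognormal(-sigma**2 / 2, sigma))
        model = cfg.uptake_model.scaled(factor)
        truth = build_phantom(cfg, seed=sub_seed, genotype=genotype,
                              uptake_model=model)
        n_in_group = k + 1 if genotype == "WT" else k - n_wt + 1
        sid = f"{genotype.lower()}{n_in_group:02d}"
        subjects.append(
            simulate_subject(truth, cfg, seed=sub_seed + 1, subject_id=sid)
        )
    return Cohort(subjects=subjects, config=cfg, seed=int(seed))
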