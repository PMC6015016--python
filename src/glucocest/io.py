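"""NIfTI + JSON-sidecar I/O for the glucoCEST pipeline.

On-disk dialect: every 4-D acquisition is a NIfTI volume (x, y, 1, frames)
with a same-stem ``.json`` sidecar carrying the acquisition metadata the
analysis needs (offset schedule, timing, saturation parameters).  Parameter
maps are single-slice 3-D float32 volumes.  A subject directory holds::

    labels.nii.gz                 region labels (0 background, 1 cortex,
                                  2 hippocampus, 3 thalamus, 4 ventricles)
    wasabi.nii.gz  + .json        WASABI stack
    zspec_t00..08.nii.gz + .json  Z-spectrum stacks (3 baseline, 6 post)
    dynamic.nii.gz + .json        90-frame single-offset series
    manifest.json                 subject id, genotype, seed
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .analysis import SubjectData
from .errors import ConfigError, GeometryError
from .zspec import OffsetSchedule

__all__ = [
    "save_map",
    "load_map",
    "write_stack",
    "read_stack",
    "write_subject",
    "read_subject",
    "write_cohort",
    "read_cohort",
]

ZSPEC_SIDECAR_KEYS = ("offsets_ppm", "b1_uT", "tsat_s", "s0_index", "timepoint_s")
WASABI_SIDECAR_KEYS = ("offsets_ppm", "b1_nominal_uT", "tp_s", "field_T")
DYNAMIC_SIDECAR_KEYS = ("offset_ppm", "frame_interval_s", "infusion")


def _affine(voxel_mm: tuple[float, float, float]) -> np.ndarray:
    return np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])


def save_map(path, data: np.ndarray, voxel_mm=(0.3556, 0.3556, 2.0)) -> Path:
    """Save a 2-D map (or (x, y, n) stack) as a single-slice NIfTI volume."""
    path = Path(path)
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    elif arr.ndim == 3:
        arr = arr[:, :, None, :]
    else:
        raise ConfigError(f"cannot save array of ndim {arr.ndim}")
    nib.save(nib.Nifti1Image(arr, _affine(voxel_mm)), str(path))
    return path


def load_map(path) -> np.ndarray:
    """Load a NIfTI written by :func:`save_map`, squeezing the slice axis."""
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if arr.ndim == 4:
        return arr[:, :, 0, :]
    if arr.ndim == 3:
        return arr[:, :, 0]
    return arr


def _read_sidecar(nii_path: Path, required: tuple[str, ...]) -> dict:
    sidecar_path = Path(str(nii_path).replace(".nii.gz", ".json").replace(".nii", ".json"))
    if not sidecar_path.exists():
        raise ConfigError(f"missing sidecar {sidecar_path.name}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in required:
        if key not in meta:
            raise ConfigError(f"sidecar {sidecar_path.name} missing field {key!r}")
    return meta


def write_stack(nii_path, stack: np.ndarray, sidecar: dict,
                voxel_mm=(0.3556, 0.3556, 2.0)) -> Path:
    """Write a (x, y, frames) stack plus its JSON sidecar."""
    nii_path = Path(nii_path)
    save_map(nii_path, stack, voxel_mm)
    sidecar_path = Path(str(nii_path).replace(".nii.gz", ".json").replace(".nii", ".json"))
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return nii_path


def read_stack(nii_path, kind: str = "zspec") -> tuple[np.ndarray, dict]:
    """Read a stack and its validated sidecar.

    ``kind`` selects the required sidecar fields: "zspec", "wasabi" or
    "dynamic".  A missing or malformed sidecar raises :class:`ConfigError`
    naming the offending field.
    """
    required = {
        "zspec": ZSPEC_SIDECAR_KEYS,
        "wasabi": WASABI_SIDECAR_KEYS,
        "dynamic": DYNAMIC_SIDECAR_KEYS,
    }[kind]
    meta = _read_sidecar(Path(nii_path), required)
    stack = load_map(nii_path)
    n_frames = stack.shape[-1]
    if kind in ("zspec", "wasabi") and len(meta["offsets_ppm"]) != n_frames:
        raise ConfigError(
            f"sidecar offsets_ppm has {len(meta['offsets_ppm'])} entries, "
            f"stack has {n_frames} frames"
        )
    return stack, meta


# ---------------------------------------------------------------------------
# subject / cohort directories
# ---------------------------------------------------------------------------

def write_subject(sim, out_dir) -> Path:
    """Write one simulated subject (a :class:`~glucocest.phantom.SubjectSim`)
    in the pipeline's directory dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = sim.truth.config
    vox = (cfg.voxel_mm, cfg.voxel_mm, 2.0)

    save_map(out / "labels.nii.gz", sim.truth.labels.astype(np.float32), vox)
    write_stack(out / "wasabi.nii.gz", sim.wasabi_stack, {
        "offsets_ppm": list(map(float, sim.wasabi_offsets_ppm)),
        "b1_nominal_uT": cfg.wasabi_b1_uT,
        "tp_s": cfg.wasabi_tp_s,
        "field_T": cfg.field_T,
    }, vox)
    for k, (t_min, stack) in enumerate(zip(sim.zstack_times_min, sim.zstacks)):
        write_stack(out / f"zspec_t{k:02d}.nii.gz", stack, {
            "offsets_ppm": list(map(float, sim.schedule.offsets)),
            "b1_uT": sim.schedule.b1_uT,
            "tsat_s": sim.schedule.tsat_s,
            "s0_index": sim.schedule.s0_index,
            "timepoint_s": t_min * 60.0,
        }, vox)
    write_stack(out / "dynamic.nii.gz", sim.dynamic_stack, {
        "offset_ppm": cfg.dyn_offset_ppm,
        "frame_interval_s": cfg.frame_interval_s,
        "infusion": {"start_frame": cfg.n_baseline_frames + 1,
                     "duration_s": cfg.infusion_duration_s},
    }, vox)
    with open(out / "manifest.json", "w") as fh:
        json.dump({
            "subject_id": sim.subject_id,
            "genotype": sim.genotype,
            "seed": sim.truth.seed,
            "uptake_delta_a_max": dict(sim.truth.uptake_model.delta_a_max),
        }, fh, indent=1)
    return out


def read_subject(subject_dir) -> SubjectData:
    """Load a subject directory into a :class:`SubjectData`."""
    d = Path(subject_dir)
    if not (d / "manifest.json").exists():
        raise ConfigError(f"{d} has no manifest.json")
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    labels = load_map(d / "labels.nii.gz").astype(np.int16)

    wasabi_stack, wmeta = read_stack(d / "wasabi.nii.gz", "wasabi")
    zpaths = sorted(d.glob("zspec_t*.nii.gz"))
    if not zpaths:
        raise ConfigError(f"{d} has no zspec stacks")
    zstacks, times, schedule = [], [], None
    for p in zpaths:
        stack, meta = read_stack(p, "zspec")
        sched = OffsetSchedule(tuple(meta["offsets_ppm"]), b1_uT=meta["b1_uT"],
                               tsat_s=meta["tsat_s"], s0_index=int(meta["s0_index"]))
        if schedule is None:
            schedule = sched
        elif sched.offsets_ppm != schedule.offsets_ppm:
            raise GeometryError("offset schedules differ across zspec stacks")
        if stack.shape[:2] != labels.shape:
            raise GeometryError(f"{p.name} grid differs from labels")
        zstacks.append(stack)
        times.append(meta["timepoint_s"] / 60.0)

    dyn_stack, dmeta = read_stack(d / "dynamic.nii.gz", "dynamic")
    frame_times = dmeta["frame_interval_s"] * np.arange(1, dyn_stack.shape[-1] + 1)

    return SubjectData(
        subject_id=manifest["subject_id"], genotype=manifest["genotype"],
        labels=labels, schedule=schedule, zstack_times_min=tuple(times),
        zstacks=zstacks, wasabi_offsets_ppm=np.asarray(wmeta["offsets_ppm"]),
        wasabi_stack=wasabi_stack, frame_times_s=frame_times,
        dynamic_stack=dyn_stack,
        wasabi_b1_nominal_uT=wmeta["b1_nominal_uT"], wasabi_tp_s=wmeta["tp_s"],
        field_T=wmeta["field_T"],
    )


def write_cohort(cohort, out_dir) -> Path:
    """Write a simulated cohort: one subdirectory per subject plus manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sim in cohort.subjects:
        write_subject(sim, out / sim.subject_id)
    with open(out / "cohort_manifest.json", "w") as fh:
        json.dump({
            "seed": cohort.seed,
            "subjects": [
                {"subject_id": s.subject_id, "genotype": s.genotype}
                for s in cohort.subjects
            ],
        }, fh, indent=1)
    return out


def read_cohort(cohort_dir) -> list[SubjectData]:
    d = Path(cohort_dir)
    manifest_path = d / "cohort_manifest.json"
    if not manifest_path.exists():
        raise ConfigError(f"{d} has no cohort_manifest.json")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return [read_subject(d / s["subject_id"]) for s in manifest["subjects"]]
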