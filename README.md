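# glucocest

Quantitative analysis of **glucoCEST MRI** — chemical exchange saturation
transfer imaging of 2-deoxy-D-glucose (2DG) uptake in the brain — with a
digital brain phantom that makes every stage of the pipeline verifiable by
parameter recovery.

2DG enters cells through the glucose transporters, is phosphorylated to
2DG6P and trapped; its hydroxyl protons exchange with water and are visible
as a CEST signal near +1.2 ppm. Comparing the hydroxyl signal before and
after a 2DG bolus therefore measures regional glucose uptake — a PET-like
metabolic readout without a radiotracer, at MRI resolution. The package is
aimed at preclinical imaging groups analysing Z-spectrum series from small
animal scanners (and at anyone who wants a fully testable reference
implementation of this analysis).

## What it computes

**Five-pool Z-spectrum decomposition.** Each Z-spectrum `Z(Δω) = S/S₀`
(58 offsets, normalisation frame at 300 ppm) is modelled as

    Z(Δω) = 1 − Σᵢ Aᵢ · (1 + ((Δω − δωᵢ) / (Lᵢ/2))²)⁻¹ − MT,

with pools i ∈ {water, rNOE, amine, amide, hydroxyl} (amplitude `Aᵢ`, FWHM
`Lᵢ`, centre `δωᵢ`) and a constant semi-solid MT term estimated from the
+5 ppm sample, `MT = (S₀ − S₊₅)/S₀`. Fitting is the field's two-step
procedure — water + rNOE on the hydroxyl-free offsets in [−6, 0.5] ppm,
re-centring on the fitted water minimum, then the three solute pools on the
residue — wrapped in a short fixed-point refinement and a joint polish so
that noiseless spectra are recovered to numerical precision
(`glucocest.fit_multipool`).

**WASABI field maps.** B0 and relative B1 per voxel from the analytic
rect-pulse Rabi-pattern model (`glucocest.fit_wasabi`); B0 initialises the
water centre, relative B1 linearly corrects the difference curve.

**GCE.** The Lorentzian difference `LD = Z_ref − Z_lab` (fitted background
minus full fitted model = the three solute lines) is integrated over the
hydroxyl band [1.0, 2.3] ppm, and the glucose CEST enhancement per
post-injection timepoint is

    GCE(t) = (AUC_LD(t) − AUC_LD(baseline)) / AUC_LD(baseline),

with the baseline averaged over the three pre-injection spectra
(`glucocest.gce_timecourse`).

**Dynamic CEST.** For the 90-frame single-offset series (9 s/frame,
saturation at 1.2 ppm, bolus after 15 baseline frames):
`AUC_Dyn = Σₙ (S_baseline − S(tₙ))/S_baseline` over the 110–700 s window
(`glucocest.auc_dyn`).

**Group statistics.** Per-ROI genotype × time fixed-effects ANOVA with
Hochberg step-up correction across ROIs, and a seeded voxelwise two-sample
permutation t-test (exhaustive when feasible, one-sided WT > TG by default)
as a native replacement for FSL `randomise` (`glucocest.stats`).

**Digital phantom.** A labelled 45 × 45 slice (cortex, hippocampus,
thalamus, ventricles; 16 mm FOV → 0.35 mm in-plane) with smooth B0/B1
inhomogeneity fields, a saturating 2DG-uptake model with a genotype deficit
(transgenic scaling 0.6), a ventricular bolus transient with washout, and
seeded noise — generating Z-spectrum stacks, WASABI scans and dynamic
series in exactly the NIfTI + JSON dialect the analysis consumes
(`glucocest.phantom`, `glucocest.io`).

## Worked example

`examples/` contains one short script per capability. For instance the GCE
time course of a single simulated wild-type subject
(`python examples/03_gce_timecourse.py`):

```
cortex       14min:+0.132  22min:+0.167  30min:+0.175  38min:+0.204  46min:+0.211  54min:+0.207
hippocampus  14min:+0.101  22min:+0.137  30min:+0.144  38min:+0.157  46min:+0.153  54min:+0.165
ventricles   14min:+0.002  22min:-0.013  30min:-0.004  38min:-0.017  46min:-0.021  54min:+0.010
```

The cortex hydroxyl-band area grows ~13% within 14 minutes of the bolus and
saturates around +21% as trapped 2DG6P accumulates; the ventricles stay flat
because the bolus has washed out of the CSF before the first post-injection
spectrum. The cohort example (`examples/05_cohort_statistics.py`) runs a
4 v 4 simulated cohort and prints, e.g., a cortex genotype effect of
F = 69.9, p = 5.9 × 10⁻¹⁰ (Hochberg-adjusted 1.8 × 10⁻⁹) — the built-in
transgenic uptake deficit detected end-to-end.

A thin CLI mirrors the pipeline for directory-based runs:

```bash
glucocest simulate --seed 1 --out cohort/
glucocest gce --subject cohort/wt01 --out derived/wt01
glucocest stats --cohort cohort/ --out group/
```

## Layout

- `src/glucocest/zspec.py` — model, MT estimator, two-step fit, LD curve
- `src/glucocest/wasabi.py` — B0/B1 field mapping
- `src/glucocest/gce.py`, `dynamic.py` — AUC_LD/GCE and AUC_Dyn statistics
- `src/glucocest/stats.py` — ROI stats, ANOVA + Hochberg, permutation t-test
- `src/glucocest/phantom.py` — digital phantom and forward simulation
- `src/glucocest/analysis.py`, `pipeline.py`, `io.py`, `cli.py` — orchestration
- `docs/methods.md` — model assumptions, numerical choices, limitations
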