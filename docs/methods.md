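# Methods

## The measurement problem

GlucoCEST detects 2-deoxy-D-glucose (2DG) and its trapped metabolite 2DG6P
through the chemical exchange of their hydroxyl protons (~+1.2 ppm from
water) with bulk water. Saturation transferred from the solute pool lowers
the water signal; the Z-spectrum — normalised signal vs saturation offset —
encodes every exchanging pool at once. The analysis problem is to isolate
the small hydroxyl contribution (amplitudes of order 0.02 of the water
signal) from direct water saturation, the relayed NOE, amide and amine
pools, a semi-solid MT background, and B0/B1 field inhomogeneity, and to
track its growth after a 2DG bolus.

## Spectral model

Each spectrum is modelled as a sum of five inverted Lorentzian lines plus a
constant MT term:

    Z(Δω) = 1 − Σᵢ Aᵢ (1 + ((Δω − δωᵢ)/(Lᵢ/2))²)⁻¹ − MT.

The MT term is *subtracted*: it is defined as the positive fractional signal
drop remaining at +5 ppm, `MT = (S₀ − S₊₅)/S₀` with S₀ the 300 ppm
acquisition, so the far-from-resonance plateau of the model is `1 − MT`.
(The alternative sign convention would make the MT estimator and the model
mutually inconsistent; the model/estimator link is asserted by a dedicated
test at the 2 × 10⁻³ level.) The MT estimate uses only the +5 ppm side —
the −5 ppm side is contaminated by the rNOE line, which the background fit
models explicitly.

Pool centre bounds and width bounds (not identifiable from first
principles; standard 7 T positions): water 0 ± 1 ppm around the B0
initialisation, rNOE −3.5 ± 1, amine +2.0 ± 0.4, amide +3.5 ± 0.4, hydroxyl
+1.2 ± 0.4 ppm, widths water [0.3, 4] ppm, others [0.5, 8] ppm, amplitudes
[0, 1]. Solute and rNOE centre windows are expressed *relative to the
fitted water centre*: chemical shifts ride on the local B0.

## Two-step inversion and its refinement

The inversion follows the two-step scheme: (A) water + rNOE fitted on the
hydroxyl-free offsets in [−6, +0.5] ppm with MT held fixed, the offset
origin re-centred on the fitted water minimum; (B) the residue (background
model minus data) fitted with the three solute lines.

Two systematic couplings make a single pass inexact: the pool tails at
+5 ppm bias the MT estimate (≈0.03 for typical in-vivo-like parameters),
and the solute tails leak into the background window. Both steps therefore
sit in a short fixed-point loop (3 passes): after each pass the MT estimate
is corrected by the fitted pool tails at +5 ppm and the background refit
removes the fitted solute contribution from its window. The loop is
stationary at the generating parameters. Because its linear convergence is
slow near the fixed point, the two-step result then seeds a joint bounded
least-squares refinement of all 16 parameters over the full offset range,
which reaches the exact noiseless solution in a few Gauss-Newton steps.
The result keeps the two-step's structure (the reported re-centring shift
is the fitted water-minimum location) while meeting a 10⁻³ noiseless
round-trip tolerance with two orders of magnitude to spare.

Re-centring is implemented as a rigid shift applied to the *model* (solute
centre windows displaced by the fitted water centre; LD evaluated on the
water-centred axis) rather than by resampling the data onto a shifted axis.
The two are mathematically equivalent, but linear interpolation of the
steep water line on the ~0.17 ppm offset grid would introduce O(10⁻²)
signal errors and destroy noiseless recovery; shifting the model is exact.

Numerics: `scipy.optimize.least_squares` (trust-region reflective) with
analytic Jacobians, ftol/xtol/gtol 10⁻¹²–10⁻¹⁴, ≤2000–3000 evaluations;
seeded jittered restarts (3 for the sub-fits, 2 for the joint polish,
accepted early at cost < 10⁻¹²) guard against the rare local minimum of
strongly overlapping solute lines. All restarts are deterministic.

Degenerate inputs: a flat spectrum drives all amplitudes to the zero bound
and succeeds; NaN anywhere is rejected before fitting; fewer than 7 usable
background samples raises an underdetermined-fit error.

## WASABI field mapping

The rect-pulse WASABI model
`|c − d · sin²(atan(γB₁/Δf)) · sin²(π t_p √((γB₁)² + Δf²))|` with
γ = 42.577 MHz/T, t_p = 5 ms, nominal B₁ = 3.7 μT at 7 T is inverted by
bounded least squares with a multi-start over dB0 ∈ {−0.5, 0, +0.5} ppm.
Relative B1 is the fitted B1 over nominal. Flat signals (no Rabi pattern)
return a degenerate status; at map level such voxels fall back to
dB0 = 0, rel B1 = 1 and are flagged. Noiseless recovery is exact to
numerical precision; at σ = 0.01 noise the median errors are well under
0.02 ppm / 3%.

## Lorentzian difference, AUC and GCE

`LD = Z_ref − Z_lab` with Z_ref the fitted background (water + rNOE + MT)
and Z_lab the full fitted model — algebraically the sum of the three fitted
solute lines, evaluated on a dense grid (0.01 ppm step) in the
water-centred frame. Using the *fitted* Z_lab (not the measured spectrum)
makes LD smooth and the MT term cancel exactly.

The B1 correction is linear: the default multiplies LD by the relative B1
(`multiply`, the convention of the source protocol);
`divide` is offered because low-power CEST contrast scales
approximately linearly *with* B1, so division is the compensating
direction. The mode is recorded with every output. For GCE the choice is
immaterial when B1 is constant over the averaging region, since a common
factor cancels in the ratio.

AUC_LD integrates LD over [1.0, 2.3] ppm (trapezoid on the dense grid,
endpoint-interpolated; verified against the arctan antiderivative at
10⁻⁶). GCE(t) is the fractional change of AUC_LD versus the mean of the
three baseline spectra; averaging is over baseline *AUC values*, not
spectra (order of operations matters only at second order, and AUC-level
averaging keeps each baseline spectrum's fit independent). Voxels with
non-positive baseline AUC are masked and counted in the QC report.

## Dynamic single-offset analysis

Frame timestamps are end-of-frame times tₙ = 9n s, n = 1…90; the baseline
is the mean of frames 1–15 and the bolus starts after frame 15. AUC_Dyn
sums the fractional drop over all frames with tₙ ∈ [110, 700] s, inclusive.
Two protocol quirks are handled literally but configurably: the printed
window bounds cannot be frame indices (there are only 90 frames), so they
are read as seconds; and the window's start (110 s) precedes the end of the
baseline block (135 s), so the two overlap slightly — `auc_dyn` accepts an
explicit baseline override for analyses that need them decoupled. No B0/B1
correction is applied to dynamic data: with a single offset there is
nothing to correct against, which is also why this readout is the noisier
of the two.

## Group statistics

Per ROI, a fixed-effects two-way ANOVA (genotype × time with interaction,
statsmodels OLS, type-II sums of squares — the design is balanced, so the
type choice is moot) on the GCE table. Subjects are treated as independent
within each cell; repeated measures over time are *not* modelled, so the
time and interaction p values should be read cautiously (a mixed model is
deliberately out of scope). Hochberg's step-up adjustment is applied across
the family of ROIs, separately per effect; the family choice is
configurable.

The voxelwise test is a two-sample pooled-variance t with permutation p
values over group relabelings: exhaustive enumeration whenever
C(n_A+n_B, n_A) ≤ the permutation budget (3432 for 7 v 7, so the study
design is always exhaustive), otherwise seeded Monte Carlo with the
observed labeling added (`(1+k)/(1+B)` estimator). One-sided WT > TG is the
default alternative; an optional max-t distribution provides familywise
correction. Voxels with zero pooled variance are masked (t = 0, p = 1).
P values are exactly reproducible given (seed, budget).

## The digital phantom

No imaging data are distributed with the analysis, so validation rests on a
synthetic subject whose ground truth is known exactly. The phantom is a
45 × 45 labelled slice (16 mm FOV, 0.356 mm in-plane — the acquisition
geometry) with four regions; per-region five-pool parameters default to
water A 0.85 / L 1.4, rNOE 0.10 / 3.5 at −3.5, amide 0.05 / 1.5 at +3.5,
amine 0.03 / 1.5 at +2.0, hydroxyl baseline 0.02 / 1.0 at +1.2 ppm,
MT 0.05 — literature-plausible 7 T values chosen once so that simulated
cortex GCE lands in the tens-of-percent range.

Uptake: tissue hydroxyl amplitude follows A₀ + g·ΔA_max·(1 − e^(−t/τ)) with
ΔA_max 0.015/0.012/0.010 (cortex/hippocampus/thalamus), τ = 15 min, and
genotype scaling g = 1 (wild type) vs 0.6 (transgenic) — trapping of 2DG6P
motivates the saturating form. Ventricles get a genotype-independent
transient (rise 0.5 min, washout 3 min) that returns to within 5% of
baseline before the first post-injection spectrum at 14 min, emulating
bolus washout from CSF. Acquisition timing: three baseline spectra at
−24/−16/−8 min and six post at 14…54 min in 8 min steps (the per-spectrum
scan time), 90 dynamic frames at 9 s.

Field inhomogeneity: smooth seeded low-order polynomial fields, B0 within
±0.1 ppm and relative B1 within [0.9, 1.1] by default (the B1 range is kept
small because the analysis's linear correction is only first-order).  The
forward model shifts all pool centres by the local B0 and scales the
exchange-mediated (non-water) pool amplitudes by the local relative B1;
recovery tests compare fitted maps against this *effective* per-voxel
truth, which is what the spectrum actually contains. Noise is additive
Gaussian on the normalised signal (default σ 0.005, plausible for summed
RARE readouts; a Rician option exists), applied before renormalisation by
the (noisy) S₀ frame. Cohorts draw per-subject seeds from a master
`SeedSequence` and apply unit-mean lognormal between-subject variability
(CV 0.2) to the uptake increments.

What the phantom does *not* emulate — and hence what passing tests do not
show about real data: realistic anatomy and partial-volume mixtures,
exchange-rate physics (the forward model *is* the Lorentzian
parameterisation, so model error of the Lorentzian approximation itself is
invisible), motion, drift other than static B0, coil-profile intensity
bias, and inter-scanner variability. Effect sizes are order-of-magnitude
plausible rather than calibrated to in-vivo measurements.

## Problem sizes of the validation runs

Round-trip recovery uses 100 random admissible draws; ANOVA type-I
calibration uses 500 null tables of the full 7 v 7 × 6-timepoint design;
effect detection uses 20 independently seeded 7 v 7 cohorts analysed at ROI
scope (ROI-mean spectra, one fit per region and timepoint). ROI scope is
the package's default for cohort statistics: averaging ~10²–10³ voxels
suppresses spectral noise by the usual √N and makes the per-subject
analysis a few dozen fits; voxelwise fitting (every in-brain voxel, per
timepoint) produces the parameter and GCE maps and is exercised on smaller
grids in the test suite.

## Known limitations

- The MT term is a constant, valid only at low saturation power; no
  Bloch–McConnell exchange modelling, exchange rates or concentrations.
- Amine/hydroxyl lines overlap strongly; their individual amplitudes are
  poorly conditioned at realistic single-voxel noise (the hydroxyl-band
  AUC, which sums them over [1, 2.3] ppm, is much better behaved).
- The repeated-measures structure of the time courses is ignored by the
  fixed-effects ANOVA (see above).
- Spatial normalisation/registration is out of scope: all volumes are
  assumed co-registered on a common grid, and the pipeline refuses
  heterogeneous grids rather than resampling.
- The dynamic readout has no field correction and is sensitive to drift;
  it is a delivery surrogate, not a perfusion measurement.
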