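"""Fit a single noisy Z-spectrum with the two-step five-pool decomposition.

Simulates one voxel's Z-spectrum from known pool parameters (58-offset
steady-state schedule, additive noise), inverts it with ``fit_multipool``,
and prints recovered vs true parameters.  The hydroxyl amplitude is the
quantity glucoCEST ultimately tracks.
"""

import numpy as np

from glucocest import OffsetSchedule, Pool, PoolParams, ZSpectrum, fit_multipool, zmodel

schedule = OffsetSchedule.steady_state()
truth = PoolParams(
    water=Pool(0.85, 1.4, 0.05),      # direct water saturation, B0-shifted
    noe=Pool(0.10, 3.5, -3.45),       # relayed NOE (aliphatic protons)
    amine=Pool(0.03, 1.5, 2.05),
    amide=Pool(0.05, 1.5, 3.55),
    hydroxyl=Pool(0.025, 1.0, 1.25),  # the 2DG/2DG6P-sensitive pool
)
mt_true = 0.05

rng = np.random.default_rng(0)
z = zmodel(schedule.offsets, truth, mt_true)
z[schedule.s0_index] = 1.0
z += rng.normal(0.0, 0.002, z.shape)          # ~SNR of a summed RARE readout
z /= z[schedule.s0_index]

fit = fit_multipool(ZSpectrum(schedule, z), b0_init=0.05)

print(f"{'pool':<10}{'A fit':>8}{'A true':>8}{'L fit':>8}{'L true':>8}"
      f"{'c fit':>8}{'c true':>8}")
for name, (p_fit, p_true) in zip(
    ("water", "rNOE", "amine", "amide", "hydroxyl"),
    zip(fit.pools.as_tuple(), truth.as_tuple()),
):
    print(f"{name:<10}{p_fit.amplitude:8.4f}{p_true.amplitude:8.4f}"
          f"{p_fit.fwhm:8.3f}{p_true.fwhm:8.3f}"
          f"{p_fit.center:8.3f}{p_true.center:8.3f}")
print(f"MT constant: fitted {fit.mt:.4f}, true {mt_true:.4f}")
print(f"residual RMS {fit.residual_rms:.2e}, "
      f"re-centring shift {fit.recentering_shift_ppm:+.3f} ppm")
print("Amplitudes are fractions of the normalised signal; widths/centres in "
      "ppm. The fitted water centre doubles as the per-voxel B0 correction.")
print("Note how the small solute pools are noise-limited at the single-voxel "
      "level — this is why the cohort analysis fits ROI-averaged spectra.")
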