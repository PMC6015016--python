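"""Five-pool Z-spectrum model, MT estimator, two-step fit and LD curve."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glucocest.errors import (
    InvalidInputError,
    InvalidParameterError,
    InvalidSignalError,
    MissingOffsetError,
    NegativeSignalWarning,
    OffsetRangeError,
    UnderdeterminedError,
)
from glucocest.zspec import (
    OffsetSchedule,
    Pool,
    PoolParams,
    ZSpectrum,
    compute_mt,
    fit_background,
    fit_multipool,
    fit_solutes,
    lorentzian,
    lorentzian_difference,
    mtr_asym,
    zmodel,
)

from conftest import draw_admissible_pools, simulate_zspectrum


class TestLorentzian:
    @pytest.mark.parametrize(
        "dw, expected",
        [
            (0.0, 0.5),            # peak equals amplitude at the centre
            (1.0, 0.25),           # half maximum at half FWHM
            (20.0, 0.5 / 401.0),   # closed form far in the tail
        ],
    )
    def test_closed_form(self, dw, expected):
        assert lorentzian(dw, 0.5, 2.0, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            lorentzian(0.0, 0.5, 0.0, 0.0)

    @given(
        dw=st.floats(-30, 30),
        amp=st.floats(0.001, 1.0),
        fwhm=st.floats(0.1, 10.0),
        center=st.floats(-5, 5),
    )
    def test_bounded_and_symmetric(self, dw, amp, fwhm, center):
        val = lorentzian(dw, amp, fwhm, center)
        assert 0.0 <= val <= amp + 1e-15
        mirrored = lorentzian(2 * center - dw, amp, fwhm, center)
        assert val == pytest.approx(mirrored, rel=1e-9, abs=1e-12)
        assert lorentzian(center + fwhm / 2, amp, fwhm, center) == pytest.approx(amp / 2)


class TestZModel:
    def test_trivial_limits(self, schedule):
        zeros = PoolParams(*[Pool(0.0, 1.0, c) for c in (0, -3.5, 2.0, 3.5, 1.2)])
        assert np.allclose(zmodel(schedule.offsets, zeros, 0.0), 1.0)
        assert np.allclose(zmodel(schedule.offsets, zeros, 0.1), 0.9)
        water_only = PoolParams(
            Pool(0.9, 2.0, 0.0), *[Pool(0.0, 1.0, c) for c in (-3.5, 2.0, 3.5, 1.2)]
        )
        assert zmodel(np.array([0.0]), water_only, 0.0)[0] == pytest.approx(0.1)

    def test_oversaturation_warns(self):
        pools = PoolParams(
            Pool(0.95, 2.0, 0.0), *[Pool(0.0, 1.0, c) for c in (-3.5, 2.0, 3.5, 1.2)]
        )
        with pytest.warns(NegativeSignalWarning):
            zmodel(np.array([0.0]), pools, 0.1)

    def test_invalid_mt(self, schedule, default_pools):
        with pytest.raises(InvalidParameterError):
            zmodel(schedule.offsets, default_pools, 1.0)


class TestComputeMT:
    def test_normalized_and_raw_agree(self, schedule):
        z = np.ones(len(schedule))
        z[schedule.index_of(5.0)] = 0.85
        assert compute_mt(ZSpectrum(schedule, z)) == pytest.approx(0.15)
        assert compute_mt(ZSpectrum(schedule, 2000.0 * z)) == pytest.approx(0.15)

    def test_no_saturation_transfer(self, schedule):
        assert compute_mt(ZSpectrum(schedule, np.ones(len(schedule)))) == 0.0

    def test_missing_offset(self):
        sched = OffsetSchedule((300.0, 1.0, 0.0), s0_index=0)
        with pytest.raises(MissingOffsetError):
            compute_mt(ZSpectrum(sched, np.ones(3)))

    def test_nonpositive_s0(self, schedule):
        z = np.ones(len(schedule))
        z[schedule.s0_index] = 0.0
        with pytest.raises(InvalidSignalError):
            compute_mt(ZSpectrum(schedule, z))


class TestBackgroundFit:
    WATER = Pool(0.85, 1.4, 0.05)
    NOE = Pool(0.08, 3.0, -3.5)

    def _two_pool_spectrum(self, schedule, axis_shift=0.0):
        zeros = [Pool(0.0, 1.0, c) for c in (2.0, 3.5, 1.2)]
        water = Pool(self.WATER.amplitude, self.WATER.fwhm, self.WATER.center + axis_shift)
        noe = Pool(self.NOE.amplitude, self.NOE.fwhm, self.NOE.center + axis_shift)
        pools = PoolParams(water, noe, *zeros)
        return simulate_zspectrum(schedule, pools, 0.0)

    def test_noiseless_recovery(self, schedule):
        zs = self._two_pool_spectrum(schedule)
        water, noe, shift = fit_background(zs, b0_init=0.0, mt=0.0)
        for got, want in (
            (water.amplitude, 0.85), (water.fwhm, 1.4), (water.center, 0.05),
            (noe.amplitude, 0.08), (noe.fwhm, 3.0), (noe.center, -3.5),
        ):
            assert got == pytest.approx(want, abs=1e-3)
        assert shift == pytest.approx(0.05, abs=1e-3)

    def test_flat_spectrum_gives_zero_amplitudes(self, schedule):
        zs = ZSpectrum(schedule, np.ones(len(schedule)))
        water, noe, _ = fit_background(zs, b0_init=0.0)
        assert water.amplitude == pytest.approx(0.0, abs=1e-6)
        assert noe.amplitude == pytest.approx(0.0, abs=1e-6)

    def test_shifted_axis_recenters(self, schedule):
        zs = self._two_pool_spectrum(schedule, axis_shift=0.2)
        water, _, shift = fit_background(zs, b0_init=0.0, mt=0.0)
        assert water.center == pytest.approx(0.25, abs=1e-3)
        assert shift == pytest.approx(0.25, abs=1e-3)

    def test_underdetermined(self):
        sched = OffsetSchedule((300.0, 5.0, -1.0, 0.0), s0_index=0)
        with pytest.raises(UnderdeterminedError):
            fit_background(ZSpectrum(sched, np.ones(4)), b0_init=0.0)


class TestSoluteFit:
    OFFSETS = np.linspace(-6, 6, 73)

    def test_zero_residual(self):
        amine, amide, oh = fit_solutes(self.OFFSETS, np.zeros_like(self.OFFSETS))
        for p in (amine, amide, oh):
            assert p.amplitude == pytest.approx(0.0, abs=1e-8)

    def test_single_hydroxyl_recovered(self):
        res = lorentzian(self.OFFSETS, 0.03, 1.0, 1.2)
        _, _, oh = fit_solutes(self.OFFSETS, res)
        assert oh.amplitude == pytest.approx(0.03, abs=1e-3)
        assert oh.fwhm == pytest.approx(1.0, abs=1e-3)
        assert oh.center == pytest.approx(1.2, abs=1e-3)

    def test_amide_only_no_hydroxyl_crosstalk(self):
        res = lorentzian(self.OFFSETS, 0.05, 1.5, 3.5)
        amine, amide, oh = fit_solutes(self.OFFSETS, res)
        assert amide.amplitude == pytest.approx(0.05, abs=1e-3)
        assert oh.amplitude < 1e-3
        assert amine.amplitude < 1e-3


class TestMultipoolFit:
    def test_roundtrip_recovery(self, schedule):
        """Noiseless spectra return the generating parameters (spot check;
        the full 100-draw sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            pools, mt = draw_admissible_pools(rng)
            zs = simulate_zspectrum(schedule, pools, mt)
            fit = fit_multipool(zs, b0_init=pools.water.center)
            err = np.abs(
                np.concatenate([fit.pools.as_array(), [fit.mt]])
                - np.concatenate([pools.as_array(), [mt]])
            ).max()
            assert err < 1e-3

    def test_self_consistency(self, schedule, default_pools):
        zs = simulate_zspectrum(schedule, default_pools, 0.05)
        fit = fit_multipool(zs, b0_init=0.0)
        assert fit.residual_rms < 1e-6

    def test_recentering_invariant(self, schedule, default_pools):
        """After subtracting the re-centring shift the water minimum is at 0."""
        shifted = PoolParams(*[
            Pool(p.amplitude, p.fwhm, p.center + 0.12)
            for p in default_pools.as_tuple()
        ])
        zs = simulate_zspectrum(schedule, shifted, 0.05)
        fit = fit_multipool(zs, b0_init=0.12)
        assert fit.pools.water.center - fit.recentering_shift_ppm == pytest.approx(0.0)
        assert fit.recentering_shift_ppm == pytest.approx(0.12, abs=1e-3)

    def test_nan_input_rejected(self, schedule, default_pools):
        z = zmodel(schedule.offsets, default_pools, 0.05)
        z[schedule.s0_index] = 1.0
        z[10] = np.nan
        with pytest.raises(InvalidInputError):
            fit_multipool(ZSpectrum(schedule, z))

    def test_invalid_rel_b1(self, schedule, default_pools):
        zs = simulate_zspectrum(schedule, default_pools, 0.05)
        with pytest.raises(InvalidParameterError):
            fit_multipool(zs, rel_b1=0.0)

    def test_mt_consistency_with_plateau(self, schedule):
        """Z at +5 ppm equals 1 - MT when all other pools have negligible
        tails there (consistency of the model with the MT estimator)."""
        narrow = PoolParams(
            water=Pool(0.4, 0.4, 0.0), noe=Pool(0.02, 0.5, -3.5),
            amine=Pool(0.005, 0.5, 2.0), amide=Pool(0.005, 0.5, 3.5),
            hydroxyl=Pool(0.005, 0.5, 1.2),
        )
        mt = 0.07
        tails = sum(p(5.0) for p in narrow)
        assert tails < 1e-3
        z5 = zmodel(np.array([5.0]), narrow, mt)[0]
        assert abs(z5 - (1.0 - mt)) < 2e-3


class TestMtrAsym:
    def test_symmetric_spectrum_is_zero(self, schedule):
        pools = PoolParams(
            Pool(0.8, 1.5, 0.0), *[Pool(0.0, 1.0, c) for c in (-3.5, 2.0, 3.5, 1.2)]
        )
        zs = simulate_zspectrum(schedule, pools, 0.0)
        for dw in (0.0, 1.2, 3.5):
            assert mtr_asym(zs, dw) == pytest.approx(0.0, abs=1e-12)

    def test_reference_minus_label(self, schedule):
        z = np.ones(len(schedule))
        z[schedule.index_of(-1.0)] = 0.60
        z[schedule.index_of(1.0)] = 0.55
        assert mtr_asym(ZSpectrum(schedule, z), 1.0) == pytest.approx(0.05)

    def test_out_of_range(self, schedule, default_pools):
        zs = simulate_zspectrum(schedule, default_pools, 0.0)
        with pytest.raises(OffsetRangeError):
            mtr_asym(zs, 25.0)


class TestLorentzianDifference:
    def _fit(self, schedule, pools, mt, rel_b1=1.0):
        zs = simulate_zspectrum(schedule, pools, mt)
        return fit_multipool(zs, b0_init=pools.water.center, rel_b1=rel_b1)

    def test_zero_solutes_gives_zero_ld(self, schedule):
        pools = PoolParams(
            Pool(0.85, 1.4, 0.0), Pool(0.08, 3.0, -3.5),
            *[Pool(0.0, 1.0, c) for c in (2.0, 3.5, 1.2)]
        )
        fit = self._fit(schedule, pools, 0.05)
        ld = lorentzian_difference(fit, b1_correction_mode="none")
        assert np.abs(ld.ld).max() < 1e-6

    def test_ld_is_solute_sum(self, schedule, default_pools):
        fit = self._fit(schedule, default_pools, 0.05)
        ld = lorentzian_difference(fit, b1_correction_mode="none")
        expected = sum(
            lorentzian(ld.eval_grid_ppm, p.amplitude, p.fwhm,
                       p.center - fit.recentering_shift_ppm)
            for p in fit.pools.solutes
        )
        assert np.allclose(ld.ld, expected)

    def test_modes_identical_at_unit_b1(self, schedule, default_pools):
        fit = self._fit(schedule, default_pools, 0.05, rel_b1=1.0)
        curves = [
            lorentzian_difference(fit, b1_correction_mode=m).ld
            for m in ("none", "multiply", "divide")
        ]
        assert np.allclose(curves[0], curves[1])
        assert np.allclose(curves[0], curves[2])

    def test_b1_modes_scale_as_documented(self, schedule, default_pools):
        fit = self._fit(schedule, default_pools, 0.05, rel_b1=0.9)
        base = lorentzian_difference(fit, b1_correction_mode="none").ld
        mul = lorentzian_difference(fit, b1_correction_mode="multiply").ld
        div = lorentzian_difference(fit, b1_correction_mode="divide").ld
        assert np.allclose(mul, base * 0.9)
        assert np.allclose(div, base / 0.9)

    def test_mt_invariance(self, schedule, default_pools):
        """LD (mode none) does not change with the MT level: MT cancels in
        Z_ref - Z_lab."""
        ld_lo = lorentzian_difference(
            self._fit(schedule, default_pools, 0.02), b1_correction_mode="none").ld
        ld_hi = lorentzian_difference(
            self._fit(schedule, default_pools, 0.12), b1_correction_mode="none").ld
        assert np.allclose(ld_lo, ld_hi, atol=1e-6)

    def test_hydroxyl_amplitude_monotonicity(self, schedule, default_pools):
        """Raising only the hydroxyl amplitude strictly raises LD at 1.2 ppm."""
        import dataclasses
        vals = []
        for a_oh in (0.01, 0.02, 0.04):
            pools = dataclasses.replace(
                default_pools,
                hydroxyl=Pool(a_oh, 1.0, 1.2),
            )
            fit = self._fit(schedule, pools, 0.05)
            ld = lorentzian_difference(fit, b1_correction_mode="none")
            vals.append(np.interp(1.2, ld.eval_grid_ppm, ld.ld))
        assert vals[0] < vals[1] < vals[2]
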