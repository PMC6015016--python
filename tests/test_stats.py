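"""ROI summaries, two-way ANOVA, Hochberg correction, permutation t-test."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glucocest.errors import (
    DesignError,
    EmptyROIError,
    InvalidPValueError,
    UnbalancedDesignError,
)
from glucocest.stats import (
    anova_all_rois,
    anova_genotype_time,
    hochberg,
    perm_ttest,
    roi_stats,
)


class TestRoiStats:
    LABELS = np.array([[1, 1, 1], [2, 2, 0]])

    def test_uniform(self):
        img = np.full((2, 3), 0.2)
        mean, sem, n = roi_stats(img, self.LABELS, 1)
        assert mean == pytest.approx(0.2)
        assert sem == pytest.approx(0.0, abs=1e-12)
        assert n == 3

    def test_sem_oracle(self):
        """Values {1,2,3}: mean 2, SEM = sd/sqrt(n) = 1/sqrt(3)."""
        img = np.array([[1.0, 2.0, 3.0], [0, 0, 0]])
        mean, sem, n = roi_stats(img, self.LABELS, 1)
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(0.5774, abs=1e-4)

    def test_absent_label(self):
        with pytest.raises(EmptyROIError):
            roi_stats(np.ones((2, 3)), self.LABELS, 9)

    def test_nonfinite_excluded(self):
        img = np.array([[1.0, np.nan, 3.0], [0, 0, 0]])
        mean, _, n = roi_stats(img, self.LABELS, 1)
        assert (mean, n) == (2.0, 2)


def toy_table(jitter=1e-3):
    """Balanced 2x2 design: WT/t1 {1,1}, WT/t2 {2,2}, TG/t1 {0,0},
    TG/t2 {1,1} plus tiny jitter so variances are nonzero."""
    rows = []
    vals = {("WT", 1): 1.0, ("WT", 2): 2.0, ("TG", 1): 0.0, ("TG", 2): 1.0}
    rng = np.random.default_rng(0)
    for (geno, t), v in vals.items():
        for k in range(2):
            rows.append({
                "subject_id": f"{geno}{k}", "genotype": geno, "roi": "cortex",
                "timepoint_min": t, "gce": v + jitter * rng.standard_normal(),
            })
    return pd.DataFrame(rows)


def anova_by_hand(table):
    """Independent sums-of-squares oracle for the balanced two-way design."""
    y = table["gce"].to_numpy()
    g = table["genotype"].to_numpy()
    t = table["timepoint_min"].to_numpy()
    grand = y.mean()
    genos, times = np.unique(g), np.unique(t)
    n_cell = len(y) / (len(genos) * len(times))
    ss_a = sum((y[g == gi].mean() - grand) ** 2 * (g == gi).sum() for gi in genos)
    ss_b = sum((y[t == ti].mean() - grand) ** 2 * (t == ti).sum() for ti in times)
    ss_cells = sum(
        (y[(g == gi) & (t == ti)].mean() - grand) ** 2 * n_cell
        for gi in genos for ti in times
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((y[(g == gi) & (t == ti)] - y[(g == gi) & (t == ti)].mean()) ** 2).sum()
        for gi in genos for ti in times
    )
    df_a, df_b = len(genos) - 1, len(times) - 1
    df_ab = df_a * df_b
    df_err = len(y) - len(genos) * len(times)
    return {
        "genotype": (ss_a / df_a) / (ss_err / df_err),
        "time": (ss_b / df_b) / (ss_err / df_err),
        "genotype_x_time": (ss_ab / df_ab) / (ss_err / df_err),
    }


class TestAnova:
    def test_matches_hand_sums_of_squares(self):
        table = toy_table()
        res = anova_genotype_time(table, "cortex")
        hand = anova_by_hand(table)
        for eff in ("genotype", "time", "genotype_x_time"):
            assert res.f[eff] == pytest.approx(hand[eff], rel=1e-4)
        assert res.f["genotype"] > 1e4 and res.f["time"] > 1e4
        assert res.f["genotype_x_time"] < 10.0   # no interaction by design

    def test_single_timepoint_rejected(self):
        table = toy_table()
        with pytest.raises(UnbalancedDesignError):
            anova_genotype_time(table[table["timepoint_min"] == 1], "cortex")

    def test_missing_cell_rejected(self):
        table = toy_table()
        table = table[~((table["genotype"] == "TG") & (table["timepoint_min"] == 2))]
        with pytest.raises(UnbalancedDesignError):
            anova_genotype_time(table, "cortex")

    def test_type_i_error_calibrated(self):
        """Null responses (pure noise): each effect rejects at about the
        nominal 5% level (spot check at 200 replicates; the full 500-replicate
        calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(5)
        rej = {"genotype": 0, "time": 0, "genotype_x_time": 0}
        n_rep = 200
        for _ in range(n_rep):
            rows = [
                {"subject_id": f"{g}{k}", "genotype": g, "roi": "cortex",
                 "timepoint_min": t, "gce": rng.standard_normal()}
                for g in ("WT", "TG") for k in range(7) for t in (14, 22, 30)
            ]
            res = anova_genotype_time(pd.DataFrame(rows), "cortex")
            for eff in rej:
                rej[eff] += res.p[eff] < 0.05
        for eff, n in rej.items():
            assert 0.02 <= n / n_rep <= 0.09, (eff, n / n_rep)


class TestHochberg:
    def test_step_up_oracle(self):
        assert np.allclose(hochberg([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])
        assert np.allclose(hochberg([0.05, 0.05, 0.05]), [0.05, 0.05, 0.05])
        assert hochberg([0.03]) == pytest.approx([0.03])

    def test_invalid_p(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(InvalidPValueError):
                hochberg(bad)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_monotone_and_bounded(self, pvals):
        adj = hochberg(pvals)
        assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_family_is_rois_per_effect(self):
        table = pd.concat([toy_table().assign(roi=r) for r in ("cortex", "thalamus")])
        results = anova_all_rois(table, ["cortex", "thalamus"])
        for r in results:
            for eff in r.p:
                assert r.p_adjusted[eff] >= r.p[eff] - 1e-15


class TestPermTTest:
    def test_identical_constant_groups(self):
        maps = np.ones((3, 4, 4))
        res = perm_ttest(maps, maps.copy(), n_perm=200, seed=0)
        assert np.all(res.t[np.isfinite(res.t)] == 0.0)
        assert np.all(res.p[np.isfinite(res.p)] == 1.0)
        assert res.degenerate.all()

    def test_strong_separation_exhaustive_minimum_p(self):
        """Groups 10 pooled SDs apart, 7 vs 7: exhaustive enumeration gives
        p = 1/C(14,7) at every voxel."""
        rng = np.random.default_rng(1)
        a = 10.0 + 0.1 * rng.standard_normal((7, 5, 5))
        b = 0.1 * rng.standard_normal((7, 5, 5))
        res = perm_ttest(a, b, n_perm=5000, seed=0)
        assert res.exhaustive and res.n_perm == comb(14, 7)
        assert np.allclose(res.p, 1.0 / comb(14, 7))

    def test_label_swap_symmetry(self):
        """Swapping the groups mirrors the one-sided p value through the
        permutation distribution (p_A>B + p_B>A = 1 + p_tie mass)."""
        rng = np.random.default_rng(2)
        a = rng.standard_normal((4, 3, 3)) + 0.5
        b = rng.standard_normal((4, 3, 3))
        res_ab = perm_ttest(a, b, n_perm=5000, seed=0)
        res_ba = perm_ttest(b, a, n_perm=5000, seed=0)
        total = comb(8, 4)
        # exhaustive and continuous data: ties only at the observed labeling
        assert np.allclose(res_ab.p + res_ba.p, 1.0 + 1.0 / total, atol=1e-9)

    def test_seed_reproducibility_random_mode(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((10, 4, 4)) + 0.3
        b = rng.standard_normal((10, 4, 4))
        r1 = perm_ttest(a, b, n_perm=500, seed=42)
        r2 = perm_ttest(a, b, n_perm=500, seed=42)
        assert np.array_equal(r1.p, r2.p)
        assert not r1.exhaustive

    def test_too_few_maps(self):
        with pytest.raises(DesignError):
            perm_ttest(np.ones((2, 3, 3)), np.ones((3, 3, 3)))

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((3, 2, 2)), rng.standard_normal((3, 2, 2))
        with pytest.warns(UserWarning, match="n_perm"):
            perm_ttest(a, b, n_perm=50, seed=0)

    def test_null_false_positive_rate(self):
        """Same-distribution groups: about alpha of the voxels reach
        p < alpha."""
        rng = np.random.default_rng(6)
        a = rng.standard_normal((7, 20, 20))
        b = rng.standard_normal((7, 20, 20))
        res = perm_ttest(a, b, n_perm=5000, seed=0)
        frac = float(np.mean(res.p[np.isfinite(res.p)] < 0.05))
        assert 0.02 <= frac <= 0.09

    def test_max_t_fwe_is_conservative(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((5, 6, 6))
        b = rng.standard_normal((5, 6, 6))
        res = perm_ttest(a, b, n_perm=252, seed=0, max_t_correction=True)
        ok = np.isfinite(res.p)
        assert np.all(res.p_fwe[ok] >= res.p[ok] - 1e-12)
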