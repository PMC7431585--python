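"""Statistical toolbox: hand-computed examples, enumeration oracles, calibration."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats

import alphalat.stats as als
from alphalat.stats import (
    ali_followup,
    bf_ttest,
    fdr_bh,
    friedman,
    hedges_g,
    hedges_g1,
    lilliefors,
    mark_errors,
    one_sample_t,
    paired_t,
    rm_anova_1way,
    wilcoxon_signed_rank,
)


class TestTTests:
    def test_identical_samples(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p == 1.0 and r.effect_size == 0.0

    def test_hand_computed_paired_t(self):
        r = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert r.statistic == pytest.approx(3.4641, abs=1e-4)
        assert r.df == 2

    def test_hand_computed_one_sample_t(self):
        r = one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert r.statistic == pytest.approx(3.4641, abs=1e-4)

    def test_symmetric_sample_mean_zero(self):
        r = one_sample_t([-2.0, -1.0, 1.0, 2.0], 0.0)
        assert r.statistic == 0.0

    def test_zero_variance_nonzero_mean_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(400):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0, 1, 12)
            ps.append(paired_t(x, y, with_bf=False).p)
        # uniformity of p under H0: KS against U(0,1)
        stat = sp_stats.kstest(ps, "uniform").pvalue
        assert stat > 0.01
        assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.03)


class TestHedges:
    def test_hand_computed_g(self):
        # diffs (1,2,3): d = 2, J = 1 - 3/7, g = 2 * 4/7 = 1.1429
        assert hedges_g([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]) == pytest.approx(1.1429, abs=1e-4)

    def test_zero_mean_difference(self):
        assert hedges_g([1.0, -1.0, 0.5, -0.5], [0.0, 0.0, 0.0, 0.0]) == pytest.approx(0.0)

    def test_correction_vanishes_asymptotically(self, rng):
        x = rng.normal(1.0, 1.0, 5000)
        d = x.mean() / x.std(ddof=1)
        assert hedges_g1(x) == pytest.approx(d, rel=1e-3)


def _exact_wilcoxon_p(d):
    """Enumerate all sign patterns for the exact two-sided signed-rank p."""
    d = np.asarray(d, float)
    ranks = sp_stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = np.array([
        np.sum(np.array(signs) * ranks) for signs in product([0, 1], repeat=len(d))
    ])
    p_lo = np.mean(dist <= w_obs)
    p_hi = np.mean(dist >= w_obs)
    return min(1.0, 2 * min(p_lo, p_hi))


class TestWilcoxon:
    def test_all_positive_small_sample(self):
        # diffs (1,2,3): W- = 0, exact two-tailed p = 2/8
        r = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p == pytest.approx(0.25)
        assert r.extra["method"] == "exact"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, 9)
        r = wilcoxon_signed_rank(d)
        assert r.p == pytest.approx(_exact_wilcoxon_p(d), abs=1e-12)

    def test_antisymmetric_differences_centered(self):
        r = wilcoxon_signed_rank([-3.0, -2.0, -1.0, 1.0, 2.0, 3.5])
        assert r.p > 0.5

    def test_normal_approximation_close_to_exact(self, rng):
        d = rng.normal(0.4, 1.0, 18)
        exact = _exact_wilcoxon_p(d)
        approx = sp_stats.wilcoxon(d, alternative="two-sided", method="approx",
                                   correction=True).pvalue
        assert approx == pytest.approx(exact, abs=0.01)

    def test_ties_fall_back_to_approximation(self):
        r = wilcoxon_signed_rank([1.0, 1.0, 2.0, 3.0, -1.0])
        assert r.extra["method"] == "approx"


class TestRmAnova:
    def test_two_levels_epsilon_exactly_one(self, rng):
        data = rng.normal(0, 1, (10, 2))
        r = rm_anova_1way(data)
        assert r.extra["gg_epsilon"] == 1.0
        assert not r.extra["gg_applied"]

    def test_flat_profiles_give_zero_f(self, rng):
        subj = rng.normal(0, 1, 8)
        data = np.tile(subj[:, None], (1, 3))   # per-subject flat across levels
        r = rm_anova_1way(data)
        assert r.statistic == pytest.approx(0.0, abs=1e-10)
        assert r.effect_size == pytest.approx(0.0, abs=1e-10)

    def test_compound_symmetry_epsilon_near_one(self, rng):
        subj = rng.normal(0, 2, (120, 1))
        data = subj + rng.normal(0, 1, (120, 4))
        r = rm_anova_1way(data)
        assert r.extra["gg_epsilon"] > 0.9

    def test_df_and_effect_detection(self, rng):
        data = rng.normal(0, 1, (15, 3)) + np.array([0.0, 1.5, 0.5])
        r = rm_anova_1way(data)
        assert r.p < 0.01
        if not r.extra["gg_applied"]:
            assert r.df == (2.0, 28.0)
        assert 0 < r.effect_size < 1

    def test_missing_cells_rejected(self):
        data = np.ones((5, 3))
        data[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_1way(data)


class TestFriedman:
    def test_identical_orderings_hand_computed(self):
        # ranks 1,2,3 for every subject: chi2 = 12/(3*3*4)*(9+36+81) - 3*3*4 = 6
        data = np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0], [2.0, 5.0, 9.0]])
        r = friedman(data)
        assert r.statistic == pytest.approx(6.0)
        assert r.df == 2

    def test_constant_data(self):
        r = friedman(np.ones((4, 3)))
        assert r.statistic == 0.0 and r.p == 1.0

    def test_null_tail_matches_chi_square(self, rng):
        stats = [friedman(rng.normal(0, 1, (12, 3))).statistic for _ in range(300)]
        frac = np.mean(np.array(stats) > sp_stats.chi2.ppf(0.95, 2))
        assert frac == pytest.approx(0.05, abs=0.035)


class TestFDR:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_unchanged(self):
        assert fdr_bh([0.42])[0] == pytest.approx(0.42)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0.001, 1.0, int(rng.integers(2, 12)))
            mine = fdr_bh(p)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(np.minimum(mine, 1.0), ref, atol=1e-12)

    def test_two_large_ps(self):
        # classic step-up: min over j>=i of p(j) m/j -> both 0.9
        np.testing.assert_allclose(fdr_bh([0.9, 0.8]), [0.9, 0.9])

    def test_dependence_correction_exceeds_one_uncapped(self):
        adj = fdr_bh([0.9, 0.8], method="dep")
        assert adj.max() > 1.0   # reported as-is, not clipped

    @given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None, derandomize=True, database=None)
    def test_adjusted_at_least_raw_and_order_invariant(self, ps):
        p = np.array(ps)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-12)
        perm = np.argsort(p)
        np.testing.assert_allclose(fdr_bh(p[perm]), adj[perm], atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])


def _jzs_g_integral_oracle(t, n, scale):
    """Independent JZS form: integrate over the variance-scale mixture g."""
    from scipy.integrate import quad

    nu = n - 1

    def integrand(g):
        return (
            (1 + n * g * scale**2) ** -0.5
            * (1 + t**2 / ((1 + n * g * scale**2) * nu)) ** (-(nu + 1) / 2)
            * (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1 / (2 * g))
        )

    num, _ = quad(integrand, 0, np.inf, limit=200)
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return num / den


class TestBayesFactor:
    def test_null_t_favors_null(self):
        for n in (2, 5, 20, 50):
            assert bf_ttest(0.0, n) < 1.0

    def test_monotone_in_t(self):
        bfs = [bf_ttest(t, 15) for t in (0.0, 1.0, 2.0, 3.0, 5.0)]
        assert np.all(np.diff(bfs) > 0)

    @pytest.mark.parametrize("t,n", [(3.4641, 3), (2.0, 10), (0.5, 25), (4.5, 20)])
    def test_matches_g_integral_oracle(self, t, n):
        assert bf_ttest(t, n) == pytest.approx(
            _jzs_g_integral_oracle(t, n, als.JZS_DEFAULT_SCALE), rel=1e-4
        )

    def test_matches_pingouin(self):
        import pingouin as pg

        # pingouin's own quadrature carries ~1e-4 relative error, so the
        # cross-implementation agreement bound is looser than the oracle's
        for t, n in ((2.5, 12), (1.0, 30), (3.8, 20)):
            ref = float(pg.bayesfactor_ttest(t, n, paired=True))
            assert bf_ttest(t, n) == pytest.approx(ref, rel=1e-3)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            bf_ttest(1.0, 1)


class TestLilliefors:
    def test_gaussian_rarely_rejected(self, rng):
        hits = sum(lilliefors(rng.normal(0, 1, 300)).p > 0.05 for _ in range(200))
        assert hits / 200 >= 0.90

    def test_bimodal_rejected(self, rng):
        x = np.concatenate([rng.normal(-5, 0.3, 50), rng.normal(5, 0.3, 50)])
        assert lilliefors(x).p < 0.05

    def test_statistic_affine_invariant(self, rng):
        x = rng.normal(3, 2, 80)
        a = lilliefors(x).statistic
        b = lilliefors(5.0 * x - 11.0).statistic
        assert a == pytest.approx(b, abs=1e-12)


class TestScriptedAnalyses:
    def test_mark_errors_flags_late_premature_missing(self):
        t = pd.DataFrame({
            "response": ["yes", "yes", "none", "yes"],
            "rt_ms": [500.0, 150.0, np.nan, 2500.0],
            "correct": [True, True, True, True],
        })
        out = mark_errors(t)
        assert out["correct"].tolist() == [True, False, False, False]

    def test_ali_followup_null_input(self):
        wm = pd.DataFrame({
            "target_lateral": np.zeros(6),
            "distractor_lateral": np.zeros(6),
            "neutral": np.zeros(6),
        })
        res = ali_followup(wm)
        assert len(res) == 5
        for r in res.values():
            assert r.statistic == 0.0 and r.p == 1.0
            assert r.p_adj >= r.p

    def test_ali_followup_family_of_five(self, rng):
        wm = pd.DataFrame({
            "target_lateral": rng.normal(0.1, 0.05, 10),
            "distractor_lateral": rng.normal(-0.1, 0.05, 10),
            "neutral": rng.normal(0.0, 0.05, 10),
        })
        res = ali_followup(wm)
        assert sorted(r.family for r in res.values()) == ["ali"] * 5
        for r in res.values():
            assert r.p_adj >= r.p
            assert r.bf is not None and r.bf > 0

    def test_neutral_trials_never_reach_noncued_cell(self):
        import alphalat as al
        from alphalat.simulate import SimParams, simulate_behavior

        params = SimParams(n_trials=64, lapse_rate=0.0, seed=0)
        tables = []
        for s in range(4):
            d = al.generate_design(64, seed=s)
            tables.append(simulate_behavior(d, params, rng=np.random.default_rng(s)))
        cells = als._subject_cells(tables[0])
        # the probe-type cells are computed from selective trials only
        neutral_rt = tables[0].query("retrocue == 'neutral'")["rt_ms"]
        assert "rt_noncued" in cells
        res = als.behavioral_analysis(tables)
        assert {"rt_cue_type", "acc_cue_type", "rt_probe_type", "acc_probe_type"} <= set(res)
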