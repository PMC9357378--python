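import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from organoidmorph import robust_stats as rs
from organoidmorph.errors import ConfigurationError, InsufficientDataError, InvalidParameterError


class TestRoutClean:
    def test_gross_outlier_flagged(self):
        res = rs.rout_clean([1.0, 1.1, 0.9, 1.05, 0.95, 100.0], q=0.01)
        assert res.outlier_flags.tolist() == [False] * 5 + [True]
        np.testing.assert_array_equal(res.cleaned, [1.0, 1.1, 0.9, 1.05, 0.95])

    def test_identical_values_no_flags(self):
        res = rs.rout_clean([5.0] * 10, q=0.01)
        assert res.n_outliers == 0
        assert res.rsdr == 0.0

    def test_q_zero_disables_flagging(self):
        res = rs.rout_clean([1.0, 2.0, 300.0], q=0)
        assert res.n_outliers == 0

    def test_too_few_values_raises(self):
        with pytest.raises(InsufficientDataError):
            rs.rout_clean([1.0, 2.0], q=0.01)

    def test_invalid_q_raises(self):
        with pytest.raises(InvalidParameterError):
            rs.rout_clean([1.0, 2.0, 3.0], q=0.7)

    def test_false_flag_rate_near_target(self):
        # clean Gaussian data: flagged-point rate should stay close to Q
        flagged = total = 0
        for seed in range(200):
            x = np.random.default_rng(seed).standard_normal(50)
            flagged += rs.rout_clean(x, 0.01).n_outliers
            total += 50
        assert flagged / total <= 0.015

    def test_power_on_planted_8_sigma_outliers(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            x = rng.standard_normal(50)
            x[0] += 8.0
            x[1] -= 8.0
            flags = rs.rout_clean(x, 0.01).outlier_flags
            hits += bool(flags[0] and flags[1])
        assert hits / n_seeds >= 0.99

    def test_robust_center_ignores_outlier(self):
        res = rs.rout_clean([10.0, 10.2, 9.8, 10.1, 9.9, 500.0], q=0.01)
        assert res.robust_center == pytest.approx(10.0, abs=0.2)


class TestOnewayAnova:
    def test_hand_sum_of_squares_example(self):
        # SSB = 6, SSW = 6, df = (2, 6) -> F = (6/2)/(6/6) = 3.0
        res = rs.oneway_anova({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert res.f_statistic == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_groups_give_zero_f(self):
        res = rs.oneway_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f_statistic == pytest.approx(0.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 9)
        res = rs.oneway_anova({"a": a, "b": b})
        t, p = sps.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_anova == pytest.approx(p, rel=1e-10)

    def test_agrees_with_scipy_f_oneway(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.3, 1, 8) for i in range(4)}
        res = rs.oneway_anova(groups)
        f, p = sps.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(f, rel=1e-10)
        assert res.p_anova == pytest.approx(p, rel=1e-10)

    def test_small_group_raises(self):
        with pytest.raises(InsufficientDataError):
            rs.oneway_anova({"a": [1.0], "b": [1, 2]})

    def test_type_one_error_calibrated(self):
        rej = 0
        n_sims = 2000
        for seed in range(n_sims):
            r = np.random.default_rng(seed)
            groups = {f"g{i}": r.normal(0, 1, 10) for i in range(4)}
            rej += rs.oneway_anova(groups).p_anova < 0.05
        assert rej / n_sims == pytest.approx(0.05, abs=0.015)


class TestDunnett:
    def test_single_treatment_reduces_to_t_test(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.6, 1, 8)
        res = rs.dunnett_posthoc({"Control": a, "T": b}, "Control", n_draws=400_000, seed=3)
        _, p = sps.ttest_ind(b, a)
        assert res.comparisons[0].p_adjusted == pytest.approx(p, abs=1e-3)

    def test_duplicated_treatments_get_identical_p(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 10)
        res = rs.dunnett_posthoc(
            {"Control": a, "T1": b, "T2": b.copy()}, "Control", n_draws=50_000, seed=7
        )
        ps = [c.p_adjusted for c in res.comparisons]
        assert ps[0] == pytest.approx(ps[1], abs=1e-12)

    def test_adjusted_p_at_least_unadjusted(self, rng):
        groups = {"Control": rng.normal(0, 1, 9), "T1": rng.normal(0.5, 1, 7),
                  "T2": rng.normal(1.0, 1, 11), "T3": rng.normal(0, 1, 9)}
        res = rs.dunnett_posthoc(groups, "Control", n_draws=100_000, seed=11)
        for c in res.comparisons:
            assert c.p_adjusted >= c.p_unadjusted - 2e-3  # MC slack
            assert 0 <= c.p_adjusted <= 1

    def test_agrees_with_scipy_dunnett(self, rng):
        g = {"Control": rng.normal(0, 1, 10), "T1": rng.normal(0.8, 1, 10),
             "T2": rng.normal(0, 1, 7)}
        mine = rs.dunnett_posthoc(g, "Control", n_draws=300_000, seed=5)
        ref = sps.dunnett(g["T1"], g["T2"], control=g["Control"])
        for c, p_ref in zip(mine.comparisons, ref.pvalue):
            assert c.p_adjusted == pytest.approx(p_ref, abs=5e-3)

    def test_missing_control_raises(self):
        with pytest.raises(ConfigurationError):
            rs.dunnett_posthoc({"a": [1, 2, 3], "b": [2, 3, 4]}, "Control")

    def test_same_seed_reproduces(self, rng):
        g = {"Control": rng.normal(0, 1, 6), "T": rng.normal(0.4, 1, 6)}
        r1 = rs.dunnett_posthoc(g, "Control", n_draws=10_000, seed=42)
        r2 = rs.dunnett_posthoc(g, "Control", n_draws=10_000, seed=42)
        assert r1.comparisons[0].p_adjusted == r2.comparisons[0].p_adjusted


class TestFishersLSD:
    def test_two_groups_equal_pooled_t_test(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
        res = rs.fishers_lsd({"a": a, "b": b})
        _, p = sps.ttest_ind(a, b)
        assert res.comparisons[0].p_unadjusted == pytest.approx(p, rel=1e-10)

    def test_identical_pair_gives_p_one(self):
        res = rs.fishers_lsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.comparisons[0].t == 0.0
        assert res.comparisons[0].p_unadjusted == 1.0

    def test_t_matches_hand_formula(self):
        groups = {"a": [10.0, 12.0], "b": [20.0, 22.0], "c": [15.0, 17.0]}
        res = rs.fishers_lsd(groups)
        # MS_within = pooled within variance: each group has var 2 -> MS = 2, df = 3
        comp = {(c.group, c.other): c for c in res.comparisons}
        t_ab = (11.0 - 21.0) / np.sqrt(2.0 * (0.5 + 0.5))
        assert comp[("a", "b")].t == pytest.approx(t_ab)

    def test_control_mode_limits_contrasts(self, rng):
        groups = {"Control": rng.normal(0, 1, 5), "T1": rng.normal(0, 1, 5),
                  "T2": rng.normal(0, 1, 5)}
        res = rs.fishers_lsd(groups, control="Control")
        assert {c.group for c in res.comparisons} == {"T1", "T2"}


class TestBHFDR:
    def test_single_small_p_flagged(self):
        flags, _ = rs.bh_fdr([0.004], q=0.01)
        assert flags.tolist() == [True]

    def test_hand_bh_example(self):
        # sorted p vs (i/m)q at q=0.05: 0.001<0.0125, 0.011<0.025, 0.02<0.0375, 0.8>0.05
        flags, qvals = rs.bh_fdr([0.001, 0.011, 0.02, 0.8], q=0.05)
        assert flags.tolist() == [True, True, True, False]
        assert qvals[0] == pytest.approx(0.004)

    def test_all_ones_unflagged(self):
        flags, _ = rs.bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not flags.any()

    def test_invalid_p_raises(self):
        with pytest.raises(InvalidParameterError):
            rs.bh_fdr([0.5, 1.5], q=0.05)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ps=st.lists(st.floats(0, 1), min_size=1, max_size=20),
        q1=st.floats(0.01, 0.2),
        q2=st.floats(0.2, 0.5),
    )
    def test_raising_q_never_unflags(self, ps, q1, q2):
        f_low, _ = rs.bh_fdr(ps, q=q1)
        f_high, _ = rs.bh_fdr(ps, q=q2)
        assert np.all(f_high[f_low])


class TestTwowayAnova:
    def test_additive_effects_detected(self, rng):
        a = np.repeat(["x", "y"], 20)
        b = np.tile(np.repeat(["u", "v"], 10), 2)
        y = rng.normal(0, 1, 40) + (a == "y") * 2.0
        out = rs.twoway_anova(y, a, b)
        assert out["a"]["p"] < 1e-4
        assert out["b"]["p"] > 0.001
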