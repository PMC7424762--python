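"""Tests for performance index, Kaplan-Meier, log-rank, permutation and ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from synapseflux.errors import DegenerateTestError, ParameterError
from synapseflux.stats import (
    ClimbingCounts,
    SurvivalRecord,
    kaplan_meier,
    logrank_test,
    one_way_anova,
    performance_index,
    permutation_interaction_test,
    permutation_pi_test,
)

from _oracles import brute_force_anova_f, brute_force_km, brute_force_logrank


def _records(days, events, genotype="g", induction="RU0"):
    return [
        SurvivalRecord(f"{genotype}{i}", genotype, induction, float(d), not bool(e))
        for i, (d, e) in enumerate(zip(days, events))
    ]


class TestPerformanceIndex:
    @pytest.mark.parametrize(
        "counts, expected",
        [((10, 0, 0), 1.0), ((0, 10, 0), 0.5), ((0, 0, 10), 0.0), ((6, 3, 1), 0.75)],
    )
    def test_boundary_and_mixed_values(self, counts, expected):
        pi = performance_index(ClimbingCounts(*counts))
        assert pi.value == pytest.approx(expected)

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 7)
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_bounds(self, t, m, b, k):
        if t + m + b == 0:
            t = 1
        pi1 = performance_index(ClimbingCounts(t, m, b)).value
        pik = performance_index(ClimbingCounts(k * t, k * m, k * b)).value
        assert pi1 == pytest.approx(pik)
        assert 0.0 <= pi1 <= 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ParameterError):
            performance_index(ClimbingCounts(0, 0, 0))


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = kaplan_meier(_records([2, 5], [1, 1]))
        times = dict(zip(km["time"], km["survival"]))
        assert times[0.0] == 1.0
        assert times[2.0] == pytest.approx(0.5)
        assert times[5.0] == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        km = kaplan_meier(_records([3, 4, 5], [0, 0, 0]))
        assert (km["survival"] == 1.0).all()

    def test_duplicating_cohort_leaves_curve_unchanged(self):
        recs = _records([2, 3, 3, 7, 9], [1, 1, 0, 1, 1])
        km1 = kaplan_meier(recs)
        km2 = kaplan_meier(recs + _records([2, 3, 3, 7, 9], [1, 1, 0, 1, 1], genotype="h"))
        np.testing.assert_allclose(km1["survival"], km2["survival"])

    def test_monotone_and_matches_hand_oracle(self):
        rng = np.random.default_rng(7)
        days = rng.integers(1, 15, 40).astype(float)
        events = rng.random(40) < 0.8
        km = kaplan_meier(_records(days, events))
        surv = km["survival"].to_numpy()
        assert (np.diff(surv) <= 1e-12).all()
        assert surv[0] == 1.0
        oracle = dict(brute_force_km(days, events))
        got = dict(zip(km["time"], km["survival"]))
        for t, s in oracle.items():
            assert got[t] == pytest.approx(s, abs=1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        days = rng.integers(1, 20, 60).astype(float)
        events = rng.random(60) < 0.7
        km = kaplan_meier(_records(days, events))
        kmf = lifelines.KaplanMeierFitter().fit(days, events)
        for t, s in zip(km["time"], km["survival"]):
            assert kmf.predict(t) == pytest.approx(s, abs=1e-10)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        a = _records([1, 2, 3], [1, 1, 1])
        res = logrank_test(a, a)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_six_fly_toy_matches_hand_tabulation(self):
        days_a, ev_a = [2.0, 4.0, 6.0], [True, True, True]
        days_b, ev_b = [3.0, 5.0, 7.0], [True, True, True]
        res = logrank_test(_records(days_a, ev_a), _records(days_b, ev_b, genotype="h"))
        want = brute_force_logrank(days_a, ev_a, days_b, ev_b)
        assert res.chi_square == pytest.approx(want, abs=1e-10)
        assert res.df == 1

    def test_tied_event_days_match_hand_tabulation(self):
        days_a, ev_a = [2.0, 2.0, 5.0, 8.0], [True, True, False, True]
        days_b, ev_b = [2.0, 5.0, 5.0, 9.0], [True, True, True, False]
        res = logrank_test(_records(days_a, ev_a), _records(days_b, ev_b, genotype="h"))
        want = brute_force_logrank(days_a, ev_a, days_b, ev_b)
        assert res.chi_square == pytest.approx(want, abs=1e-10)

    def test_symmetric_in_group_order(self):
        a = _records([2, 3, 9, 11], [1, 1, 0, 1])
        b = _records([4, 5, 6, 12], [1, 0, 1, 1], genotype="h")
        assert logrank_test(a, b).chi_square == pytest.approx(
            logrank_test(b, a).chi_square, abs=1e-12
        )

    def test_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(3)
        da = rng.weibull(2, 50) * 30 + 0.5
        db = rng.weibull(2, 50) * 24 + 0.5
        ea = rng.random(50) < 0.9
        eb = rng.random(50) < 0.9
        res = logrank_test(_records(da, ea), _records(db, eb, genotype="h"))
        ll = lifelines_stats.logrank_test(da, db, event_observed_A=ea, event_observed_B=eb)
        assert res.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-9)

    def test_group_without_events_rejected(self):
        with pytest.raises(DegenerateTestError):
            logrank_test(_records([2, 3], [1, 1]), _records([4, 5], [0, 0], genotype="h"))
        with pytest.raises(ParameterError):
            logrank_test([], _records([1], [1]))


def _design(seed=0, interaction_hr=1.0, n=40, induction_hr=2.0):
    from synapseflux.synthetic import SurvivalSimParams, simulate_survival

    return simulate_survival(
        SurvivalSimParams(
            n_per_group=n,
            induction_hr=induction_hr,
            interaction_hr=interaction_hr,
            seed=seed,
        )
    )


class TestInteractionTest:
    def test_same_seed_reproducible(self):
        recs = _design(seed=5)
        r1 = permutation_interaction_test(recs, n_perm=200, seed=42)
        r2 = permutation_interaction_test(recs, n_perm=200, seed=42)
        assert r1 == r2
        assert 0.0 < r1.p_value <= 1.0

    def test_detects_strong_interaction(self):
        recs = _design(seed=2, interaction_hr=4.0, n=120)
        res = permutation_interaction_test(recs, n_perm=300, seed=9)
        assert res.p_value < 0.05

    def test_agrees_with_cox_model_direction(self):
        """Cross-check: a Cox fit with a genotype x induction term finds the
        same interaction the permutation test flags."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        recs = _design(seed=4, interaction_hr=3.0, n=120)
        df = pd.DataFrame(
            {
                "day": [r.day for r in recs],
                "event": [not r.censored for r in recs],
                "geno": [int(r.genotype == "tg") for r in recs],
                "ind": [int(r.induction == "RU200") for r in recs],
            }
        )
        df["geno_x_ind"] = df["geno"] * df["ind"]
        cph = lifelines.CoxPHFitter().fit(df, duration_col="day", event_col="event")
        assert cph.summary.loc["geno_x_ind", "p"] < 0.05
        assert cph.summary.loc["geno_x_ind", "coef"] > 0  # extra hazard when both
        res = permutation_interaction_test(recs, n_perm=300, seed=10)
        assert res.p_value < 0.05
        assert res.observed_stat > 0

    def test_requires_full_design_and_seed(self):
        recs = _design(seed=1)
        with pytest.raises(ParameterError):
            permutation_interaction_test(recs, n_perm=100, seed=None)
        only_one_geno = [r for r in recs if r.genotype == "wt"]
        with pytest.raises(ParameterError):
            permutation_interaction_test(only_one_geno, n_perm=100, seed=1)

    def test_low_n_perm_warns(self):
        recs = _design(seed=3)
        with pytest.warns(UserWarning):
            permutation_interaction_test(recs, n_perm=50, seed=1)


class TestPermutationPiTest:
    def test_deterministic_and_detects_difference(self):
        strong = [ClimbingCounts(45, 4, 1, timepoint=f"t{i}") for i in range(4)]
        weak = [ClimbingCounts(5, 10, 35, timepoint=f"t{i}") for i in range(4)]
        r1 = permutation_pi_test(strong, weak, n_perm=200, seed=1)
        r2 = permutation_pi_test(strong, weak, n_perm=200, seed=1)
        assert r1 == r2
        assert r1.p_value < 0.01
        assert r1.observed_stat > 0.5

    def test_null_is_not_significant_typically(self):
        a = [ClimbingCounts(20, 20, 10, timepoint="t0")]
        b = [ClimbingCounts(19, 22, 9, timepoint="t0")]
        res = permutation_pi_test(a, b, n_perm=200, seed=3)
        assert res.p_value > 0.05


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova({"a": [3.0, 3.0, 3.0], "b": [3.0, 3.0, 3.0]})
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_matches_sum_of_squares_oracle(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [3.0, 4.0, 5.0]]
        res = one_way_anova(groups)
        want_f, df_b, df_w = brute_force_anova_f(groups)
        assert res.f_stat == pytest.approx(want_f, abs=1e-10)
        assert (res.df_between, res.df_within) == (df_b, df_w)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 9)
        res = one_way_anova({"a": a, "b": b})
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert res.f_stat == pytest.approx(t**2, abs=1e-10)

    def test_df_structure_for_unbalanced_four_groups(self):
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.normal(i * 0.1, 1, n) for i, n in enumerate([5, 5, 4, 4])}
        res = one_way_anova(groups)
        assert (res.df_between, res.df_within) == (3, 14)

    def test_tukey_flags_the_shifted_group(self):
        rng = np.random.default_rng(2)
        groups = {
            "a": rng.normal(0, 0.1, 8),
            "b": rng.normal(0, 0.1, 8),
            "c": rng.normal(2, 0.1, 8),
        }
        res = one_way_anova(groups)
        flagged = {frozenset(pair) for pair, _, p in res.tukey_pairs if p < 0.05}
        assert flagged == {frozenset({"a", "c"}), frozenset({"b", "c"})}

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            one_way_anova({"a": [1.0], "b": [1.0, 2.0]})
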