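"""Kaplan-Meier, log-rank and Cox machinery against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from npiplus.survival import (
    ExtrapolationWarning,
    SurvivalRecord,
    bcss_encode,
    bonferroni_adjust,
    cox_fit,
    km_estimate,
    logrank_test,
    survival_at,
)


def km_oracle(durations, events):
    """Independent product-limit computation by direct tabulation."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, int)
    times = np.unique(durations[events == 1])
    surv = []
    s = 1.0
    for t in times:
        n_at_risk = int((durations >= t).sum())
        d = int(((durations == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return times, np.array(surv)


def logrank_oracle(groups):
    """Independent observed-minus-expected log-rank tabulation (2 groups)."""
    (t0, e0), (t1, e1) = groups
    all_t = np.unique(np.concatenate([t0[e0 == 1], t1[e1 == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_t:
        n0 = (t0 >= t).sum()
        n1 = (t1 >= t).sum()
        d0 = ((t0 == t) & (e0 == 1)).sum()
        d1 = ((t1 == t) & (e1 == 1)).sum()
        n = n0 + n1
        d = d0 + d1
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n0 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestEncoding:
    @pytest.mark.parametrize(
        "time,event,expected",
        [(5.0, "bc_death", (5.0, 1)), (12.3, "other_death", (12.3, 0)),
         (25.5, "alive", (25.5, 0))],
    )
    def test_bcss_censoring_rule(self, time, event, expected):
        assert bcss_encode(SurvivalRecord(time, event)) == expected

    @pytest.mark.parametrize("time", [0.0, -1.0, float("inf")])
    def test_nonpositive_time_rejected(self, time):
        with pytest.raises(ValueError):
            SurvivalRecord(time, "alive")

    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord(1.0, "lost")


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        records = [SurvivalRecord(t, "alive") for t in (1.0, 2.0, 3.0)]
        curve = km_estimate(records)
        assert curve.times.size == 0
        assert survival_at(curve, 2.5) == 1.0

    def test_single_event_among_four(self):
        records = [SurvivalRecord(2.0, "bc_death")] + [
            SurvivalRecord(t, "alive") for t in (3.0, 4.0, 5.0)
        ]
        curve = km_estimate(records)
        assert survival_at(curve, 2.0) == pytest.approx(0.75)

    def test_matches_product_oracle_on_random_data(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            durations = np.round(rng.exponential(5.0, n), 1) + 0.1
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            curve = km_estimate(durations, events)
            times, surv = km_oracle(durations, events)
            np.testing.assert_allclose(curve.times, times)
            np.testing.assert_allclose(curve.survival, surv, rtol=1e-10)
            assert np.all(np.diff(curve.survival) <= 1e-12)
            assert np.all(np.diff(curve.at_risk) < 0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            durations = rng.exponential(3.0, n) + 0.01
            curve = km_estimate(durations, np.ones(n, dtype=int))
            for t in rng.uniform(0, durations.max(), 5):
                empirical = (durations > t).mean()
                assert survival_at(curve, t) == pytest.approx(empirical, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_step_evaluation_conventions(self):
        curve = km_estimate([2.0, 4.0, 6.0, 8.0], [1, 1, 0, 0])
        assert survival_at(curve, 0.0) == 1.0
        assert survival_at(curve, 1.999) == 1.0
        assert survival_at(curve, 2.0) == pytest.approx(0.75)  # post-drop value
        with pytest.warns(ExtrapolationWarning):
            assert survival_at(curve, 100.0) == pytest.approx(0.5)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 0])
        stat, dof, p = logrank_test([(t, e), (t.copy(), e.copy())])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert dof == 1
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulation_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(25):
            n0, n1 = int(rng.integers(8, 30)), int(rng.integers(8, 30))
            g0 = (np.round(rng.exponential(5, n0), 1) + 0.1, rng.integers(0, 2, n0))
            g1 = (np.round(rng.exponential(3, n1), 1) + 0.1, rng.integers(0, 2, n1))
            if g0[1].sum() + g1[1].sum() == 0:
                continue
            stat, dof, p = logrank_test([g0, g1])
            assert stat == pytest.approx(logrank_oracle([g0, g1]), rel=1e-8)
            from scipy.stats import chi2

            assert p == pytest.approx(chi2.sf(stat, dof), rel=1e-10)

    def test_invariant_under_relabelling_and_time_rescaling(self):
        rng = np.random.default_rng(4)
        g0 = (rng.exponential(5, 30) + 0.1, rng.integers(0, 2, 30))
        g1 = (rng.exponential(2, 25) + 0.1, rng.integers(0, 2, 25))
        stat, _, _ = logrank_test([g0, g1])
        stat_swapped, _, _ = logrank_test([g1, g0])
        stat_scaled, _, _ = logrank_test([(g0[0] * 3.7, g0[1]), (g1[0] * 3.7, g1[1])])
        assert stat == pytest.approx(stat_swapped, rel=1e-10)
        assert stat == pytest.approx(stat_scaled, rel=1e-10)

    def test_all_censored_rejected(self):
        t = np.array([1.0, 2.0])
        z = np.zeros(2, dtype=int)
        with pytest.raises(ValueError, match="undefined"):
            logrank_test([(t, z), (t + 1, z)])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([(np.array([1.0]), np.array([1]))])


class TestCoxFit:
    def test_binary_covariate_with_known_hazard_ratio(self):
        rng = np.random.default_rng(12)
        n = 2000
        x = rng.integers(0, 2, n)
        t_event = rng.exponential(1.0 / (0.05 * np.exp(np.log(2) * x)))
        times = np.minimum(t_event, 25.0)
        events = (t_event <= 25.0).astype(int)
        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert fit.betas["x"] == pytest.approx(np.log(2), abs=0.1)

    def test_duplicated_rows_keep_beta_and_halve_variance(self):
        rng = np.random.default_rng(13)
        n = 300
        x = rng.normal(size=n)
        t_event = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x)))
        times = np.minimum(t_event, 20.0)
        events = (t_event <= 20.0).astype(int)
        single = cox_fit(pd.DataFrame({"x": x}), times, events)
        double = cox_fit(
            pd.DataFrame({"x": np.tile(x, 2)}), np.tile(times, 2), np.tile(events, 2)
        )
        # duplication creates ties at every event time; Efron handling
        # perturbs the estimate slightly
        assert double.betas["x"] == pytest.approx(single.betas["x"], rel=0.02)
        var_ratio = single.standard_errors["x"] ** 2 / double.standard_errors["x"] ** 2
        assert var_ratio == pytest.approx(2.0, rel=0.08)

    def test_null_covariate_beta_small(self):
        rng = np.random.default_rng(14)
        n = 1500
        noise = rng.normal(size=n)
        t_event = rng.exponential(10.0, n)
        times = np.minimum(t_event, 20.0)
        events = (t_event <= 20.0).astype(int)
        fit = cox_fit(pd.DataFrame({"noise": noise}), times, events)
        assert abs(fit.betas["noise"]) < 3 * fit.standard_errors["noise"] + 0.1

    def test_coverage_of_generating_beta(self):
        # the Wald interval beta_hat +/- 2 se should cover the truth in the
        # vast majority of replicates
        rng = np.random.default_rng(15)
        true_beta = 0.7
        hits = 0
        reps = 200
        for _ in range(reps):
            n = 150
            x = rng.normal(size=n)
            t_event = rng.exponential(1.0 / (0.1 * np.exp(true_beta * x)))
            times = np.minimum(t_event, 15.0)
            events = (t_event <= 15.0).astype(int)
            fit = cox_fit(pd.DataFrame({"x": x}), times, events)
            if abs(fit.betas["x"] - true_beta) <= 2 * fit.standard_errors["x"]:
                hits += 1
        assert hits / reps >= 0.93

    def test_constant_column_and_no_event_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, [1, 2, 3], [1, 0, 1])
        with pytest.raises(ValueError, match="events"):
            cox_fit(pd.DataFrame({"x": [0.0, 1.0, 2.0]}), [1, 2, 3], [0, 0, 0])


class TestBonferroni:
    def test_single_test_uses_raw_alpha(self):
        assert bonferroni_adjust([0.009], alpha=0.01) == [True]

    def test_family_of_five(self):
        flags = bonferroni_adjust([0.009, 0.001, 0.5, 0.0019, 0.002], alpha=0.01)
        assert flags == [False, True, False, True, False]

    def test_empty_family(self):
        assert bonferroni_adjust([]) == []

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5, 1.2])
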