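"""Survival estimators against hand-computed tables and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from prognet.survival import (
    SurvivalRecords,
    concordance_index,
    fit_cox_baseline,
    kaplan_meier,
    log_rank_test,
    survival_report,
)


def _brute_force_cindex(risk, times, events):
    conc, ties, admissible = 0, 0, 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                admissible += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    ties += 1
    return (conc + 0.5 * ties) / admissible


def _brute_force_logrank(g1, g2):
    """Independent hypergeometric-variance log-rank computation."""
    all_times = np.unique(
        np.concatenate([g1.times[g1.events == 1], g2.times[g2.events == 1]])
    )
    o_minus_e, var = 0.0, 0.0
    for t in all_times:
        n1 = np.sum(g1.times >= t)
        n2 = np.sum(g2.times >= t)
        d1 = np.sum((g1.times == t) & (g1.events == 1))
        d2 = np.sum((g2.times == t) & (g2.events == 1))
        n, d = n1 + n2, d1 + d2
        if n < 2 or d == 0:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        o_minus_e += d1 - e1
        var += v
    return o_minus_e**2 / var


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        rec = SurvivalRecords([1.0, 2.0, 3.0], [1, 1, 1])
        km = kaplan_meier(rec)
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0],
                                   atol=1e-12)
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_all_censored_flat_at_one(self):
        rec = SurvivalRecords([5.0, 7.0], [0, 0])
        km = kaplan_meier(rec)
        assert len(km.event_times) == 0
        assert km.survival_at(100.0) == 1.0

    def test_censoring_between_events(self):
        # n=4: event t=1, censor t=2, event t=3 (+1 still at risk)
        rec = SurvivalRecords([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        km = kaplan_meier(rec)
        np.testing.assert_allclose(km.survival, [0.75, 0.375], atol=1e-12)

    def test_monotone_non_increasing_from_one(self):
        rng = np.random.default_rng(0)
        rec = SurvivalRecords(
            rng.exponential(10, 50), rng.integers(0, 2, 50)
        )
        km = kaplan_meier(rec)
        s = np.r_[1.0, km.survival]
        assert (np.diff(s) <= 1e-12).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecords([-1.0], [1])


class TestLogRank:
    def test_identical_groups(self):
        rec = SurvivalRecords([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1])
        chi2, p = log_rank_test(rec, rec)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_computation_on_toy_fixture(self):
        g1 = SurvivalRecords([1.0, 3.0, 5.0], [1, 1, 0])
        g2 = SurvivalRecords([2.0, 4.0, 6.0], [1, 0, 1])
        chi2, _ = log_rank_test(g1, g2)
        assert chi2 == pytest.approx(_brute_force_logrank(g1, g2),
                                     abs=1e-10)

    def test_strongly_separated_groups(self):
        rng = np.random.default_rng(1)
        g1 = SurvivalRecords(rng.exponential(10, 200), np.ones(200, int))
        g2 = SurvivalRecords(rng.exponential(40, 200), np.ones(200, int))
        _, p = log_rank_test(g1, g2)
        assert p < 1e-6

    def test_no_events_convention(self):
        g = SurvivalRecords([1.0, 2.0], [0, 0])
        assert log_rank_test(g, g) == (0.0, 1.0)


class TestConcordance:
    def test_anti_monotone_risk_is_perfect(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        risk = -times
        rec = SurvivalRecords(times, np.ones(4, int))
        assert concordance_index(risk, rec) == 1.0

    def test_constant_risk_is_half(self):
        rec = SurvivalRecords([1.0, 2.0, 3.0], [1, 1, 1])
        assert concordance_index(np.zeros(3), rec) == 0.5

    def test_censored_fixture_matches_brute_force(self):
        times = np.array([2.0, 4.0, 3.0, 5.0])
        events = np.array([1, 1, 0, 1])
        risk = np.array([0.9, 0.3, 0.5, 0.1])
        rec = SurvivalRecords(times, events)
        assert concordance_index(risk, rec) == pytest.approx(
            _brute_force_cindex(risk, times, events)
        )

    @given(st.integers(0, 2**31 - 1))
    def test_brute_force_oracle_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        times = np.round(rng.exponential(10, n), 1) + 0.1
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        risk = rng.choice([0.1, 0.4, 0.7], size=n)
        rec = SurvivalRecords(times, events)
        assert concordance_index(risk, rec) == pytest.approx(
            _brute_force_cindex(risk, times, events), abs=1e-12
        )

    def test_matches_lifelines_on_untied_times(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(7)
        times = rng.exponential(10, 80)  # continuous: no ties
        events = rng.integers(0, 2, 80)
        events[0] = 1
        risk = rng.standard_normal(80)
        rec = SurvivalRecords(times, events)
        assert concordance_index(risk, rec) == pytest.approx(
            float(ll_cindex(times, -risk, events)), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(5, 40)
        events = rng.integers(0, 2, 40)
        events[0] = 1
        risk = rng.standard_normal(40)
        rec = SurvivalRecords(times, events)
        a = concordance_index(risk, rec)
        b = concordance_index(np.exp(risk), rec)
        assert a == pytest.approx(b, abs=1e-12)


class TestCoxBaseline:
    def test_recovers_generating_coefficient(self):
        rng = np.random.default_rng(3)
        n, beta = 500, 0.7
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-beta * x))
        res = fit_cox_baseline(
            pd.DataFrame({"x": x}), SurvivalRecords(t, np.ones(n, int))
        )
        assert res.coefficients["x"] == pytest.approx(beta, rel=0.15)

    def test_null_feature_near_zero(self):
        rng = np.random.default_rng(4)
        n = 500
        x = rng.standard_normal(n)
        t = rng.exponential(np.ones(n))
        res = fit_cox_baseline(
            pd.DataFrame({"x": x}), SurvivalRecords(t, np.ones(n, int))
        )
        assert abs(res.coefficients["x"]) < 0.1
        assert res.concordance == pytest.approx(0.5, abs=0.05)

    def test_duplicated_column_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="rank"):
            fit_cox_baseline(
                df, SurvivalRecords(np.abs(x) + 1, np.ones(50, int))
            )


class TestSurvivalReport:
    def test_separated_groups_report(self):
        rng = np.random.default_rng(6)
        n = 200
        poor = rng.integers(0, 2, n)
        times = rng.exponential(np.where(poor == 1, 20, 120))
        rec = SurvivalRecords(times, np.ones(n, int))
        scores = np.where(poor == 1, 0.9, 0.1)
        rep = survival_report(scores, rec)
        assert rep.five_year_survival["poor"] < rep.five_year_survival["good"]
        assert rep.logrank_p < 1e-6
        assert rep.c_index > 0.6

    def test_single_predicted_group_warns(self, caplog):
        rec = SurvivalRecords([1.0, 2.0, 3.0], [1, 1, 1])
        with caplog.at_level("WARNING"):
            rep = survival_report(np.zeros(3), rec)
        assert rep.logrank_p is None
        assert list(rep.km_by_group) == ["good"]

    def test_null_scores_type_one_error(self):
        rng = np.random.default_rng(0)
        rejections, n_rep = 0, 200
        for _ in range(n_rep):
            n = 60
            times = rng.exponential(50, n)
            events = (rng.random(n) > 0.3).astype(int)
            scores = rng.random(n)
            rep = survival_report(scores, SurvivalRecords(times, events))
            if rep.logrank_p is not None and rep.logrank_p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07
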