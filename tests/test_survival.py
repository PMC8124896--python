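"""Survival kernel: product-limit estimator, median CI, log-rank test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pnetrecur.survival import km_fit, km_median_ci, logrank_test
from .oracles import logrank_permutation_p


def _stat(times, events, a_idx):
    """Two-group log-rank statistic for a given index split (test helper)."""
    mask = np.zeros(times.size, dtype=bool)
    mask[a_idx] = True
    return logrank_test(
        [(times[mask], events[mask]), (times[~mask], events[~mask])]
    ).statistic


class TestKaplanMeier:
    def test_all_events_hand_product(self):
        curve = km_fit([1, 2, 3], [True, True, True])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert list(curve.at_risk) == [3, 2, 1]

    def test_all_censored_flat_at_one(self):
        curve = km_fit([5, 7, 9], [False, False, False])
        assert curve.times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_censoring_shrinks_risk_set(self):
        # event at 1 (n=3), censored at 2, event at 3 (n=1)
        curve = km_fit([1, 2, 3], [True, False, True])
        assert curve.survival_at(1) == pytest.approx(2 / 3, abs=1e-12)
        assert curve.survival_at(3) == pytest.approx(0.0, abs=1e-12)

    def test_censored_at_event_time_stays_at_risk(self):
        # at t=2: 2 at risk, 1 event -> factor 1/2 (censored one still counted)
        curve = km_fit([2, 2], [True, False])
        assert curve.survival_at(2) == pytest.approx(0.5, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_fit([-1.0, 2.0], [True, True])

    @given(
        st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_no_censoring_matches_empirical_cdf(self, times):
        """With every observation an event, S(t) = 1 − ECDF(t) exactly."""
        curve = km_fit(times, [True] * len(times))
        arr = np.asarray(times)
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(
                np.mean(arr > t), abs=1e-12
            )


class TestMedianCI:
    def test_exponential_median_recovered(self, rng):
        lam = 0.1
        t = rng.exponential(1 / lam, 5000)
        est = km_median_ci(km_fit(t, np.ones(t.size, dtype=bool)))
        true_median = np.log(2) / lam
        assert abs(est.median - true_median) / true_median < 0.05
        assert est.lower95 <= est.median <= est.upper95

    def test_undefined_when_curve_stays_high(self):
        # 1 event among 5: S bottoms out at 0.8
        est = km_median_ci(km_fit([1, 2, 3, 4, 5], [True, False, False, False, False]))
        assert est.median is None

    def test_step_landing_exactly_on_half(self):
        # S = 0.75, 0.50, 0.25, 0 -> median at the second event time
        est = km_median_ci(km_fit([1, 2, 3, 4], [True] * 4))
        assert est.median == 2.0


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = ([1.0, 2.0, 3.0, 4.0], [True, True, False, True])
        result = logrank_test([g, g])
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_observed_equals_expected_in_total(self, recurred):
        early = [r for r in recurred if r.rfs_months <= 18]
        late = [r for r in recurred if r.rfs_months > 18]
        result = logrank_test(
            [
                ([r.prs_months for r in early], [r.prs_event for r in early]),
                ([r.prs_months for r in late], [r.prs_event for r in late]),
            ]
        )
        assert result.observed.sum() == pytest.approx(result.expected.sum(), abs=1e-9)

    def test_six_observation_hand_value(self):
        """A: events at 1, 3, censored 5; B: events at 2, 6, censored 4.

        Hand hypergeometric sums give O_A = 2, E_A = 1.4, V = 0.74, so the
        statistic is 0.36/0.74 = 18/37; the exact permutation p over all 20
        equal-size relabelings brackets the chi-square approximation.
        """
        times = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        events = np.array([True, True, False, True, False, True])
        result = logrank_test([(times[:3], events[:3]), (times[3:], events[3:])])
        assert result.statistic == pytest.approx(18 / 37, abs=1e-9)
        assert result.observed[0] == 2
        assert result.expected[0] == pytest.approx(1.4, abs=1e-12)

        p_perm = logrank_permutation_p(times, events, [0, 1, 2], _stat)
        # chi2(1) is only an approximation at n = 6; bound the gap loosely
        assert abs(result.p_value - p_perm) < 0.25

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1, 2], [False, False]), ([3], [False])])

    def test_group_order_invariance(self, rng):
        a = (rng.exponential(10, 30), rng.random(30) < 0.7)
        b = (rng.exponential(20, 25), rng.random(25) < 0.7)
        r1, r2 = logrank_test([a, b]), logrank_test([b, a])
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_time_shift_invariance(self, rng):
        t = rng.exponential(10, 40)
        e = rng.random(40) < 0.6
        base = logrank_test([(t[:20], e[:20]), (t[20:], e[20:])])
        shifted = logrank_test([(t[:20] + 7.5, e[:20]), (t[20:] + 7.5, e[20:])])
        assert base.statistic == pytest.approx(shifted.statistic, abs=1e-12)

    def test_single_event_time_matches_pearson_chi2(self):
        """With one distinct event time the log-rank statistic equals
        (N−1)/N times the Pearson chi-square of the induced 2×2 table (the
        factor is the hypergeometric variance's finite-population term)."""
        from scipy.stats import chi2_contingency

        # all at risk at t=2; events: 2/4 in A, 1/3 in B
        a = ([2, 2, 2, 2], [True, True, False, False])
        b = ([2, 2, 2], [True, False, False])
        result = logrank_test([a, b])
        table = [[2, 2], [1, 2]]
        chi2 = chi2_contingency(table, correction=False)[0]
        n = 7
        assert result.statistic == pytest.approx((n - 1) / n * chi2, abs=1e-9)

    def test_three_group_degrees_of_freedom(self, rng):
        groups = [(rng.exponential(s, 40), np.ones(40, dtype=bool)) for s in (5, 10, 20)]
        result = logrank_test(groups)
        assert result.df == 2
        assert result.p_value < 0.01

    def test_cross_check_against_lifelines(self, rng):
        """Statistic and p agree with an established survival library to 1e-6
        on 100 random small censored datasets."""
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(100):
            n1, n2 = rng.integers(5, 30, 2)
            t1, t2 = rng.exponential(10, n1), rng.exponential(14, n2)
            e1, e2 = rng.random(n1) < 0.7, rng.random(n2) < 0.7
            if not (e1.any() or e2.any()):
                continue
            mine = logrank_test([(t1, e1), (t2, e2)])
            theirs = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
            assert mine.statistic == pytest.approx(theirs.test_statistic, abs=1e-6)
            assert mine.p_value == pytest.approx(theirs.p_value, abs=1e-6)

    def test_power_under_strong_alternative(self, rng):
        """Hazard ratio 3 with 500 per arm: p < 0.001 in ≥ 99/100 replicates."""
        hits = 0
        for _ in range(100):
            t1 = rng.exponential(30, 500)
            t2 = rng.exponential(10, 500)
            cens = rng.uniform(0, 60, 1000)
            t = np.concatenate([t1, t2])
            e = t <= cens
            tt = np.minimum(t, cens)
            p = logrank_test([(tt[:500], e[:500]), (tt[500:], e[500:])]).p_value
            hits += p < 0.001
        assert hits >= 99
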