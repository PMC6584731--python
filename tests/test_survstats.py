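"""Survival kernels against independent oracles and their invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from lifelines import CoxPHFitter
from scipy import optimize

from metasurv import (KAPPA, d_index, fit_cox, km_curve, logrank_test,
                      median_split, rankits)
from metasurv._cox import DegenerateInputError, score_test_stat


# --- independent oracles ----------------------------------------------------

def breslow_neg_loglik(beta, x, time, event):
    """Plain-python Cox partial likelihood (valid when event times are unique)."""
    ll = 0.0
    for i in range(len(x)):
        if event[i] == 1:
            risk = [j for j in range(len(x)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return -ll


def logrank_by_hand(groups, time, event):
    """Sum of observed-minus-expected with hypergeometric variance."""
    O = E = V = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        O += (dying & (groups == 1)).sum()
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


FIX_TIME = np.array([5.0, 8.0, 12.0, 16.0, 23.0, 30.0])
FIX_EVENT = np.array([1, 1, 0, 1, 1, 0])
FIX_X = np.array([1.2, -0.4, 0.8, -1.1, 0.3, -0.6])


class TestFitCox:
    def test_coefficient_matches_brute_force_likelihood_maximum(self):
        coef, se, p = fit_cox(FIX_X, FIX_TIME, FIX_EVENT)
        res = optimize.minimize_scalar(
            breslow_neg_loglik, bounds=(-5, 5), method="bounded",
            args=(FIX_X, FIX_TIME, FIX_EVENT),
            options={"xatol": 1e-12})
        assert coef == pytest.approx(res.x, abs=1e-8)

    def test_matches_lifelines_with_tied_event_times(self):
        rng = np.random.default_rng(3)
        n = 60
        x = rng.standard_normal(n)
        time = np.ceil(rng.exponential(20.0 / np.exp(0.5 * x)))  # many ties
        event = rng.random(n) < 0.8
        coef, se, _ = fit_cox(x, time, event.astype(int))
        df = pd.DataFrame({"t": time, "e": event.astype(int), "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        # lifelines stops at a looser gradient tolerance than our solver
        assert coef == pytest.approx(cph.params_["x"], abs=5e-4)
        assert se == pytest.approx(cph.standard_errors_["x"], abs=5e-4)

    def test_permutation_invariance(self):
        perm = np.array([3, 0, 5, 2, 1, 4])
        a = fit_cox(FIX_X, FIX_TIME, FIX_EVENT)
        b = fit_cox(FIX_X[perm], FIX_TIME[perm], FIX_EVENT[perm])
        assert a == pytest.approx(b, abs=1e-10)

    def test_negating_covariate_negates_coefficient(self):
        coef, se, p = fit_cox(FIX_X, FIX_TIME, FIX_EVENT)
        coef_n, se_n, p_n = fit_cox(-FIX_X, FIX_TIME, FIX_EVENT)
        assert coef_n == pytest.approx(-coef, abs=1e-10)
        assert se_n == pytest.approx(se, abs=1e-10)

    @pytest.mark.parametrize("x,event", [
        (np.ones(6), FIX_EVENT),                      # constant covariate
        (FIX_X, np.array([1, 0, 0, 0, 0, 0])),        # single event
    ])
    def test_degenerate_inputs_raise(self, x, event):
        with pytest.raises(DegenerateInputError):
            fit_cox(x, FIX_TIME, event)

    def test_score_statistic_equals_logrank_for_binary_covariate(self):
        rng = np.random.default_rng(8)
        n = 40
        g = (rng.random(n) < 0.5).astype(float)
        time = rng.exponential(100.0 / np.exp(0.7 * g))  # continuous, no ties
        event = np.ones(n, dtype=int)
        chi2, _ = logrank_test(g.astype(int), time, event)
        assert score_test_stat(g, time, event) == pytest.approx(chi2, abs=1e-8)


class TestDIndex:
    def test_invariant_under_strictly_increasing_transforms(self):
        rng = np.random.default_rng(1)
        scores = rng.standard_normal(50)
        time = rng.exponential(100.0 / np.exp(scores))
        event = (rng.random(50) < 0.8).astype(int)
        a = d_index(scores, time, event)
        b = d_index(np.exp(3 * scores) + 7, time, event)
        assert (a.log_hr, a.se) == pytest.approx((b.log_hr, b.se), abs=1e-12)

    def test_negating_scores_flips_sign_keeps_se(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal(50)
        time = rng.exponential(100.0 / np.exp(scores))
        event = np.ones(50, dtype=int)
        a = d_index(scores, time, event)
        b = d_index(-scores, time, event)
        assert b.log_hr == pytest.approx(-a.log_hr, abs=1e-9)
        assert b.se == pytest.approx(a.se, abs=1e-9)

    def test_hr_consistency_and_counts(self):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal(30)
        time = rng.exponential(50, 30)
        event = (rng.random(30) < 0.7).astype(int)
        r = d_index(scores, time, event)
        assert r.hr == pytest.approx(np.exp(r.log_hr))
        assert r.n == 30 and r.n_events == event.sum() <= r.n

    def test_blom_rankits_definition(self):
        scores = np.array([10.0, 3.0, 7.0])
        from scipy.stats import norm
        expected = norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        np.testing.assert_allclose(rankits(scores), expected)


class TestKMCurve:
    def test_all_censored_gives_flat_one(self):
        c = km_curve(np.array([5.0, 9.0, 11.0]), np.array([0, 0, 0]))
        assert np.all(c.survival == 1.0)

    def test_hand_product_limit_values(self):
        c = km_curve(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        assert c(1.0) == pytest.approx(2 / 3)
        assert c(2.5) == pytest.approx(2 / 3)
        assert c(3.0) == pytest.approx(0.0)
        assert c(0.0) == pytest.approx(1.0)

    def test_no_censoring_closed_form(self):
        n = 7
        t = np.arange(1.0, n + 1)
        c = km_curve(t, np.ones(n, dtype=int))
        for k in range(1, n + 1):
            assert c(float(k)) == pytest.approx((n - k) / n)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        c = km_curve(rng.exponential(10, 40), (rng.random(40) < 0.6).astype(int))
        assert np.all(np.diff(c.survival) <= 1e-15)
        assert np.all((c.survival >= 0) & (c.survival <= 1))


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([3.0, 6.0, 9.0, 3.0, 6.0, 9.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        g = np.array([0, 0, 0, 1, 1, 1])
        chi2, p = logrank_test(g, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(10, 30)
        e = (rng.random(30) < 0.7).astype(int)
        g = (rng.random(30) < 0.5).astype(int)
        assert logrank_test(g, t, e) == pytest.approx(logrank_test(1 - g, t, e))

    def test_matches_hand_computed_o_minus_e(self):
        t = np.array([2.0, 4.0, 4.0, 6.0, 7.0, 9.0, 12.0, 15.0])
        e = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        g = np.array([1, 0, 1, 1, 0, 1, 0, 0])
        chi2, _ = logrank_test(g, t, e)
        assert chi2 == pytest.approx(logrank_by_hand(g, t, e), abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(np.zeros(4, dtype=int), np.arange(1.0, 5.0),
                         np.ones(4, dtype=int))


class TestMedianSplit:
    def test_even_split(self):
        np.testing.assert_array_equal(median_split(np.array([1.0, 2, 3, 4])),
                                      [0, 0, 1, 1])

    def test_constant_scores_warns_single_group(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = median_split(np.ones(5))
        assert labels.sum() == 0

    def test_odd_n_median_element_goes_low(self):
        labels = median_split(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(labels, [0, 0, 1])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    def test_high_group_strictly_above_low_group(self, xs):
        scores = np.array(xs)
        labels = median_split(scores)
        if labels.any() and (~labels.astype(bool)).any():
            assert scores[labels == 1].min() > scores[labels == 0].max()
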