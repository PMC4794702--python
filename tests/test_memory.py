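"""Dual-year drought regression, hierarchical partitioning and AIC."""

from itertools import permutations

import numpy as np
import pytest

import droughtwue as dw
from droughtwue.memory import _ols_r2, aic_least_squares


def brute_force_partition(y, predictors):
    """Oracle: average R^2 increments over explicit orderings of entry."""
    X = np.column_stack(predictors)
    k = X.shape[1]
    effects = np.zeros(k)
    orders = list(permutations(range(k)))
    for order in orders:
        entered = []
        r2_prev = 0.0
        for j in order:
            entered.append(j)
            r2_now = _ols_r2(np.asarray(y, float), X[:, sorted(entered)])
            effects[j] += r2_now - r2_prev
            r2_prev = r2_now
    return effects / len(orders)


class TestDualRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(21)
        d = rng.normal(0, 1, 31)
        wue = 2.0 * d[1:] - 1.0 * d[:-1] + 5.0
        reg = dw.dual_regression(np.concatenate([[0.0], wue]), d)
        assert reg["a"] == pytest.approx(2.0, abs=1e-10)
        assert reg["b"] == pytest.approx(-1.0, abs=1e-10)
        assert reg["c"] == pytest.approx(5.0, abs=1e-10)
        assert reg["r2_full"] == pytest.approx(1.0, abs=1e-12)

    def test_no_lag_dependence_gives_zero_b(self):
        rng = np.random.default_rng(22)
        d = rng.normal(0, 1, 31)
        wue = np.concatenate([[0.0], 3.0 * d[1:] + 1.0])
        reg = dw.dual_regression(wue, d)
        assert reg["b"] == pytest.approx(0.0, abs=1e-10)

    def test_collinear_predictors_rejected(self):
        d = np.ones(10)
        d[0] = 1.0  # d_cur == d_prev exactly
        with pytest.raises(ValueError, match="collinear"):
            dw.dual_regression(np.arange(10.0), d)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            dw.dual_regression(np.arange(3.0), np.arange(3.0))


class TestHierarchicalPartition:
    def test_single_predictor_gets_full_r2(self):
        rng = np.random.default_rng(23)
        x = rng.normal(0, 1, 30)
        y = 0.7 * x + rng.normal(0, 1, 30)
        effects, pct, r2 = dw.hierarchical_partition(y, [x])
        assert effects[0] == pytest.approx(r2, abs=1e-12)
        assert pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_orthogonal_predictors_closed_form(self):
        # orthonormal design, y built for marginal R^2 of exactly 0.3 and 0.2
        n = 20
        t = np.arange(n)
        x1 = np.sqrt(2.0 / n) * np.cos(2 * np.pi * (t + 0.5) / n)
        x2 = np.sqrt(2.0 / n) * np.cos(4 * np.pi * (t + 0.5) / n)
        resid = np.sqrt(2.0 / n) * np.cos(6 * np.pi * (t + 0.5) / n)
        y = np.sqrt(0.3) * x1 + np.sqrt(0.2) * x2 + np.sqrt(0.5) * resid
        effects, pct, r2 = dw.hierarchical_partition(y, [x1, x2])
        assert r2 == pytest.approx(0.5, abs=1e-10)
        np.testing.assert_allclose(effects, [0.3, 0.2], atol=1e-10)
        np.testing.assert_allclose(pct, [60.0, 40.0], atol=1e-7)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_ordering_enumeration_oracle(self, k):
        rng = np.random.default_rng(100 + k)
        for _ in range(25):
            n = 25
            X = rng.normal(0, 1, (n, k)) @ (np.eye(k) + 0.5 * rng.uniform(size=(k, k)))
            y = X @ rng.normal(0, 1, k) + rng.normal(0, 1, n)
            effects, _, r2 = dw.hierarchical_partition(y, list(X.T))
            oracle = brute_force_partition(y, list(X.T))
            np.testing.assert_allclose(effects, oracle, atol=1e-12)
            assert effects.sum() == pytest.approx(r2, abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(24)
        X = rng.normal(0, 1, (30, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(0, 1, 30)
        e123, _, _ = dw.hierarchical_partition(y, [X[:, 0], X[:, 1], X[:, 2]])
        e321, _, _ = dw.hierarchical_partition(y, [X[:, 2], X[:, 1], X[:, 0]])
        np.testing.assert_allclose(e123, e321[::-1], atol=1e-12)

    def test_zero_r2_percentages_flagged(self):
        y = np.zeros(10)
        with pytest.warns(RuntimeWarning, match="zero"):
            _, pct, _ = dw.hierarchical_partition(y, [np.arange(10.0)])
        assert np.isnan(pct).all()


class TestAic:
    def test_equal_rss_pure_parameter_penalty(self):
        aic1, aic2, improved = dw.aic_compare((10.0, 2, 30), (10.0, 3, 30))
        assert aic2 - aic1 == pytest.approx(2.0)
        assert not improved

    def test_closed_form_improvement(self):
        n = 30
        rss1 = 10.0
        rss2 = rss1 * np.exp(-6.0 / n)  # dAIC = -6 + 2 = -4
        aic1, aic2, improved = dw.aic_compare((rss1, 2, n), (rss2, 3, n))
        assert aic1 - aic2 == pytest.approx(4.0, abs=1e-10)
        assert improved

    def test_zero_rss_sentinel(self):
        with pytest.warns(RuntimeWarning, match="-inf"):
            assert aic_least_squares(0.0, 20, 2) == -np.inf

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError):
            dw.aic_compare((10.0, 2, 30), (9.0, 3, 29))


class TestDroughtMemoryRegression:
    def test_recovers_prescribed_lag_structure(self):
        rng = np.random.default_rng(25)
        w = rng.normal(0, 1, 31)
        index = w[1:]
        wue = 0.3 * w[1:] - 0.15 * w[:-1] + rng.normal(0, 0.02, 30)
        est = dw.DroughtMemoryRegression(detrended=True).fit(index, wue)
        assert est.a_ > 0 > est.b_
        assert est.improved_
        assert est.indep_current_pct_ + est.indep_previous_pct_ == pytest.approx(100.0, abs=1e-6)
        assert est.indep_current_pct_ > est.indep_previous_pct_

    def test_functional_wrapper_agrees(self):
        rng = np.random.default_rng(26)
        w = rng.normal(0, 1, 30)
        wue = 0.2 * w + rng.normal(0, 0.05, 30)
        res = dw.memory_effect(wue, w)
        est = dw.DroughtMemoryRegression().fit(w, wue)
        assert res.a == est.a_ and res.aic_two == est.aic_two_
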