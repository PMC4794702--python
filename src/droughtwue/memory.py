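"""Drought memory effect: lagged regression, hierarchical partitioning, AIC.

Current-year WUE is regressed on current- and previous-year drought,

    WUE_t = a * D_t + b * D_{t-1} + c ,

and the previous year's "memory" is quantified three ways: the sign and size
of b, the independent effect of D_{t-1} from hierarchical partitioning
(the Shapley decomposition of the full-model R^2 over predictor entry
orderings, reported as a percentage of R^2), and whether adding the lag
improves the model by more than 2 AIC units over the single-predictor fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .wue import detrend

AIC_IMPROVEMENT = 2.0


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of the OLS fit of y on the columns of X plus an intercept."""
    n = y.size
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        return 0.0
    return 1.0 - float((resid ** 2).sum()) / tss


def dual_regression(wue, index):
    """Fit WUE_t on (D_t, D_{t-1}) and the two single-predictor models.

    ``wue`` and ``index`` are aligned annual series; the first year is
    dropped to form the lag pair.  Returns a dict with the coefficients
    (a, b, c), the three R^2 values and the fitted statsmodels results.
    """
    y_full = np.asarray(wue, dtype=float)
    d_full = np.asarray(index, dtype=float)
    if y_full.shape != d_full.shape or y_full.ndim != 1:
        raise ValueError("wue and index must be aligned 1-D annual series")
    if y_full.size < 4:
        raise ValueError("need at least 4 years to form lagged pairs")
    y = y_full[1:]
    d_cur = d_full[1:]
    d_prev = d_full[:-1]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(d_cur, d_prev)[0, 1]
    if not np.isfinite(corr) or abs(corr) >= 1.0 - 1e-12:
        raise ValueError("current- and previous-year index are collinear")

    X2 = sm.add_constant(np.column_stack([d_cur, d_prev]))
    fit_two = sm.OLS(y, X2).fit()
    fit_cur = sm.OLS(y, sm.add_constant(d_cur)).fit()
    fit_prev = sm.OLS(y, sm.add_constant(d_prev)).fit()
    c, a, b = fit_two.params
    return {
        "a": float(a), "b": float(b), "c": float(c),
        "r2_full": float(fit_two.rsquared),
        "r2_current_only": float(fit_cur.rsquared),
        "r2_previous_only": float(fit_prev.rsquared),
        "fit_two": fit_two, "fit_current": fit_cur, "fit_previous": fit_prev,
        "n": int(y.size),
    }


def hierarchical_partition(y, predictors):
    """Independent effect of each predictor on the goodness of fit.

    The independent effect I_j is the average, over all orderings in which
    predictors can enter the model, of the R^2 increment when predictor j
    enters — the Shapley value of R^2.  The identity sum_j I_j = R^2_full
    holds exactly.  Returned as ``(effects, percentages, r2_full)`` with
    percentages relative to the full-model R^2 (NaN when R^2_full = 0).
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.asarray(p, dtype=float) for p in predictors])
    k = X.shape[1]
    if k < 1:
        raise ValueError("need at least one predictor")
    if y.size <= k + 1:
        raise ValueError("need n > k + 1 observations")

    r2 = {(): 0.0}
    idx = tuple(range(k))
    for size in range(1, k + 1):
        for subset in combinations(idx, size):
            r2[subset] = _ols_r2(y, X[:, subset])
    r2_full = r2[idx]

    effects = np.zeros(k)
    kfact = factorial(k)
    for j in range(k):
        others = tuple(i for i in idx if i != j)
        for size in range(0, k):
            weight = factorial(size) * factorial(k - size - 1) / kfact
            for subset in combinations(others, size):
                with_j = tuple(sorted(subset + (j,)))
                effects[j] += weight * (r2[with_j] - r2[subset])

    if r2_full > 0:
        pct = effects / r2_full * 100.0
    else:
        warnings.warn("full-model R^2 is zero; percentages undefined",
                      RuntimeWarning, stacklevel=2)
        pct = np.full(k, np.nan)
    return effects, pct, float(r2_full)


def aic_least_squares(rss: float, n: int, n_coef: int) -> float:
    """Gaussian least-squares AIC = n*ln(RSS/n) + 2*(p + 1).

    ``n_coef`` counts regression coefficients including the intercept; the
    +1 accounts for the error variance.  RSS = 0 returns -inf (perfect fit
    sentinel) with a warning.
    """
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if rss == 0.0:
        warnings.warn("RSS is zero; AIC is -inf", RuntimeWarning, stacklevel=2)
        return -np.inf
    return n * np.log(rss / n) + 2.0 * (n_coef + 1)


def aic_compare(fit_one, fit_two):
    """AIC of the one- and two-predictor fits and the improvement flag.

    Accepts statsmodels results or ``(rss, n_coef)`` tuples sharing the same
    n.  The lagged model is an improvement when aic_one - aic_two > 2.0.
    """
    def _unpack(fit):
        if hasattr(fit, "ssr"):
            return float(fit.ssr), int(fit.df_model) + 1, int(fit.nobs)
        rss, n_coef, n = fit
        return float(rss), int(n_coef), int(n)

    rss1, p1, n1 = _unpack(fit_one)
    rss2, p2, n2 = _unpack(fit_two)
    if n1 != n2:
        raise ValueError("models must share the same response vector length")
    aic_one = aic_least_squares(rss1, n1, p1)
    aic_two = aic_least_squares(rss2, n2, p2)
    improved = bool(aic_one - aic_two > AIC_IMPROVEMENT)
    return aic_one, aic_two, improved


@dataclass
class MemoryEffectResult:
    a: float
    b: float
    c: float
    r2_full: float
    r2_current_only: float
    r2_previous_only: float
    indep_current_pct: float
    indep_previous_pct: float
    aic_one: float
    aic_two: float
    improved: bool
    n: int


class DroughtMemoryRegression(BaseEstimator):
    """Dual-year drought regression of annual WUE, sklearn style.

    ``fit(index, wue)`` detrends both series (optional), drops the first
    year to form the (current, previous) predictor pair, fits the dual and
    single-predictor OLS models, partitions R^2 hierarchically and compares
    AICs.  Fitted attributes: ``a_``, ``b_``, ``c_``, ``r2_full_``,
    ``indep_previous_pct_``, ``aic_one_``, ``aic_two_``, ``improved_``,
    ``result_``.
    """

    def __init__(self, detrended: bool = True):
        self.detrended = detrended

    def fit(self, index, wue):
        index = np.asarray(index, dtype=float)
        wue = np.asarray(wue, dtype=float)
        if self.detrended:
            index = detrend(index)
            wue = detrend(wue)
        reg = dual_regression(wue, index)
        d_cur = index[1:]
        d_prev = index[:-1]
        effects, pct, r2_full = hierarchical_partition(wue[1:], [d_cur, d_prev])
        aic_one, aic_two, improved = aic_compare(reg["fit_current"], reg["fit_two"])
        self.result_ = MemoryEffectResult(
            a=reg["a"], b=reg["b"], c=reg["c"],
            r2_full=reg["r2_full"],
            r2_current_only=reg["r2_current_only"],
            r2_previous_only=reg["r2_previous_only"],
            indep_current_pct=float(pct[0]),
            indep_previous_pct=float(pct[1]),
            aic_one=aic_one, aic_two=aic_two, improved=improved,
            n=reg["n"],
        )
        for name in ("a", "b", "c", "r2_full", "indep_current_pct",
                     "indep_previous_pct", "aic_one", "aic_two", "improved"):
            setattr(self, name + "_", getattr(self.result_, name))
        return self


def memory_effect(wue, index, detrended: bool = True) -> MemoryEffectResult:
    """Functional wrapper around :class:`DroughtMemoryRegression`."""
    return DroughtMemoryRegression(detrended=detrended).fit(index, wue).result_
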