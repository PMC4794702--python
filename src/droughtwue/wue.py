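"""Annual water-use efficiency and its detrended correlation with drought.

WUE = annual GPP / annual ET (g C per kg H2O; 1 mm ET = 1 kg H2O m^-2).
To isolate interannual variability, annual series are detrended by removing
the least-squares linear trend before computing Pearson's r; significance is
the F-test of the regression (equivalently the two-sided t-test on r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .series import FluxSeries

logger = logging.getLogger(__name__)


@dataclass
class WUESeries:
    """Annual GPP, ET and their ratio."""

    table: pd.DataFrame  # index: year; columns: gpp_annual, et_annual, wue

    @property
    def wue(self) -> pd.Series:
        return self.table["wue"]


def annual_wue(fluxes: FluxSeries) -> WUESeries:
    """Annual sums of GPP and ET and their ratio, complete calendar years only.

    Years with fewer than 12 months are dropped with a warning; years with
    zero annual ET have an undefined ratio and are excluded.
    """
    data = fluxes.data
    grouped = data.groupby(data.index.year)
    counts = grouped["gpp"].count()
    incomplete = counts.index[counts != 12]
    if len(incomplete):
        logger.warning("dropping incomplete year(s): %s", list(incomplete))
    sums = grouped[["gpp", "et"]].sum().loc[counts.index[counts == 12]]
    zero_et = sums.index[sums["et"] <= 0]
    if len(zero_et):
        logger.warning("dropping year(s) with zero ET (WUE undefined): %s", list(zero_et))
        sums = sums.drop(index=zero_et)
    table = pd.DataFrame(
        {"gpp_annual": sums["gpp"], "et_annual": sums["et"],
         "wue": sums["gpp"] / sums["et"]})
    table.index.name = "year"
    return WUESeries(table)


def detrend(values, years=None):
    """Residuals of the OLS fit of ``values`` on time (mean zero, slope zero).

    Idempotent: detrending a detrended series returns it unchanged.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("detrend expects a 1-D annual series")
    n = arr.size
    if n < 3:
        raise ValueError("need at least 3 years to detrend")
    x = np.arange(n, dtype=float) if years is None else np.asarray(years, dtype=float)
    slope, intercept = np.polyfit(x, arr, 1)
    resid = arr - (slope * x + intercept)
    if isinstance(values, pd.Series):
        return pd.Series(resid, index=values.index, name=values.name)
    return resid


class Detrender(BaseEstimator, TransformerMixin):
    """Column-wise linear detrending as a scikit-learn transformer.

    ``fit`` stores per-column OLS slope and intercept against the sample
    index; ``transform`` subtracts the fitted line, so train-period trends
    can be removed from held-out years as well.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] < 3:
            raise ValueError("need at least 3 samples to fit a trend")
        t = np.arange(X.shape[0], dtype=float)
        coef = np.polyfit(t, X, 1)
        self.slope_, self.intercept_ = coef[0], coef[1]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        t = np.arange(X.shape[0], dtype=float)
        out = X - (np.outer(t, self.slope_) + self.intercept_)
        return out[:, 0] if squeeze else out


@dataclass
class CorrelationResult:
    """Pearson correlation of annual WUE with a drought index."""

    r: float
    p_value: float
    n: int
    slope: float
    detrended: bool = True
    degenerate: bool = False


def correlate(wue, index, detrended: bool = True) -> CorrelationResult:
    """Pearson r between two aligned annual series, F-test significance.

    The p-value comes from F = t^2 with t = r*sqrt((n-2)/(1-r^2)), on
    (1, n-2) degrees of freedom — identical to the two-sided test on r.
    A zero-variance input makes r undefined: the result is flagged
    ``degenerate`` with NaN statistics.
    """
    x = np.asarray(index, dtype=float)
    y = np.asarray(wue, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be aligned 1-D annual series")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 years")
    sx = x - x.mean()
    sy = y - y.mean()
    vx = float(sx @ sx)
    vy = float(sy @ sy)
    if vx == 0.0 or vy == 0.0:
        return CorrelationResult(r=np.nan, p_value=np.nan, n=n, slope=np.nan,
                                 detrended=detrended, degenerate=True)
    r = float(sx @ sy) / np.sqrt(vx * vy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        f_stat = r * r * (n - 2) / (1.0 - r * r)
        p = float(stats.f.sf(f_stat, 1, n - 2))
    slope = float(sx @ sy) / vx
    return CorrelationResult(r=r, p_value=p, n=n, slope=slope, detrended=detrended)


@dataclass
class StratumSummary:
    """Boxplot statistics of per-location r within one stratum."""

    stratum: str
    median: float
    q25: float
    q75: float
    min: float
    max: float
    count: int


def stratify(r_values, labels) -> list[StratumSummary]:
    """Boxplot statistics (median, quartiles, extremes) of r per stratum.

    Quartiles use linear interpolation (type-7).  Empty strata are omitted.
    NaN r values (degenerate correlations) are dropped per stratum.
    """
    r_values = np.asarray(r_values, dtype=float)
    labels = np.asarray(labels)
    if r_values.shape != labels.shape:
        raise ValueError("one label per correlation result required")
    out = []
    for stratum in pd.unique(labels):
        vals = r_values[labels == stratum]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("stratum %r has no finite r values; omitted", stratum)
            continue
        out.append(StratumSummary(
            stratum=str(stratum),
            median=float(np.median(vals)),
            q25=float(np.quantile(vals, 0.25)),
            q75=float(np.quantile(vals, 0.75)),
            min=float(vals.min()),
            max=float(vals.max()),
            count=int(vals.size),
        ))
    return out


def stratify_frame(results: pd.DataFrame, by: str, value: str = "r") -> pd.DataFrame:
    """``stratify`` on a per-location results table, returned as a DataFrame."""
    summaries = stratify(results[value].to_numpy(), results[by].to_numpy())
    return pd.DataFrame([s.__dict__ for s in summaries]).set_index("stratum")
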