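"""GPP- vs ET-control of water-use-efficiency variability.

The relative sensitivity of GPP (or ET) to drought is the OLS slope between
the flux and the drought index after each is normalised by its time-series
mean.  Where the GPP slope exceeds the ET slope the pixel's WUE variability
is GPP-controlled, otherwise ET-controlled; pixels whose WUE–drought
correlation is not significant are left undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .wue import CorrelationResult, correlate, detrend


def relative_sensitivity(series, index) -> float:
    """OLS slope of (series / mean(series)) on (index / mean(index)).

    Mean-normalisation makes the slope unit-free and scale-invariant.
    """
    y = np.asarray(series, dtype=float)
    x = np.asarray(index, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("series and index must be aligned 1-D annual series")
    if y.size < 3:
        raise ValueError("need at least 3 years")
    my, mx = y.mean(), x.mean()
    if my <= 0:
        raise ValueError("series mean must be positive to normalise")
    if mx == 0:
        raise ValueError("index mean is zero; normalisation undefined")
    yn = y / my
    xn = x / mx
    sx = xn - xn.mean()
    vx = float(sx @ sx)
    if vx == 0.0:
        raise ValueError("index has zero variance")
    return float(sx @ (yn - yn.mean())) / vx


@dataclass
class SensitivityResult:
    slope_gpp: float
    slope_et: float
    dominant: str  # "GPP" | "ET" | "undetermined"
    gated_by: CorrelationResult | None = None


def classify_dominance(slope_gpp: float, slope_et: float,
                       gate: CorrelationResult | None = None,
                       alpha: float = 0.05,
                       absolute: bool = False) -> SensitivityResult:
    """Dominance call from the two relative sensitivities.

    GPP-controlled when slope_gpp > slope_et (strictly), otherwise
    ET-controlled — ties go to ET.  With ``absolute=True`` the magnitudes
    are compared instead of the signed slopes.  A non-significant gating
    correlation (p >= alpha) yields "undetermined".
    """
    if not (np.isfinite(slope_gpp) and np.isfinite(slope_et)):
        raise ValueError("slopes must be finite")
    if gate is not None and (gate.degenerate or not gate.p_value < alpha):
        dominant = "undetermined"
    else:
        a, b = (abs(slope_gpp), abs(slope_et)) if absolute else (slope_gpp, slope_et)
        dominant = "GPP" if a > b else "ET"
    return SensitivityResult(slope_gpp=slope_gpp, slope_et=slope_et,
                             dominant=dominant, gated_by=gate)


class DominanceClassifier(BaseEstimator):
    """Fit the GPP/ET dominance call for one location.

    ``fit(gpp, et, index, wue=None)`` takes aligned annual series, detrends
    the regression inputs when ``detrended`` (mean-normalisation uses the raw
    means), computes both relative sensitivities and the gating WUE–index
    correlation, and stores ``slope_gpp_``, ``slope_et_``, ``gate_`` and
    ``dominant_``.
    """

    def __init__(self, alpha: float = 0.05, absolute: bool = False,
                 detrended: bool = True):
        self.alpha = alpha
        self.absolute = absolute
        self.detrended = detrended

    @staticmethod
    def _normalised(series):
        y = np.asarray(series, dtype=float)
        if y.mean() == 0:
            raise ValueError("series mean is zero; normalisation undefined")
        return y / y.mean()

    def fit(self, gpp, et, index, wue=None):
        gpp_n = self._normalised(gpp)
        et_n = self._normalised(et)
        idx_n = self._normalised(index)
        if wue is None:
            wue = np.asarray(gpp, dtype=float) / np.asarray(et, dtype=float)
        wue = np.asarray(wue, dtype=float)
        if self.detrended:
            gpp_n, et_n, idx_n, wue = (detrend(v) for v in (gpp_n, et_n, idx_n, wue))
        # after detrending the means are 0; slopes come from plain OLS
        sx = idx_n - idx_n.mean()
        vx = float(sx @ sx)
        if vx == 0.0:
            raise ValueError("index has zero variance")
        self.slope_gpp_ = float(sx @ (gpp_n - gpp_n.mean())) / vx
        self.slope_et_ = float(sx @ (et_n - et_n.mean())) / vx
        self.gate_ = correlate(wue, idx_n, detrended=self.detrended)
        result = classify_dominance(self.slope_gpp_, self.slope_et_, self.gate_,
                                    alpha=self.alpha, absolute=self.absolute)
        self.dominant_ = result.dominant
        self.result_ = result
        return self

    def predict(self) -> str:
        return self.dominant_
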