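"""Palmer Drought Severity Index driven by Penman potential evapotranspiration.

The engine follows Palmer's (1965) monthly procedure with the operational
spell-tracking conventions of Alley (1984):

1. a two-layer soil water balance (surface layer holds 25.4 mm = 1 inch;
   the underlying layer the remainder of the available water capacity),
   yielding actual and potential evapotranspiration, recharge, runoff and
   loss for every month;
2. CAFEC ("climatically appropriate for existing conditions") coefficients
   alpha, beta, gamma, delta — ratios of calibration-period means per
   calendar month — giving an expected precipitation P-hat and the moisture
   departure d = P − P-hat;
3. the climatic characteristic K that weights departures so the index is
   comparable between climates (Palmer's empirical constants, fitted in
   inches, hence the internal mm → inch conversion before this step);
4. the moisture anomaly (Z-index) z = K·d and the damped recursion
   X_i = 0.897·X_{i−1} + z_i/3 run on three tracks (incipient wet X1 >= 0,
   incipient dry X2 <= 0, established spell X3), with spell establishment at
   |X| >= 1, termination probabilities from accumulated effective moisture,
   and retroactive backtracking once a spell's fate is decided.

All empirical constants are Palmer's; the only departure from his original
is the PET model (Penman instead of Thornthwaite), supplied by
:mod:`droughtwue.pet`.  More negative PDSI = more severe drought.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .pet import penman_pet
from .series import ClimateSeries, PetSeries

MM_PER_INCH = 25.4
#: Surface-layer capacity: Palmer's 1-inch top layer.
SURFACE_CAPACITY = 25.4
#: Default available water capacity (mm) when no soil map is supplied.
DEFAULT_AWC = 152.4

_DAMPING = 0.897          # X carry-over factor
_Z_DIVISOR = 3.0          # z contribution divisor
_K_SUM = 17.67            # Palmer's normalisation constant (inches)
_SPELL_THRESHOLD = 1.0    # |X| at which a spell is established
_U_OFFSET = 0.15          # effective-moisture offset in U
_ZE_SLOPE = 2.691         # slope in the spell-ending moisture requirement
_ZE_OFFSET = 1.5


@dataclass
class SoilWaterState:
    """Two-layer soil moisture store (all mm)."""

    ss: float
    su: float
    awc: float
    surface_capacity: float = SURFACE_CAPACITY

    def __post_init__(self) -> None:
        if self.awc <= self.surface_capacity:
            raise ValueError("awc must exceed the surface-layer capacity")
        if not (0.0 <= self.ss <= self.surface_capacity + 1e-9):
            raise ValueError("surface store outside [0, surface_capacity]")
        if not (0.0 <= self.su <= self.awc - self.surface_capacity + 1e-9):
            raise ValueError("underlying store outside [0, awc - surface_capacity]")

    @classmethod
    def full(cls, awc: float, surface_capacity: float = SURFACE_CAPACITY) -> "SoilWaterState":
        return cls(ss=surface_capacity, su=awc - surface_capacity, awc=awc,
                   surface_capacity=surface_capacity)


TERM_COLUMNS = ("p", "pe", "et", "r", "ro", "l", "pr", "pro", "pl")


def water_balance_step(state: SoilWaterState, p: float, pe: float):
    """One month of Palmer's two-layer accounting.

    Potential terms are evaluated against the antecedent stores; the surface
    layer wets and dries first, and the underlying layer loses water in
    proportion to its relative content su/awc.
    Returns ``(new_state, terms)`` with ``terms`` a dict over TERM_COLUMNS.
    """
    if p < 0 or pe < 0:
        raise ValueError("precipitation and PET must be non-negative")
    ss, su = state.ss, state.su
    cap_s = state.surface_capacity
    cap_u = state.awc - cap_s

    pl_s = min(pe, ss)
    pl_u = min(su, (pe - pl_s) * su / state.awc)
    pl = pl_s + pl_u
    pr = state.awc - (ss + su)
    pro = ss + su

    if p >= pe:
        et = pe
        surplus = p - pe
        rech_s = min(surplus, cap_s - ss)
        ss += rech_s
        rech_u = min(surplus - rech_s, cap_u - su)
        su += rech_u
        r = rech_s + rech_u
        ro = max(surplus - r, 0.0)  # guard float dust when stores just fill
        loss = 0.0
    else:
        deficit = pe - p
        l_s = min(ss, deficit)
        l_u = min(su, (deficit - l_s) * su / state.awc)
        ss -= l_s
        su -= l_u
        loss = l_s + l_u
        et = p + loss
        r = ro = 0.0

    new_state = replace(state, ss=ss, su=su)
    terms = {"p": p, "pe": pe, "et": et, "r": r, "ro": ro, "l": loss,
             "pr": pr, "pro": pro, "pl": pl}
    return new_state, terms


def run_water_balance(precip: pd.Series, pet: pd.Series, awc: float = DEFAULT_AWC,
                      surface_capacity: float = SURFACE_CAPACITY,
                      initial: SoilWaterState | None = None) -> pd.DataFrame:
    """Water-balance terms for a whole monthly series (starts from full stores)."""
    if initial is None:
        initial = SoilWaterState.full(awc, surface_capacity)
    state = initial
    rows = []
    for p, pe in zip(precip.to_numpy(dtype=float), pet.to_numpy(dtype=float)):
        state, terms = water_balance_step(state, p, pe)
        terms["ss"] = state.ss
        terms["su"] = state.su
        rows.append(terms)
    return pd.DataFrame(rows, index=precip.index)


def calibrate_cafec(terms: pd.DataFrame) -> pd.DataFrame:
    """CAFEC coefficients and calibration means per calendar month.

    alpha = mean(ET)/mean(PE), beta = mean(R)/mean(PR),
    gamma = mean(RO)/mean(PRO), delta = mean(L)/mean(PL),
    with the 0/0 convention alpha → 1 and beta, gamma, delta → 0.
    """
    if len(terms) < 12:
        raise ValueError("need at least one complete year to calibrate")
    months = terms.index.month
    means = terms.groupby(months)[list(TERM_COLUMNS)].mean()

    def _ratio(num, den, on_zero):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        return np.where(den > 0, out, on_zero)

    coeffs = pd.DataFrame(index=means.index)
    coeffs["alpha"] = _ratio(means["et"], means["pe"], 1.0)
    coeffs["beta"] = _ratio(means["r"], means["pr"], 0.0)
    coeffs["gamma"] = _ratio(means["ro"], means["pro"], 0.0)
    coeffs["delta"] = _ratio(means["l"], means["pl"], 0.0)
    return coeffs.join(means.add_prefix("mean_"))


def cafec_precipitation(terms: pd.DataFrame, coeffs: pd.DataFrame) -> pd.Series:
    """P-hat = alpha·PE + beta·PR + gamma·PRO − delta·PL per month."""
    m = terms.index.month
    c = coeffs.loc[m]
    phat = (c["alpha"].to_numpy() * terms["pe"].to_numpy()
            + c["beta"].to_numpy() * terms["pr"].to_numpy()
            + c["gamma"].to_numpy() * terms["pro"].to_numpy()
            - c["delta"].to_numpy() * terms["pl"].to_numpy())
    return pd.Series(phat, index=terms.index, name="cafec_p")


def moisture_departure(terms: pd.DataFrame, coeffs: pd.DataFrame) -> pd.Series:
    """d = P − P-hat (mm)."""
    d = terms["p"] - cafec_precipitation(terms, coeffs)
    d.name = "d"
    return d


def climatic_characteristic(d: pd.Series, coeffs: pd.DataFrame) -> pd.DataFrame:
    """Palmer's climatic characteristic K per calendar month.

    Evaluated in inches (the units the empirical constants were fitted in):

        K'_j = 1.5·log10((T_j + 2.8) / Dbar_j) + 0.5,
        T_j  = (PEbar_j + Rbar_j + RObar_j) / (Pbar_j + Lbar_j),
        K_j  = 17.67 / sum_i(Dbar_i·K'_i) · K'_j.
    """
    months = d.index.month
    dbar = d.abs().groupby(months).mean() / MM_PER_INCH
    if (dbar <= 0).any():
        raise ValueError("mean |d| is zero for some month; degenerate climate")
    supply = (coeffs["mean_pe"] + coeffs["mean_r"] + coeffs["mean_ro"]) / MM_PER_INCH
    demand = (coeffs["mean_p"] + coeffs["mean_l"]) / MM_PER_INCH
    if (demand <= 0).any():
        raise ValueError("zero precipitation + loss mean; degenerate climate")
    t = supply / demand
    k_prime = 1.5 * np.log10((t + 2.8) / dbar) + 0.5
    k = _K_SUM / float((dbar * k_prime).sum()) * k_prime
    out = pd.DataFrame({"dbar": dbar, "k_prime": k_prime, "k": k})
    out.index.name = "month"
    return out


def z_index(d: pd.Series, k: pd.DataFrame | pd.Series) -> pd.Series:
    """Moisture anomaly z = K_j · d (d converted to inches)."""
    kvals = k["k"] if isinstance(k, pd.DataFrame) else k
    z = kvals.loc[d.index.month].to_numpy() * d.to_numpy() / MM_PER_INCH
    return pd.Series(z, index=d.index, name="z")


def pdsi_recursion(z: pd.Series | np.ndarray) -> pd.DataFrame:
    """Run the three-track Palmer recursion with backtracking.

    Returns a frame with columns x1, x2, x3, pdsi and spell_prob (% chance
    that the established spell has ended).  After backtracking, pdsi equals
    one of x1/x2/x3 at every month.
    """
    index = z.index if isinstance(z, pd.Series) else pd.RangeIndex(len(z))
    zv = np.asarray(z, dtype=float)
    if not np.isfinite(zv).all():
        raise ValueError("z contains non-finite values")
    n = len(zv)
    x1 = np.zeros(n)
    x2 = np.zeros(n)
    x3 = np.zeros(n)
    pdsi = np.zeros(n)
    prob = np.zeros(n)

    X1 = X2 = X3 = 0.0
    V = 0.0
    Pe = 0.0
    pending: list[int] = []  # months whose final value awaits backtracking

    for i in range(n):
        PX1 = max(0.0, _DAMPING * X1 + zv[i] / _Z_DIVISOR)
        PX2 = min(0.0, _DAMPING * X2 + zv[i] / _Z_DIVISOR)
        x1[i], x2[i] = PX1, PX2

        if X3 == 0.0:
            # no established spell: watch the incipient tracks
            V = 0.0
            Pe = 0.0
            if PX1 >= _SPELL_THRESHOLD:
                X3 = PX1
                for j in pending:
                    pdsi[j] = x1[j]
                pending.clear()
                X1 = X2 = 0.0
                x3[i] = X3
                pdsi[i] = X3
            elif PX2 <= -_SPELL_THRESHOLD:
                X3 = PX2
                for j in pending:
                    pdsi[j] = x2[j]
                pending.clear()
                X1 = X2 = 0.0
                x3[i] = X3
                pdsi[i] = X3
            else:
                X1, X2 = PX1, PX2
                if PX1 == 0.0 and PX2 == 0.0:
                    # both tracks extinguished: keep the larger-magnitude side
                    for j in pending:
                        pdsi[j] = x1[j] if abs(x1[j]) > abs(x2[j]) else x2[j]
                    pending.clear()
                    pdsi[i] = 0.0
                else:
                    pending.append(i)
                    pdsi[i] = PX1 if abs(PX1) > abs(PX2) else PX2
            continue

        # established spell: update X3 and the probability of its ending
        PX3 = _DAMPING * X3 + zv[i] / _Z_DIVISOR
        x3[i] = PX3
        wet = X3 > 0
        if wet:
            Ze = -(-_ZE_SLOPE * X3 + _ZE_OFFSET)   # moisture deficit needed, as magnitude
            U = -(zv[i] - _U_OFFSET)               # effective dryness, as magnitude
        else:
            Ze = -_ZE_SLOPE * X3 - _ZE_OFFSET      # moisture needed to end the drought
            U = zv[i] + _U_OFFSET                  # effective wetness
        Q = Ze + V if Pe > 0 else Ze
        Vnew = U + (V if Pe > 0 else 0.0)

        if Q <= 0 or (Vnew > 0 and 100.0 * Vnew / Q >= 100.0):
            # spell terminated: the uncertain stretch belongs to the other track
            for j in pending:
                pdsi[j] = x1[j] if not wet else x2[j]
            pending.clear()
            new = PX1 if not wet else PX2
            pdsi[i] = new
            prob[i] = 100.0
            X3 = new if abs(new) >= _SPELL_THRESHOLD else 0.0
            if X3 != 0.0:
                x3[i] = X3
                X1 = X2 = 0.0
            else:
                X1, X2 = PX1, PX2
            V = 0.0
            Pe = 0.0
            continue

        if Vnew <= 0:
            # no progress towards ending: the spell certainly continues
            for j in pending:
                pdsi[j] = x3[j]
            pending.clear()
            V = 0.0
            Pe = 0.0
            pdsi[i] = PX3
        else:
            V = Vnew
            Pe = 100.0 * V / Q
            prob[i] = Pe
            pending.append(i)
            pdsi[i] = PX3
        X3 = PX3
        X1, X2 = PX1, PX2

    # series ends with the spell's fate undecided: keep provisional values
    for j in pending:
        pdsi[j] = x3[j] if x3[j] != 0.0 else (x1[j] if abs(x1[j]) > abs(x2[j]) else x2[j])

    return pd.DataFrame(
        {"x1": x1, "x2": x2, "x3": x3, "pdsi": pdsi, "spell_prob": prob}, index=index
    )


@dataclass
class PdsiSeries:
    """Monthly Palmer intermediates and index, plus annual means."""

    monthly: pd.DataFrame      # d, z, x1, x2, x3, pdsi, spell_prob
    annual: pd.Series          # calendar-year mean PDSI
    coefficients: pd.DataFrame
    k: pd.DataFrame


def annual_mean_pdsi(monthly: pd.DataFrame) -> pd.Series:
    grouped = monthly["pdsi"].groupby(monthly.index.year)
    counts = grouped.count()
    out = grouped.mean()[counts == 12]
    out.name = "pdsi"
    return out


class PalmerDroughtIndex(BaseEstimator):
    """Palmer Drought Severity Index as a fit/transform estimator.

    ``fit`` runs the water balance over the calibration window and freezes
    the CAFEC coefficients and climatic characteristic K; ``transform``
    applies them to (possibly different) forcing and runs the Z-index and
    spell recursion.  ``fit_transform`` on the same climate reproduces the
    classic single-pass Palmer computation.

    Parameters
    ----------
    awc : float
        Available water capacity of the soil column (mm).
    surface_capacity : float
        Capacity of Palmer's surface layer (mm).
    calibration : tuple[int, int] | None
        Inclusive (start_year, end_year) of the calibration window; the
        full record when None.
    """

    def __init__(self, awc: float = DEFAULT_AWC,
                 surface_capacity: float = SURFACE_CAPACITY,
                 calibration: tuple[int, int] | None = None):
        self.awc = awc
        self.surface_capacity = surface_capacity
        self.calibration = calibration

    def _terms(self, climate: ClimateSeries, pet: PetSeries | None) -> pd.DataFrame:
        if pet is None:
            pet = penman_pet(climate)
        return run_water_balance(climate.data["precip"], pet.pet, self.awc,
                                 self.surface_capacity)

    def fit(self, climate: ClimateSeries, pet: PetSeries | None = None):
        n_years = len(climate.time) / 12.0
        if n_years < 10:
            warnings.warn(
                f"only {n_years:.1f} years of forcing; PDSI calibration is "
                "recommended on >= 10 years", UserWarning, stacklevel=2)
        terms = self._terms(climate, pet)
        if self.calibration is not None:
            y0, y1 = self.calibration
            window = terms[(terms.index.year >= y0) & (terms.index.year <= y1)]
        else:
            window = terms
        if len(window) < 12:
            raise ValueError("calibration window shorter than one year")
        self.coefficients_ = calibrate_cafec(window)
        d_cal = moisture_departure(window, self.coefficients_)
        self.k_ = climatic_characteristic(d_cal, self.coefficients_)
        return self

    def transform(self, climate: ClimateSeries, pet: PetSeries | None = None) -> PdsiSeries:
        terms = self._terms(climate, pet)
        d = moisture_departure(terms, self.coefficients_)
        z = z_index(d, self.k_)
        tracks = pdsi_recursion(z)
        monthly = pd.concat([d, z, tracks], axis=1)
        return PdsiSeries(monthly=monthly, annual=annual_mean_pdsi(monthly),
                          coefficients=self.coefficients_, k=self.k_)

    def fit_transform(self, climate: ClimateSeries, pet: PetSeries | None = None) -> PdsiSeries:
        return self.fit(climate, pet).transform(climate, pet)


def compute_pdsi(climate: ClimateSeries, awc: float = DEFAULT_AWC,
                 calibration: tuple[int, int] | None = None,
                 pet: PetSeries | None = None) -> PdsiSeries:
    """One-call Penman-PDSI: water balance → CAFEC → K → z → recursion."""
    return PalmerDroughtIndex(awc=awc, calibration=calibration).fit_transform(climate, pet)
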