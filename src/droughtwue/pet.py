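"""Penman potential evapotranspiration, wetness index and UNEP aridity classes.

The PET model is the classic open-water Penman (1948) combination equation:

    PET_day = Delta/(Delta+gamma) * Rn/lambda
            + gamma/(Delta+gamma) * f(u) * (e_s(T) - e_a)

with the Tetens saturation curve, lambda = 2.501 - 0.002361*T MJ kg^-1, the
psychrometric constant gamma from an elevation-corrected surface pressure, the
empirical wind function f(u) = 2.6*(1 + 0.536*u) mm day^-1 kPa^-1, and ground
heat flux neglected at the monthly scale.  Monthly PET is the daily value
times the number of days in the month.

The wetness index WI = P/PET (annual totals) drives the UNEP aridity
classification: hyper-arid (< 0.05), arid (< 0.2), semi-arid (< 0.5), dry
sub-humid (< 0.65) and humid (>= 0.65), grouped for analysis into the three
zones arid / semi-arid--sub-humid / humid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import CLIMATE_COLUMNS, ClimateSeries, PetSeries

ARIDITY_CLASSES = ("hyper_arid", "arid", "semi_arid", "dry_sub_humid", "humid")
ANALYSIS_ZONES = ("arid", "semi_arid_sub_humid", "humid")

#: WI upper bounds of each class (lower-closed, half-open intervals).
_CLASS_BOUNDS = (0.05, 0.2, 0.5, 0.65, np.inf)

_ZONE_OF_CLASS = {
    "hyper_arid": "arid",
    "arid": "arid",
    "semi_arid": "semi_arid_sub_humid",
    "dry_sub_humid": "semi_arid_sub_humid",
    "humid": "humid",
}


def saturation_vapor_pressure(tair):
    """Tetens saturation vapour pressure (kPa) at air temperature ``tair`` (deg C)."""
    tair = np.asarray(tair, dtype=float)
    return 0.6108 * np.exp(17.27 * tair / (tair + 237.3))


def svp_slope(tair):
    """Slope of the saturation curve Delta (kPa K^-1)."""
    tair = np.asarray(tair, dtype=float)
    return 4098.0 * saturation_vapor_pressure(tair) / (tair + 237.3) ** 2


def latent_heat(tair):
    """Latent heat of vaporisation (MJ kg^-1), weakly temperature dependent."""
    return 2.501 - 0.002361 * np.asarray(tair, dtype=float)


def psychrometric_constant(elevation: float = 0.0):
    """Psychrometric constant gamma (kPa K^-1) at a given elevation (m)."""
    p_atm = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    return 0.000665 * p_atm


def penman_pet_daily(tair, rn, ea, wind, elevation: float = 0.0):
    """Daily Penman PET (mm day^-1) and its radiative/aerodynamic components.

    Parameters are air temperature (deg C), net radiation (MJ m^-2 day^-1),
    actual vapour pressure (kPa) and 2-m wind speed (m s^-1).  A vapour
    pressure above saturation is physically a supersaturated reading; the
    deficit is clipped at zero with a warning.
    """
    tair = np.asarray(tair, dtype=float)
    rn = np.asarray(rn, dtype=float)
    ea = np.asarray(ea, dtype=float)
    wind = np.asarray(wind, dtype=float)

    es = saturation_vapor_pressure(tair)
    delta = svp_slope(tair)
    gamma = psychrometric_constant(elevation)
    lam = latent_heat(tair)

    deficit = es - ea
    if np.any(deficit < 0):
        warnings.warn(
            "actual vapour pressure exceeds saturation; clipping deficit at 0",
            RuntimeWarning,
            stacklevel=2,
        )
        deficit = np.clip(deficit, 0.0, None)

    radiative = delta / (delta + gamma) * rn / lam
    aerodynamic = gamma / (delta + gamma) * 2.6 * (1.0 + 0.536 * wind) * deficit
    radiative = np.clip(radiative, 0.0, None)
    aerodynamic = np.clip(aerodynamic, 0.0, None)
    return radiative + aerodynamic, radiative, aerodynamic


def penman_pet(climate: ClimateSeries) -> PetSeries:
    """Monthly Penman PET (mm month^-1) from a :class:`ClimateSeries`."""
    missing = [c for c in CLIMATE_COLUMNS if c not in climate.data.columns]
    if missing:
        raise ValueError(f"missing forcing field(s): {', '.join(missing)}")
    data = climate.data
    total, rad, aero = penman_pet_daily(
        data["tair"], data["rn"], data["ea"], data["wind"], climate.elevation
    )
    days = data.index.days_in_month.to_numpy(dtype=float)
    idx = data.index
    return PetSeries(
        pet=pd.Series(total * days, index=idx, name="pet"),
        radiative=pd.Series(rad * days, index=idx, name="pet_radiative"),
        aerodynamic=pd.Series(aero * days, index=idx, name="pet_aerodynamic"),
    )


def wetness_index(precip_annual, pet_annual):
    """WI = annual precipitation / annual PET (both mm yr^-1)."""
    precip_annual = np.asarray(precip_annual, dtype=float)
    pet_annual = np.asarray(pet_annual, dtype=float)
    if np.any(pet_annual <= 0):
        raise ValueError("annual PET must be positive; wetness index undefined")
    return precip_annual / pet_annual


def classify_aridity(wi: float) -> tuple[str, str]:
    """Map a wetness index to its (UNEP aridity class, analysis zone).

    Intervals are lower-closed: wi exactly 0.65 is humid.
    """
    if not np.isfinite(wi) or wi < 0:
        raise ValueError(f"wetness index must be finite and >= 0, got {wi!r}")
    for cls, bound in zip(ARIDITY_CLASSES, _CLASS_BOUNDS):
        if wi < bound:
            return cls, _ZONE_OF_CLASS[cls]
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass
class WetnessIndexSeries:
    """Annual wetness index plus the location's period-mean aridity class."""

    wi_annual: pd.Series
    aridity_class: str
    analysis_zone: str


def annual_wetness_index(climate: ClimateSeries, pet: PetSeries | None = None) -> WetnessIndexSeries:
    """Per-year WI for a location, classified on the period-mean annual WI."""
    if pet is None:
        pet = penman_pet(climate)
    precip = climate.annual_precip()
    pet_annual = pet.annual()
    years = precip.index.intersection(pet_annual.index)
    wi = pd.Series(
        wetness_index(precip.loc[years], pet_annual.loc[years]), index=years, name="wi"
    )
    cls, zone = classify_aridity(float(wi.mean()))
    return WetnessIndexSeries(wi_annual=wi, aridity_class=cls, analysis_zone=zone)
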