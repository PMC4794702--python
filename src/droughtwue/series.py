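"""Monthly time-series containers for climate forcing and carbon/water fluxes.

All monthly data are carried as :class:`pandas.DataFrame` objects indexed by a
contiguous monthly :class:`pandas.PeriodIndex`.  The light dataclass wrappers
validate physical constraints once, at construction, so downstream numerics
can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLIMATE_COLUMNS = ("precip", "tair", "rn", "ea", "wind")
FLUX_COLUMNS = ("gpp", "et")


def monthly_index(start_year: int, n_years: int) -> pd.PeriodIndex:
    """A contiguous monthly PeriodIndex covering ``n_years`` calendar years."""
    return pd.period_range(start=f"{start_year}-01", periods=12 * n_years, freq="M")


def _check_monthly_index(index: pd.Index) -> pd.PeriodIndex:
    if not isinstance(index, pd.PeriodIndex) or index.freqstr not in ("M", "ME"):
        raise TypeError("time axis must be a monthly pandas.PeriodIndex")
    if len(index) == 0:
        raise ValueError("empty time axis")
    expected = pd.period_range(index[0], periods=len(index), freq="M")
    if not index.equals(expected):
        missing = expected.difference(index)
        raise ValueError(
            "time axis must be contiguous monthly; first gap near "
            + (str(missing[0]) if len(missing) else "reordered entries")
        )
    return index


@dataclass
class ClimateSeries:
    """Monthly meteorological forcing at one location.

    Columns of ``data``: ``precip`` (mm month^-1), ``tair`` (deg C), ``rn``
    (net radiation, MJ m^-2 day^-1), ``ea`` (actual vapour pressure, kPa),
    ``wind`` (2-m wind speed, m s^-1).
    """

    data: pd.DataFrame
    latitude: float = 0.0
    elevation: float = 0.0

    def __post_init__(self) -> None:
        missing = [c for c in CLIMATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"climate data missing column(s): {', '.join(missing)}")
        _check_monthly_index(self.data.index)
        if not np.isfinite(self.data[list(CLIMATE_COLUMNS)].to_numpy()).all():
            raise ValueError("climate data contain non-finite values")
        for col in ("precip", "ea", "wind"):
            if (self.data[col].to_numpy() < 0).any():
                raise ValueError(f"negative values in climate field '{col}'")

    @property
    def time(self) -> pd.PeriodIndex:
        return self.data.index

    def annual_precip(self) -> pd.Series:
        """Calendar-year precipitation totals (mm yr^-1), complete years only."""
        grouped = self.data["precip"].groupby(self.data.index.year)
        counts = grouped.count()
        totals = grouped.sum()
        return totals[counts == 12]


@dataclass
class FluxSeries:
    """Monthly GPP (g C m^-2 month^-1) and ET (mm month^-1) at one location."""

    data: pd.DataFrame
    site_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in FLUX_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"flux data missing column(s): {', '.join(missing)}")
        _check_monthly_index(self.data.index)
        arr = self.data[list(FLUX_COLUMNS)].to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("flux data contain non-finite values")
        if (arr < 0).any():
            raise ValueError("negative GPP or ET")

    @property
    def time(self) -> pd.PeriodIndex:
        return self.data.index


@dataclass
class PetSeries:
    """Monthly potential evapotranspiration split into its two Penman terms.

    ``pet = radiative + aerodynamic`` (mm month^-1) by construction.
    """

    pet: pd.Series
    radiative: pd.Series
    aerodynamic: pd.Series

    def __post_init__(self) -> None:
        resid = np.max(np.abs(self.pet.to_numpy() - self.radiative.to_numpy() - self.aerodynamic.to_numpy()))
        if resid > 1e-9:
            raise ValueError("PET components do not sum to total PET")

    def annual(self) -> pd.Series:
        grouped = self.pet.groupby(self.pet.index.year)
        counts = grouped.count()
        return grouped.sum()[counts == 12]
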