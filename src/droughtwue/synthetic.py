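"""Synthetic monthly climate and flux series with prescribed drought regimes.

Each location draws an i.i.d. standard-normal annual wetness anomaly w_t.
Precipitation is a fixed seasonal cycle scaled so that annual P / annual
Penman PET matches the regime's target wetness index, multiplied by a
mean-one lognormal factor exp(sigma_w * w_t - sigma_w^2/2); temperature,
radiation, humidity and wind follow climatological cycles with small
perturbations uncorrelated with w_t.  Annual GPP and ET respond
multiplicatively to the anomaly,

    GPP_t = GPP0 * (1 + trend_gpp*dt) * exp(g*w_t + lag*w_{t-1} + eps_g),
    ET_t  = ET0  * (1 + trend_et*dt)  * exp(e*w_t + eps_e),

so all series stay strictly positive and, with g = e and no noise, the
WUE ratio is exactly constant.  The previous-year (memory) term acts on
GPP — a productivity legacy — so the WUE lag slope equals lag_coefficient;
its default sign opposes the current-year WUE response g - e.

The three bundled regimes encode the qualitative drought responses the
analysis is designed to detect: arid cells are ET-dominated (WUE rises in
drought), semi-arid/sub-humid cells GPP-dominated (WUE falls in drought),
humid cells respond weakly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pet import penman_pet_daily
from .series import ClimateSeries, FluxSeries, monthly_index

REGIMES = ("arid", "semi_arid_sub_humid", "humid")

#: Interannual s.d. of the lognormal precipitation factor per unit anomaly.
PRECIP_SIGMA = 0.3

_WI_BOUNDS = {"arid": (0.0, 0.2), "semi_arid_sub_humid": (0.2, 0.65),
              "humid": (0.65, np.inf)}


@dataclass(frozen=True)
class RegimeSpec:
    """Generator parameters for one drought-response regime.

    Sensitivities are fractional responses per unit standardised wetness
    anomaly; noise_sd is the s.d. of the lognormal year-to-year flux noise;
    trends are fractions per year applied linearly around the record centre.
    """

    regime: str
    mean_wi: float
    gpp_sensitivity: float
    et_sensitivity: float
    lag_coefficient: float | None = None
    noise_sd: float = 0.05
    trend_gpp: float = 0.0
    trend_et: float = 0.0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        lo, hi = _WI_BOUNDS[self.regime]
        if not (lo <= self.mean_wi < hi) or self.mean_wi <= 0:
            raise ValueError(
                f"mean_wi={self.mean_wi} inconsistent with regime {self.regime!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("gpp_sensitivity", "et_sensitivity"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.lag_coefficient is None:
            # memory opposes the current-year WUE response by default
            object.__setattr__(
                self, "lag_coefficient",
                -0.5 * (self.gpp_sensitivity - self.et_sensitivity))


DEFAULT_REGIMES: dict[str, RegimeSpec] = {
    "arid": RegimeSpec("arid", mean_wi=0.12,
                       gpp_sensitivity=0.10, et_sensitivity=0.30),
    "semi_arid_sub_humid": RegimeSpec("semi_arid_sub_humid", mean_wi=0.40,
                                      gpp_sensitivity=0.30, et_sensitivity=0.10),
    "humid": RegimeSpec("humid", mean_wi=1.20,
                        gpp_sensitivity=0.03, et_sensitivity=0.02),
}


def mix_seed(master_seed: int, cell_id: str) -> int:
    """Platform-stable sub-seed from a master seed and a cell id.

    FNV-1a over the id bytes folded into the master seed, finished with the
    splitmix64 avalanche; reduced below 2**31.
    """
    h = master_seed & 0xFFFFFFFFFFFFFFFF
    for byte in cell_id.encode("utf-8"):
        h = ((h ^ byte) * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    h = ((h ^ (h >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    h = ((h ^ (h >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    h ^= h >> 31
    return int(h % (2**31))


def _seasonal_phase() -> np.ndarray:
    months = np.arange(1, 13)
    return np.cos(2.0 * np.pi * (months - 7) / 12.0)  # peaks in July


def _climatology(elevation: float):
    """Unperturbed monthly cycles of tair, rn, wind, ea and their annual PET."""
    phase = _seasonal_phase()
    tair = 12.0 + 9.0 * phase
    rn = 9.0 + 6.0 * phase
    wind = np.full(12, 2.5)
    es = 0.6108 * np.exp(17.27 * tair / (tair + 237.3))
    ea = 0.6 * es  # ~60% relative humidity
    days = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    pet_daily, _, _ = penman_pet_daily(tair, rn, ea, wind, elevation)
    pet_annual = float((pet_daily * days).sum())
    return tair, rn, wind, ea, pet_annual


def generate_location(spec: RegimeSpec, n_years: int, seed: int,
                      start_year: int = 1982, elevation: float = 200.0,
                      latitude: float = 40.0):
    """One location's monthly climate and fluxes plus its latent anomalies.

    Returns ``(ClimateSeries, FluxSeries, anomalies)`` where ``anomalies``
    is a pandas Series of the standardised wetness anomalies indexed by
    year, including the pre-record year used by the lag term.
    """
    if n_years < 3:
        raise ValueError("n_years must be >= 3")
    rng = np.random.default_rng(seed)
    idx = monthly_index(start_year, n_years)
    tair_c, rn_c, wind_c, ea_c, pet_annual = _climatology(elevation)

    # latent anomalies, one extra draw for the year before the record
    w = rng.standard_normal(n_years + 1)
    w_prev, w_cur = w[:-1], w[1:]

    # precipitation: seasonal shape scaled to the target wetness index
    phase = _seasonal_phase()
    share = 1.0 + 0.3 * phase
    share = share / share.sum()
    p_target = spec.mean_wi * pet_annual
    annual_factor = np.exp(PRECIP_SIGMA * w_cur - 0.5 * PRECIP_SIGMA**2)
    precip = np.concatenate([p_target * share * f for f in annual_factor])

    # meteorology: climatology plus small perturbations, independent of w
    n_m = 12 * n_years
    tair = np.tile(tair_c, n_years) + rng.normal(0.0, 0.5, n_m)
    rn = np.maximum(np.tile(rn_c, n_years) + rng.normal(0.0, 0.3, n_m), 0.5)
    wind = np.maximum(np.tile(wind_c, n_years) + rng.normal(0.0, 0.2, n_m), 0.05)
    ea = np.tile(ea_c, n_years) * np.clip(1.0 + rng.normal(0.0, 0.02, n_m), 0.5, 1.4)

    climate = ClimateSeries(
        data=pd.DataFrame(
            {"precip": precip, "tair": tair, "rn": rn, "ea": ea, "wind": wind},
            index=idx),
        latitude=latitude, elevation=elevation)

    # annual fluxes responding to current and previous anomalies
    et0 = min(0.9 * p_target, 0.75 * pet_annual)
    gpp0 = 2.0 * et0
    dt = np.arange(n_years, dtype=float) - (n_years - 1) / 2.0
    trend_g = 1.0 + spec.trend_gpp * dt
    trend_e = 1.0 + spec.trend_et * dt
    if (trend_g <= 0).any() or (trend_e <= 0).any():
        raise ValueError("trend too steep: a linear trend factor became non-positive")
    eps_g = rng.normal(0.0, spec.noise_sd, n_years) if spec.noise_sd > 0 else np.zeros(n_years)
    eps_e = rng.normal(0.0, spec.noise_sd, n_years) if spec.noise_sd > 0 else np.zeros(n_years)
    gpp_annual = gpp0 * trend_g * np.exp(
        spec.gpp_sensitivity * w_cur + spec.lag_coefficient * w_prev + eps_g)
    et_annual = et0 * trend_e * np.exp(spec.et_sensitivity * w_cur + eps_e)

    flux_share = 0.4 + 0.6 * (1.0 + phase) / 2.0  # growing-season weighting
    flux_share = flux_share / flux_share.sum()
    gpp = np.concatenate([g * flux_share for g in gpp_annual])
    et = np.concatenate([e * flux_share for e in et_annual])
    fluxes = FluxSeries(data=pd.DataFrame({"gpp": gpp, "et": et}, index=idx))

    anomalies = pd.Series(w, index=np.arange(start_year - 1, start_year + n_years),
                          name="w")
    return climate, fluxes, anomalies


@dataclass
class SyntheticDataset:
    """A bundle of generated locations with their ground-truth regimes."""

    climate: dict[str, ClimateSeries]
    fluxes: dict[str, FluxSeries]
    anomalies: dict[str, pd.Series]
    truth: pd.DataFrame
    seed: int
    coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def location_ids(self) -> list[str]:
        return list(self.climate)


def generate_grid(regime_map, n_years: int, seed: int,
                  start_year: int = 1982) -> SyntheticDataset:
    """Generate one location per cell of ``regime_map`` (id -> RegimeSpec).

    Every cell gets an independent, platform-stable sub-seed via
    :func:`mix_seed`; cells are laid out row-major on a synthetic 0.5-degree
    grid for the NetCDF writers.
    """
    if hasattr(regime_map, "items"):
        items = list(regime_map.items())
    else:
        items = list(regime_map)
    if not items:
        raise ValueError("regime_map is empty")
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate location ids in regime_map")

    ncols = int(np.ceil(np.sqrt(len(items))))
    climate, fluxes, anomalies, coords, rows = {}, {}, {}, {}, []
    for pos, (cell_id, spec) in enumerate(items):
        sub_seed = mix_seed(seed, str(cell_id))
        lat = 30.0 + 0.5 * (pos // ncols)
        lon = -120.0 + 0.5 * (pos % ncols)
        c, f, w = generate_location(spec, n_years, sub_seed, start_year,
                                    latitude=lat)
        climate[cell_id] = c
        fluxes[cell_id] = f
        anomalies[cell_id] = w
        coords[cell_id] = (lat, lon)
        rows.append({"location": cell_id, "regime": spec.regime,
                     "mean_wi": spec.mean_wi,
                     "gpp_sensitivity": spec.gpp_sensitivity,
                     "et_sensitivity": spec.et_sensitivity,
                     "lag_coefficient": spec.lag_coefficient,
                     "noise_sd": spec.noise_sd, "lat": lat, "lon": lon,
                     "seed": sub_seed})
    truth = pd.DataFrame(rows).set_index("location")
    return SyntheticDataset(climate=climate, fluxes=fluxes, anomalies=anomalies,
                            truth=truth, seed=seed, coords=coords)


def default_regime_map(cells_per_regime: int = 200,
                       regimes: dict[str, RegimeSpec] | None = None):
    """A regime map with ``cells_per_regime`` cells of each bundled regime."""
    regimes = DEFAULT_REGIMES if regimes is None else regimes
    return {f"{name}_{i:03d}": spec
            for name, spec in regimes.items()
            for i in range(cells_per_regime)}
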