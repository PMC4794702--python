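"""Readers, writers and run configuration.

Site data travel as monthly CSV (one row per month, fixed column names);
gridded data as CF-style NetCDF with dimensions (time, lat, lon), written
through xarray's scipy backend.  A :class:`RunConfig` captures everything a
pipeline run needs and hashes canonically for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .series import ClimateSeries, FluxSeries
from .synthetic import SyntheticDataset

#: CSV column -> (internal name, frame) for monthly site files.
MONTHLY_CSV_COLUMNS = {
    "precip_mm": "precip",
    "tair_c": "tair",
    "rn_mj_m2_d": "rn",
    "ea_kpa": "ea",
    "wind_m_s": "wind",
    "gpp_gc_m2": "gpp",
    "et_mm": "et",
}
_REQUIRED = ("year", "month") + tuple(MONTHLY_CSV_COLUMNS)


def read_monthly_csv(path, elevation: float = 0.0,
                     latitude: float = 0.0) -> tuple[ClimateSeries, FluxSeries]:
    """Load one site's monthly climate and flux series from CSV.

    Validates column presence, numeric cells, duplicate and missing months
    (reported as YYYY-MM), and non-negative precipitation.
    """
    raw = pd.read_csv(path, comment="#")
    missing_cols = [c for c in _REQUIRED if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing_cols)}")
    for col in _REQUIRED:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        if raw[col].isna().any() or len(bad):
            rows = list((raw.index[coerced.isna()] + 2))  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric or empty cell(s) in '{col}' at row(s) {rows}")
        raw[col] = coerced

    periods = pd.PeriodIndex.from_fields(year=raw["year"].astype(int),
                                         month=raw["month"].astype(int), freq="M")
    dup = periods[periods.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate month(s): {[str(p) for p in dup.unique()]}")
    expected = pd.period_range(periods.min(), periods.max(), freq="M")
    gaps = expected.difference(periods)
    if len(gaps):
        raise ValueError(f"{path}: missing month(s): {[str(p) for p in gaps]}")

    neg = raw.index[raw["precip_mm"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative precipitation at row(s) {list(neg + 2)}")

    frame = raw.rename(columns=MONTHLY_CSV_COLUMNS).set_index(periods).sort_index()
    climate = ClimateSeries(frame[["precip", "tair", "rn", "ea", "wind"]],
                            latitude=latitude, elevation=elevation)
    fluxes = FluxSeries(frame[["gpp", "et"]])
    return climate, fluxes


def write_monthly_csv(path, climate: ClimateSeries, fluxes: FluxSeries,
                      header: str | None = None) -> None:
    """Write one site's series in the layout :func:`read_monthly_csv` expects."""
    idx = climate.time
    out = pd.DataFrame({"year": idx.year, "month": idx.month})
    inverse = {v: k for k, v in MONTHLY_CSV_COLUMNS.items()}
    for name in ("precip", "tair", "rn", "ea", "wind"):
        out[inverse[name]] = climate.data[name].to_numpy()
    for name in ("gpp", "et"):
        out[inverse[name]] = fluxes.data[name].to_numpy()
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        out.to_csv(fh, index=False)


def grid_to_xarray(dataset: SyntheticDataset) -> xr.Dataset:
    """Arrange a generated dataset on its synthetic (time, lat, lon) grid."""
    ids = dataset.location_ids()
    lats = sorted({dataset.coords[i][0] for i in ids})
    lons = sorted({dataset.coords[i][1] for i in ids})
    any_climate = dataset.climate[ids[0]]
    time = any_climate.time.to_timestamp()
    shape = (len(time), len(lats), len(lons))
    data_vars = {}
    fields = [("precip", "climate"), ("tair", "climate"), ("rn", "climate"),
              ("ea", "climate"), ("wind", "climate"), ("gpp", "fluxes"),
              ("et", "fluxes")]
    lat_pos = {v: i for i, v in enumerate(lats)}
    lon_pos = {v: i for i, v in enumerate(lons)}
    for name, source in fields:
        arr = np.full(shape, np.nan)
        for cell_id in ids:
            la, lo = dataset.coords[cell_id]
            series = getattr(dataset, source)[cell_id].data[name]
            arr[:, lat_pos[la], lon_pos[lo]] = series.to_numpy()
        data_vars[name] = (("time", "lat", "lon"), arr)
    return xr.Dataset(data_vars,
                      coords={"time": time, "lat": lats, "lon": lons},
                      attrs={"seed": dataset.seed})


def write_grid_netcdf(ds: xr.Dataset, path) -> None:
    """Write a gridded dataset as NETCDF3 (scipy backend)."""
    ds.to_netcdf(path, engine="scipy")


def read_grid_netcdf(path) -> xr.Dataset:
    """Read a gridded dataset, normalising dimension order to (time, lat, lon)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        for coord in ("time", "lat", "lon"):
            if coord not in ds.coords:
                raise ValueError(f"{path}: missing coordinate variable '{coord}'")
        time = pd.DatetimeIndex(ds["time"].values)
        periods = time.to_period("M")
        expected = pd.period_range(periods[0], periods=len(periods), freq="M")
        if not periods.equals(expected):
            raise ValueError(f"{path}: time axis is not contiguous monthly")
        return ds.transpose("time", "lat", "lon", ...).load()


@dataclass
class RunConfig:
    """Everything one pipeline run needs; hashable for provenance."""

    out_dir: str = "droughtwue_out"
    seed: int = 0
    n_years: int = 30
    cells_per_regime: int = 200
    start_year: int = 1982
    index: str = "wi"                       # "wi" or "pdsi"
    detrend: bool = True
    site_alpha: float = 0.1
    grid_alpha: float = 0.05
    awc: float = 152.4
    calibration: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.index not in ("wi", "pdsi"):
            raise ValueError("index must be 'wi' or 'pdsi'")
        for name in ("site_alpha", "grid_alpha"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.calibration is not None:
            y0, y1 = self.calibration
            if not (self.start_year <= y0 <= y1 < self.start_year + self.n_years):
                raise ValueError("calibration window outside the data period")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("calibration") is not None:
            raw["calibration"] = tuple(raw["calibration"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        if d["calibration"] is not None:
            d["calibration"] = list(d["calibration"])
        return d

    def config_hash(self) -> str:
        d = self.as_dict()
        d.pop("out_dir")  # where results land does not change what they are
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
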