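import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import droughtwue as dw

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Master seed for every stochastic fixture in the suite.
SUITE_SEED = 7


@pytest.fixture(scope="session")
def arid_location():
    """One 30-year arid location (climate, fluxes, anomalies)."""
    return dw.generate_location(dw.DEFAULT_REGIMES["arid"], 30, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def small_dataset():
    """A small grid: 4 cells per regime, 30 years."""
    return dw.generate_grid(dw.default_regime_map(4), 30, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def regime_grid():
    """The full recovery grid: 200 cells per regime, 30 years."""
    return dw.generate_grid(dw.default_regime_map(200), 30, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def regime_results(regime_grid):
    """Per-cell analysis of the recovery grid against the wetness index."""
    return dw.analyze_dataset(regime_grid, index="wi", detrended=True, alpha=0.05)


def monthly_series(values, start_year=2000):
    idx = pd.period_range(f"{start_year}-01", periods=len(values), freq="M")
    return pd.Series(np.asarray(values, dtype=float), index=idx)
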