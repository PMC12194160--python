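import numpy as np
import pandas as pd
import pytest

from aviclim import simulate
from aviclim import timeseries as ts


@pytest.fixture(scope="session")
def default_config():
    return simulate.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def synthetic_tables(default_config):
    """One full synthetic dataset shared across tests (seed 7)."""
    rng = default_config.rng()
    climate = simulate.generate_climate(default_config, rng)
    cover = simulate.generate_vegetation(default_config, rng)
    counts = simulate.generate_counts(default_config, climate, cover, rng)
    nests = simulate.generate_nests(default_config, rng)
    return {"climate": climate, "cover": cover, "counts": counts, "nests": nests}


@pytest.fixture()
def flat_climate():
    """Three years of constant climate: tm 10, precip 10, spei 0.5."""
    years = np.repeat([2000, 2001, 2002], 12)
    months = np.tile(np.arange(1, 13), 3)
    return pd.DataFrame(
        {
            "year": years,
            "month": months,
            "tm": 10.0,
            "tmin": 5.0,
            "tmax": 15.0,
            "precip": 10.0,
            "spei": 0.5,
        }
    )


@pytest.fixture()
def month_index_climate():
    """tm equals the month number (1..12 repeating) over three years."""
    years = np.repeat([2000, 2001, 2002], 12)
    months = np.tile(np.arange(1, 13), 3)
    return pd.DataFrame(
        {
            "year": years,
            "month": months,
            "tm": months.astype(float),
            "tmin": months - 1.0,
            "tmax": months + 1.0,
            "precip": 10.0,
            "spei": 0.0,
        }
    )


def make_counts(species, years, value_fn):
    """Monthly count table where count = value_fn(year, month)."""
    rows = [
        (species, y, m, int(value_fn(y, m)))
        for y in years
        for m in range(1, 13)
    ]
    return pd.DataFrame(rows, columns=ts.COUNT_COLUMNS)
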