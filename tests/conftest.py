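import dataclasses

import numpy as np
import pandas as pd
import pytest

from ringpheno.ringchron import RingSeries
from ringpheno.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 10 populations, ~3 trees each, 60 SNPs."""
    return dataclasses.replace(
        SimConfig(seed=11),
        n_populations=10,
        trees_per_population_mean=3.0,
        trees_per_population_sd=0.5,
        n_snps=60,
        n_causal_snps=2,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size synthetic dataset shared across tests."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture
def flat_rings():
    """Three trees with constant ring widths (no trend, no signal)."""
    years = np.arange(1990, 2015)
    return [
        RingSeries(f"T{i}", "P1", 1 + i % 2, years, np.full(years.size, 2.0 + 0.1 * i))
        for i in range(3)
    ]


@pytest.fixture
def daily_july():
    """A fully covered July with constant weather."""
    dates = pd.date_range("2000-07-01", "2000-07-31", freq="D")
    return pd.DataFrame(
        {"date": dates, "tmean_C": 20.0, "tmin_C": 10.0, "prec_mm": 0.0}
    )
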