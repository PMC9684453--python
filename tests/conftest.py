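import numpy as np
import pandas as pd
import pytest

from phenoescape import (
    MCMCConfig,
    SyntheticConfig,
    simulate_grids,
    simulate_monthly,
    simulate_records,
)

SMALL_MCMC = MCMCConfig(n_chains=2, n_iter=1500, n_burnin=500, thin=2, seed=7)


@pytest.fixture(scope="session")
def sim_config():
    return SyntheticConfig(n_species=6, n_per_species=200, seed=11)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    """A medium synthetic dataset (1200 records) shared across tests."""
    return simulate_records(sim_config)


@pytest.fixture(scope="session")
def sim_monthly(sim_config, sim_data):
    recordset, _ = sim_data
    return simulate_monthly(sim_config, recordset)


@pytest.fixture(scope="session")
def fixture_grids():
    return simulate_grids(
        extent=(-90.0, -70.0, 38.0, 52.0), resolution=1.0, scenario_delta=5.0
    )


@pytest.fixture()
def records_csv(tmp_path):
    """A tiny well-formed specimen CSV on disk."""
    df = pd.DataFrame(
        {
            "record_id": ["r1", "r2", "r3"],
            "species": ["Acer_a", "Acer_a", "Quercus_b"],
            "stratum": ["tree", "tree", "tree"],
            "continent": ["NorthAmerica"] * 3,
            "lat": [42.0, 43.5, 41.2],
            "lon": [-75.0, -76.1, -74.3],
            "elev_m": [210.0, 150.0, 320.0],
            "year": [1950, 2001, 1988],
            "doy": [120, 112, 131],
            "spring_temp_c": [6.5, 8.1, 4.2],
        }
    )
    path = tmp_path / "records.csv"
    df.to_csv(path, index=False)
    return path, df
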