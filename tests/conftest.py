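import numpy as np
import pandas as pd
import pytest

import tricoord as tc
from tricoord import weights as wmod


@pytest.fixture(scope="session")
def geography():
    cent, adj = tc.default_geography()
    return cent, adj


@pytest.fixture(scope="session")
def w_queen(geography):
    cent, adj = geography
    return wmod.from_adjacency(adj, list(cent.index), row_standardize=True,
                               centroids=cent)


@pytest.fixture(scope="session")
def w_dist(geography):
    cent, _ = geography
    return wmod.from_centroids(cent, kind="inverse_distance")


@pytest.fixture(scope="session")
def sim_config():
    return tc.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def indicator_panel(sim_config):
    panel, gt = tc.generate_indicator_panel(sim_config)
    return panel, gt


@pytest.fixture(scope="session")
def subsystem_scores(sim_config, indicator_panel):
    panel, _ = indicator_panel
    schema = tc.IndicatorSchema(sim_config.indicator_schema)
    return tc.SubsystemIndex(schema).fit(panel).scores_


@pytest.fixture(scope="session")
def ccd_panel(subsystem_scores):
    rec = tc.CouplingCoordination().fit(subsystem_scores).transform(subsystem_scores)
    return rec


def unit_year_index(n_units: int, n_years: int, start_year: int = 2013):
    units = [f"U{i:02d}" for i in range(n_units)]
    years = [start_year + t for t in range(n_years)]
    return pd.MultiIndex.from_product([units, years], names=["unit", "year"])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
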