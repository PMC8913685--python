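import numpy as np
import pytest

from beechgrow.climate import aggregate_seasons, site_mean_ai
from beechgrow.model import ModelSpec, build_design, fit_glmm
from beechgrow.ringio import network_bai_table
from beechgrow.synthetic import generate_network

#: compact vocabulary for functional tests (fits in a couple of seconds)
SMALL_SPEC = ModelSpec(seasons=("SPR", "SUM"), interaction_mode="linear")


@pytest.fixture(scope="session")
def small_network():
    return generate_network(
        n_sites=12,
        trees_per_site=2,
        year_range=(1987, 2016),
        climate_range=(1950, 2016),
        seed=4242,
    )


@pytest.fixture(scope="session")
def small_seasonal(small_network):
    return aggregate_seasons(small_network.climate)


@pytest.fixture(scope="session")
def small_bai(small_network):
    return network_bai_table(small_network.rings)


@pytest.fixture(scope="session")
def small_design(small_network, small_seasonal, small_bai):
    return build_design(small_bai, small_seasonal, small_network.sites, SMALL_SPEC)


@pytest.fixture(scope="session")
def small_fit(small_design):
    return fit_glmm(small_design, max_outer=250)
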