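import numpy as np
import pytest

from seaconnect.fixtures import FixtureConfig, make_genotypes, make_velocity_field, make_sites


@pytest.fixture
def small_config():
    return FixtureConfig(
        seed=11,
        grid_extent=(-2.0, 2.0, -2.0, 2.0),
        grid_step=0.25,
        n_days=40,
        n_pops=2,
        pop_names=("North", "South"),
        n_ind_per_pop=(30, 30),
        n_loci=100,
        fst_target=0.1,
    )


@pytest.fixture
def two_pop_genotypes(small_config):
    return make_genotypes(small_config)


@pytest.fixture
def zero_field(small_config):
    return make_velocity_field(small_config, "zero")


@pytest.fixture
def uniform_east_field(small_config):
    return make_velocity_field(small_config, "uniform", {"u": 0.1, "v": 0.0})


@pytest.fixture
def one_site(zero_field, small_config):
    return make_sites(small_config, [("A", -1.0, 0.0, 9.0, (2, 6))], field=zero_field)[0]


@pytest.fixture
def study_design_config():
    """Dimensions of the study dataset: 6 localities, 87 samples, 1534 loci."""
    return FixtureConfig(seed=2, n_loci=1534, fst_target=0.02, missing_rate=0.01)
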