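import numpy as np
import pytest

from diffenh.simulate import ScenarioConfig, make_genome, simulate_mark_tracks


SMALL_SCENARIO = dict(
    genome_length=2_000_000,
    n_genes=60,
    n_enhancers=200,
    n_activated=20,
    seed=7,
)


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(**SMALL_SCENARIO)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_genome(small_config)


@pytest.fixture(scope="session")
def small_tracks(small_truth, small_config):
    return simulate_mark_tracks(small_truth, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
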