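import numpy as np
import pytest

from spinemark.synthetic_spine import SpineSimConfig, simulate_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_config():
    return SpineSimConfig(seed=0)


@pytest.fixture(scope="session")
def sim_records(sim_config):
    """A dozen simulated radiographs shared across tests."""
    return [
        simulate_image(sim_config, np.random.default_rng(5000 + i), f"fix_{i:03d}")
        for i in range(12)
    ]
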