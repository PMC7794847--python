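import numpy as np
import pytest

from ivmquant.simulator import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20210105)


@pytest.fixture
def small_config():
    """Desk-scale session config used across tests (keeps suites fast)."""
    return SimulationConfig(image_shape=(48, 63))


@pytest.fixture
def noiseless_config():
    """Flat uptake field, no noise: the analytically invertible session."""
    return SimulationConfig(image_shape=(48, 63), shot_noise=False, texture_sd=0.0)
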