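import numpy as np
import pytest
from hypothesis import settings

from clockhsc.simulate import SimulationConfig, simulate_all

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noise_free_sim():
    """One seed of noise-free fixtures: planted structure is exact."""
    return simulate_all(SimulationConfig(seed=1, expression_noise_sd=0.0))


@pytest.fixture(scope="session")
def default_sim():
    """One seed at the default (noisy) study conditions."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
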