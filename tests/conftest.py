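import numpy as np
import pytest

from poromech.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def noise_free_config():
    return SimulationConfig(seed=0, noise_cv=0.0, probe_noise_sd=0.0)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=0)
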