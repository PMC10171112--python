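import numpy as np
import pandas as pd
import pytest

from soilcue import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def noise_free_study():
    """Small noise-free study: derived quantities equal planted truths."""
    cfg = SimulationConfig(noise_sd=0.0, seed=11, n_asvs_bacteria=40,
                           n_asvs_fungi=30)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """Default 20-site study with measurement noise."""
    return generate_study(SimulationConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
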