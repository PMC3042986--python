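import numpy as np
import pytest
from hypothesis import settings

from shootmass.synthetic import GrowthSimConfig, simulate_growth_dataset

settings.register_profile("shootmass", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("shootmass")

SEED = 20110201


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated harvest experiment (320 plants) plus its ground truth."""
    return simulate_growth_dataset()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Zero-noise simulation: SDW is exactly area x (b0 + b1 x age)."""
    cfg = GrowthSimConfig(noise_sd_g=0.0)
    return simulate_growth_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
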