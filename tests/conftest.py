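import numpy as np
import pytest

from bbbkinetics.synthetic import (
    DEFAULT_SERUM,
    ExperimentConfig,
    serum_means,
)


@pytest.fixture
def noiseless_config():
    return ExperimentConfig(noise_cv=0.0, rng_seed=0)


@pytest.fixture
def default_means(noiseless_config):
    """Noiseless biexponential serum means on the 5-60 min schedule."""
    return serum_means(DEFAULT_SERUM, noiseless_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20140825)
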