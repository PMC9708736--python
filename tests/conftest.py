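import numpy as np
import pytest

from celmfuse import RunConfig, make_training_set, train_celm


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_model(config):
    """A quickly trained model for pipeline tests (not the full protocol)."""
    return train_celm(make_training_set(120, config, seed=0), config)


@pytest.fixture(scope="session")
def trained_model(config):
    """The canonical training protocol: 500 pairs, sigma in [2,4], seed 0."""
    return train_celm(make_training_set(500, config, seed=0), config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
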