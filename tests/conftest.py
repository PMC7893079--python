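import numpy as np
import pytest

from adspeech.evaluation import prepare_inputs
from adspeech.synthetic_data import SimConfig, simulate_cohort, simulate_resources


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A small but structurally complete cohort configuration."""
    return SimConfig(n_train_per_class=8, n_test_per_class=4,
                     n_acoustic_features=20, segment_mean=12, segment_sd=4,
                     seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_resources(tiny_config):
    return simulate_resources(tiny_config)


@pytest.fixture(scope="session")
def tiny_data(tiny_cohort, tiny_resources):
    return prepare_inputs(tiny_cohort, tiny_resources, max_len=48)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
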