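import logging

import numpy as np
import pytest

import defol
from defol.datatypes import RunConfig

logging.getLogger("defol").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def pn_preset():
    return defol.make_preset("PN")


@pytest.fixture(scope="session")
def sd_preset():
    return defol.make_preset("SD")


@pytest.fixture(scope="session")
def noise_free_experiment():
    """Both ecotypes, observations exactly on the generating curves."""
    return defol.simulate_experiment(noise_cv=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_experiment():
    """Both ecotypes with 5 % lognormal observation noise."""
    return defol.simulate_experiment(noise_cv=0.05, seed=7)


@pytest.fixture(scope="session")
def fast_config():
    return RunConfig(n_permutations=0)


@pytest.fixture(scope="session")
def noise_free_result(noise_free_experiment, fast_config):
    """Full growth pipeline on the noise-free experiment (no permutations)."""
    return defol.analyze(noise_free_experiment.observations, None, fast_config)


@pytest.fixture(scope="session")
def noisy_result(noisy_experiment, fast_config):
    return defol.analyze(noisy_experiment.observations, None, fast_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
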