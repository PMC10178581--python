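import numpy as np
import pytest

import residuecast as rc


@pytest.fixture(scope="session")
def noiseless_decay_dataset():
    """Noiseless first-order decay for one pesticide under three
    temperatures, split 7:2:1 chronologically."""
    params = {"dimethoate": rc.KineticParams(
        initial_concentration=0.055, base_rate=0.02,
        temp_sensitivity=0.06, humidity_sensitivity=0.01, noise_sd=0.0)}
    conditions = [rc.StorageCondition(10, 65), rc.StorageCondition(25, 65),
                  rc.StorageCondition(35, 65)]
    dataset = rc.build_dataset(params, conditions, n_days=90, seed=3)
    return rc.split_dataset(dataset)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """Default kinetics, reduced grid, with assay noise."""
    dataset = rc.build_dataset(rc.default_kinetic_params(),
                               rc.DEFAULT_CONDITIONS[:3], n_days=60, seed=1)
    return rc.split_dataset(dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
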