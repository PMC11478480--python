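import copy

import numpy as np
import pytest

import gaitphase as gp


@pytest.fixture(scope="session")
def cohort():
    return gp.make_cohort(3, 7)


@pytest.fixture(scope="session")
def small_scripts():
    return gp.default_scripts(strides_level=8, strides_seg=4)


@pytest.fixture(scope="session")
def noiseless_profile(cohort):
    p = copy.deepcopy(cohort[0])
    p.noise_sd = 0.0
    p.jitter_sd_ms = 0.0
    return p


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_profile, small_scripts):
    return gp.simulate_trial(noiseless_profile, small_scripts[1], trial_index=1, seed=3)


@pytest.fixture(scope="session")
def tiny_dataset(small_scripts):
    """2 subjects x 3 scenarios x 3 trials of short walking."""
    cohort = gp.make_cohort(2, 11)
    return gp.simulate_protocol(cohort, small_scripts, trials_per_script=3)


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return gp.make_split(tiny_dataset, test_trial_index=3, val_fraction=0.2)


@pytest.fixture(scope="session")
def tiny_stats(tiny_split):
    return gp.fit_norm_stats(tiny_split.train_recordings)
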