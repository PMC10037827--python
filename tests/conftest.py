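import numpy as np
import pytest

import symnetmap as sn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return sn.generate_cohort(sn.zero_noise_config(7))


@pytest.fixture(scope="session")
def small_cohort():
    """A modest noisy cohort shared across tests that only need plumbing."""
    cfg = sn.strong_recovery_config(11, n_hc=25, n_amci=25, n_timepoints=120)
    return sn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fc(small_cohort):
    return sn.build_fc_matrices(small_cohort.timeseries, small_cohort.node_names)
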