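import numpy as np
import pytest

import icfilter as icf


@pytest.fixture(scope="session")
def band():
    return icf.BandConfig()


@pytest.fixture(scope="session")
def reference_thresholds():
    return icf.FilterThresholds(p_moco_crit=1e-17, p_pow_crit=1e-8)


@pytest.fixture(scope="session")
def small_cohort():
    """Three-subject default-regime cohort, shared across tests."""
    return icf.simulate_cohort(icf.CohortConfig(n_subjects=3, seed=11))


@pytest.fixture(scope="session")
def one_subject(small_cohort):
    return small_cohort[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
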