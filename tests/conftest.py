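import numpy as np
import pytest

from fsrcop import SubjectProfile, default_layout, make_cohort


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def identity_profile():
    return SubjectProfile.identity()


@pytest.fixture(scope="session")
def identity_trialset():
    """One noise-free, ideal-sensor subject (6 tasks x 3 trials)."""
    return make_cohort(1, master_seed=101, identity_profiles=True)[0]


@pytest.fixture(scope="session")
def default_trialset():
    """One subject under the default imperfect-sensor conditions."""
    return make_cohort(1, master_seed=202)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
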