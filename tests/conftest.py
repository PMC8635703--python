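import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A 260-subject default-condition cohort shared across tests."""
    from resilnet.synthetic import SyntheticConfig, generate_cohort

    return generate_cohort(SyntheticConfig(n_subjects=260, seed=7))


@pytest.fixture(scope="session")
def small_design(small_cohort):
    from resilnet.preprocess import preprocess_design

    return preprocess_design(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
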