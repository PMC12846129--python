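import numpy as np
import pytest

from gradefuse.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-patient cohort used by tests that only need structure."""
    return generate_cohort(PhantomConfig(n_patients=24, volume_shape=(16, 16, 16),
                                         seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
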