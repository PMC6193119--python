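import numpy as np
import pytest

from dynconn.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small fixed-seed cohort shared by read-only tests."""
    cfg = SyntheticCohortConfig(n_per_group=5, p=6, t=300, k_states=2,
                                dwell_mean=30, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
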