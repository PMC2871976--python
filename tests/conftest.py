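import numpy as np
import pytest

from rvrmap import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """15 subjects on a 16^3 grid, default noise — quick fits."""
    spec = CohortSpec(
        n_ad=5, n_mci=5, n_cn=5, grid_shape=(16, 16, 16), rng_seed=11
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def clean_cohort():
    """30 subjects, zero score noise — strong-signal regime."""
    spec = CohortSpec(
        n_ad=10, n_mci=10, n_cn=10, grid_shape=(16, 16, 16),
        noise_sd=0.0, rng_seed=5,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
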