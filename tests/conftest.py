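import numpy as np
import pytest

from cascnet.simulate import default_affine, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort shared across tests (seed 0)."""
    volumes, table, truth = generate_cohort(random_seed=0)
    return volumes, table, truth


@pytest.fixture
def small_grid():
    shape = (16, 18, 16)
    return shape, default_affine(shape)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
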