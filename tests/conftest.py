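import numpy as np
import pytest

from wmnet import generate_cohort
from wmnet.pipeline import PipelineConfig, connectivity_matrices


@pytest.fixture(scope="session")
def cohort66():
    """Small default-parameter cohort shared across tests (6 per group)."""
    return generate_cohort(n_per_group=6, seed=11)


@pytest.fixture(scope="session")
def zmats66(cohort66):
    """Fisher-z partial-correlation matrices for the shared cohort."""
    return connectivity_matrices(cohort66, PipelineConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_symmetric(n: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((n, n))
    z = (a + a.T) / 2
    np.fill_diagonal(z, 0.0)
    return z
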