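import numpy as np
import pytest

from brainphen.cohort import generate_cohort
from brainphen.config import CohortConfig
from brainphen.prep import prepare


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def cohort_and_truth(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def prepared(cohort_and_truth):
    cohort, _ = cohort_and_truth
    return prepare(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_weighted_graph(rng, n, p=0.4, lo=0.1, hi=1.0):
    """Symmetric nonnegative weight matrix with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(float)
    w = rng.uniform(lo, hi, (n, n))
    m = np.triu(a * w, 1)
    return m + m.T
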