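import numpy as np
import pytest
from hypothesis import settings

from sulfomics import esom, kmer, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sample():
    """The default 5-genome community, seed 42 (shared: expensive to build)."""
    return synthetic.default_community(42)


@pytest.fixture(scope="session")
def default_profile(default_sample):
    matrix, meta = kmer.profile_matrix(default_sample.contigs)
    return matrix, meta


@pytest.fixture(scope="session")
def default_grid(default_profile):
    matrix, _ = default_profile
    return esom.train(matrix, seed=42)


@pytest.fixture(scope="session")
def two_cluster_data():
    """Two spherical Gaussian clusters with centers 10 sigma apart."""
    rng = np.random.default_rng(7)
    sigma = 0.05
    c0 = np.zeros(8)
    c1 = np.full(8, 10 * sigma / np.sqrt(8))  # ||c1 - c0|| = 10 sigma
    x = np.vstack(
        [
            c0 + sigma * rng.normal(size=(100, 8)),
            c1 + sigma * rng.normal(size=(100, 8)),
        ]
    )
    labels = np.array([0] * 100 + [1] * 100)
    return x, labels
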