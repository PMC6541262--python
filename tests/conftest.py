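import numpy as np
import pytest

from cultshare.data import builtin_fixture, encode_practices
from cultshare.dissimilarity import pairwise_hamming_vector
from cultshare.synthetic import attach_synthetic_covariates


@pytest.fixture(scope="session")
def fixture_dataset():
    return builtin_fixture()


@pytest.fixture(scope="session")
def fixture_matrix(fixture_dataset):
    return encode_practices(fixture_dataset)


@pytest.fixture(scope="session")
def fixture_hamming(fixture_matrix):
    return pairwise_hamming_vector(fixture_matrix)


@pytest.fixture(scope="session")
def joined_fixture(fixture_dataset):
    """The practice inventory with synthetic coordinates and covariates joined."""
    return attach_synthetic_covariates(fixture_dataset, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
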