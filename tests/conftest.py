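import numpy as np
import pytest

from shapescale import DataMatrix, corrected_iris, standardized_sq_diffs


@pytest.fixture(scope="session")
def iris():
    """Corrected Iris matrix and species labels."""
    return corrected_iris()


@pytest.fixture(scope="session")
def iris_rho2(iris):
    data, _ = iris
    return standardized_sq_diffs(data)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_data_matrix(rng, n=12, d=3):
    """Duplicate-free random DataMatrix (continuous draws are a.s. unique)."""
    return DataMatrix.from_array(rng.normal(size=(n, d)))


@pytest.fixture
def small_data(rng):
    return random_data_matrix(rng)
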