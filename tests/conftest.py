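import numpy as np
import pytest

from gpspbs.data_model import PSPT_GROUP
from gpspbs.scoring import SubstitutionMatrix
from gpspbs.synthetic import generate_benchmark, motif_14_3_3


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def motif_benchmark():
    """A separable 14-3-3-like benchmark: 60 positives, 5x negatives."""
    return generate_benchmark(motif_14_3_3(), 60, 5.0, seed=11)


@pytest.fixture(scope="session")
def small_gaussian_data():
    """Two linearly separable Gaussian clusters in the 231-dim input space."""
    rng = np.random.default_rng(7)
    n = 120
    center = np.zeros(231)
    center[:10] = 2.0
    X = np.vstack([rng.normal(0, 1, (n, 231)) + center,
                   rng.normal(0, 1, (n, 231)) - center])
    y = np.r_[np.ones(n, int), np.zeros(n, int)]
    return X, y
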