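import warnings

import numpy as np
import pytest

from dogcog.cohort_data import CognitiveMeasureMatrix


@pytest.fixture(autouse=True)
def _quiet_convergence():
    """Silence estimator convergence chatter in bulk simulation tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_matrix(values, dog_ids=None, measure_names=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    dog_ids = dog_ids or [f"d{i}" for i in range(n)]
    measure_names = measure_names or [f"m{j}" for j in range(m)]
    return CognitiveMeasureMatrix(dog_ids, measure_names, values,
                                  ~np.isfinite(values))


@pytest.fixture
def matrix_factory():
    return make_matrix
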