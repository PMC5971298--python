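import numpy as np
import pytest

from warfrev.cohort import default_spec_from_tables, generate_cohort, inject_missingness
from warfrev.preprocessing import ColumnInfo, DesignMatrix


@pytest.fixture(scope="session")
def default_spec():
    return default_spec_from_tables(n_patients=150, seed=7)


@pytest.fixture(scope="session")
def cohort150(default_spec):
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def cohort150_missing(default_spec, cohort150):
    return inject_missingness(cohort150, default_spec.missingness_rates, seed=8)


def make_matrix(X, y, names=None):
    """Wrap plain arrays as a DesignMatrix with continuous columns."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    cols = [ColumnInfo(nm, nm, None, None, None, None) for nm in names]
    return DesignMatrix(X, cols, [f"r{i}" for i in range(n)], np.asarray(y, dtype=float))


@pytest.fixture
def matrix_factory():
    return make_matrix
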