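import numpy as np
import pytest

import spatmiss as sm
from spatmiss.data_io import RegionDataset


@pytest.fixture(scope="session")
def grid3x3():
    return sm.make_grid_lattice(3, 3)


@pytest.fixture(scope="session")
def study_data():
    """One seeded study-condition dataset with block missingness."""
    data, truth = sm.make_study_dataset(seed=7)
    return data, truth


@pytest.fixture(scope="session")
def complete_study_data():
    data, truth = sm.make_study_dataset(seed=7, missingness=False)
    return data, truth


def make_dataset(X, lattice=None, Y=None, n=None, names=None):
    """Small helper to build a RegionDataset from a raw covariate matrix."""
    X = np.asarray(X, dtype=float)
    N, p = X.shape
    names = tuple(names) if names else tuple(f"c{j}" for j in range(p))
    ids = tuple(lattice.region_ids) if lattice is not None else tuple(f"R{i}" for i in range(N))
    return RegionDataset(
        region_ids=ids,
        Y=np.full(N, 1.0) if Y is None else np.asarray(Y, dtype=float),
        n=np.full(N, 100) if n is None else np.asarray(n),
        X=X,
        mask=np.isnan(X),
        covariate_names=names,
        lattice=lattice,
    )
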