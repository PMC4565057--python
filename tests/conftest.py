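import numpy as np
import pytest

import betaconn as bc


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated session (4 conditions, 4 regions) shared by tests
    that only read from it."""
    spec = bc.SimulationSpec(grid_shape=(8, 8, 4), n_regions=4, seed=42)
    return bc.simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """Design + OLS estimates for the shared dataset."""
    ds = small_dataset
    design = bc.build_design(
        ds.events, ds.confounds, [r.n_scans for r in ds.runs], ds.spec.tr
    )
    est = bc.fit_ols(ds.runs, design, ds.mask)
    return design, est


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_correlated_columns(R, m=24, seed=0):
    """Columns with EXACT sample correlation matrix R (mean 0): orthonormal
    basis orthogonal to the constant vector, mixed by the Cholesky factor."""
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((m, n + 1))
    A[:, 0] = 1.0  # first basis vector spans the constant -> rest are centered
    Q, _ = np.linalg.qr(A)
    U = Q[:, 1 : n + 1]
    L = np.linalg.cholesky(R)
    return U @ L.T
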