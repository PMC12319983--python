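import numpy as np
import pytest

import dwimoco as dm


@pytest.fixture(scope="session")
def phantom():
    return dm.make_phantom(dm.PhantomSpec())


@pytest.fixture(scope="session")
def scheme95():
    """The recommended 2-shell acquisition: 11 b=0, 28 @ b400, 56 @ b900."""
    return dm.design_scheme(11, [(400.0, 28), (900.0, 56)], seed=1)


@pytest.fixture(scope="session")
def small_scheme():
    """A cheap multi-shell scheme for plumbing tests."""
    return dm.design_scheme(
        3, [(400.0, 6), (900.0, 12)], seed=7, n_restarts=3, n_iter=60
    )


@pytest.fixture(scope="session")
def dense_q_points():
    """Well-conditioned q-space sampling spanning the radial range of the
    order-6 basis at zeta = 700 (8 shells x 48 directions)."""
    rng = np.random.default_rng(11)
    dirs = rng.standard_normal((48, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bs = [0.0, 350.0, 840.0, 1540.0, 2450.0, 3640.0, 5250.0, 7350.0, 9800.0]
    return np.concatenate([np.sqrt(b) * dirs for b in bs])


@pytest.fixture(scope="session")
def small_series(phantom, small_scheme):
    series, truth = dm.simulate_series(
        phantom, small_scheme.in_temporal_order(),
        dm.CorruptionSpec(sigma=1.0, seed=5),
    )
    return series, truth
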