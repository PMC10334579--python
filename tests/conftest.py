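import numpy as np
import pytest

from cmot.matrix import ModalityMatrix
from cmot.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_matrix(rng):
    return ModalityMatrix(rng.normal(size=(12, 6)))


@pytest.fixture
def curve_matrix():
    """Cells sampled along a smooth 1-D manifold (spectral tests)."""
    t = np.linspace(0, 1, 30) ** 1.4 * 3  # nonuniform: no graph automorphism
    return ModalityMatrix(np.c_[np.cos(t), np.sin(t), t])


@pytest.fixture
def grid_manifold():
    """Jittered 2-D grid bent into 3-D: twin-free K-NN graph with smooth
    low-frequency spectrum (identity-matching tests)."""
    r = np.random.default_rng(1)
    gx, gy = np.meshgrid(np.arange(6), np.arange(5))
    pts = np.c_[gx.ravel(), gy.ravel()].astype(float)
    pts += 0.25 * r.normal(size=pts.shape)
    return ModalityMatrix(np.c_[pts, 0.1 * pts[:, 0] ** 2])


@pytest.fixture(scope="session")
def small_synthetic():
    """One low-noise two-cluster draw shared across pipeline tests."""
    return generate(SyntheticSpec(n_source=80, n_target=40, seed=7))
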