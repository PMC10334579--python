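"""Coupled two-modality synthetic single-cell data with known ground truth.

Cells live on a shared low-dimensional latent manifold with cluster
(cell-type) structure; each modality observes a fixed random linear map of
a pointwise nonlinearity of the latent coordinates plus Gaussian noise.
Target cells are drawn from the same process, with one modality observed
and the other held out as ground truth — exactly the structure a
cross-modality inference method assumes.

All randomness uses the counter-based Philox generator so fixtures are
bit-reproducible across platforms for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import CorrespondenceMap, full_correspondence
from .matrix import ModalityMatrix

__all__ = ["SyntheticSpec", "SyntheticData", "generate", "plant_outliers"]

_NONLINEARITIES = {
    "linear": lambda z: z,
    "tanh": np.tanh,
    "quadratic": lambda z: z + 0.5 * z**2,
}


@dataclass
class SyntheticSpec:
    """Generator parameters.

    Defaults describe the regime used throughout the test-bench: 200 source
    and 100 target cells in 2 well-separated clusters on a 4-dimensional
    latent manifold, 30 observed features per modality, tanh observation
    maps and modest additive noise (sd 0.1 against unit-scale latents).
    """

    n_source: int = 200
    n_target: int = 100
    n_clusters: int = 2
    latent_dim: int = 4
    d_X: int = 30
    d_Y: int = 30
    noise_sd: float = 0.1
    nonlinearity: str = "tanh"
    dropout_rate: float = 0.0
    cluster_sep: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_source", "n_target", "n_clusters", "latent_dim",
                     "d_X", "d_Y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.latent_dim >= min(self.d_X, self.d_Y):
            raise ValueError(
                f"latent_dim={self.latent_dim} must be < "
                f"min(d_X, d_Y)={min(self.d_X, self.d_Y)}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.nonlinearity not in _NONLINEARITIES:
            raise ValueError(
                f"nonlinearity must be one of {sorted(_NONLINEARITIES)}"
            )


@dataclass
class SyntheticData:
    """One draw from the generator, with held-out ground truth."""

    X: ModalityMatrix
    Y: ModalityMatrix
    Yhat: ModalityMatrix
    Xhat_true: ModalityMatrix
    labels_source: np.ndarray
    labels_target: np.ndarray
    full_pairs: CorrespondenceMap
    latent_source: np.ndarray
    latent_target: np.ndarray


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw coupled modalities X, Y for source cells and (Yhat, Xhat_true)
    for target cells from a shared clustered latent manifold."""
    rng = np.random.Generator(np.random.Philox(spec.seed))
    f = _NONLINEARITIES[spec.nonlinearity]

    centers = rng.standard_normal((spec.n_clusters, spec.latent_dim))
    centers *= spec.cluster_sep
    A_X = rng.standard_normal((spec.latent_dim, spec.d_X)) / np.sqrt(
        spec.latent_dim
    )
    A_Y = rng.standard_normal((spec.latent_dim, spec.d_Y)) / np.sqrt(
        spec.latent_dim
    )

    def draw(n: int, prefix: str):
        labels = rng.integers(0, spec.n_clusters, size=n)
        z = centers[labels] + rng.standard_normal((n, spec.latent_dim))
        x = f(z) @ A_X + spec.noise_sd * rng.standard_normal((n, spec.d_X))
        y = f(z) @ A_Y + spec.noise_sd * rng.standard_normal((n, spec.d_Y))
        if spec.dropout_rate > 0:
            x = x * (rng.random(x.shape) >= spec.dropout_rate)
            y = y * (rng.random(y.shape) >= spec.dropout_rate)
        cells = [f"{prefix}{i}" for i in range(n)]
        return labels, z, x, y, cells

    lab_s, z_s, x_s, y_s, cells_s = draw(spec.n_source, "src")
    lab_t, z_t, x_t, y_t, cells_t = draw(spec.n_target, "tgt")

    feats_X = [f"gx{j}" for j in range(spec.d_X)]
    feats_Y = [f"gy{j}" for j in range(spec.d_Y)]
    return SyntheticData(
        X=ModalityMatrix(x_s, cells_s, feats_X, "other"),
        Y=ModalityMatrix(y_s, cells_s, feats_Y, "other"),
        Yhat=ModalityMatrix(y_t, cells_t, feats_Y, "other"),
        Xhat_true=ModalityMatrix(x_t, cells_t, feats_X, "other"),
        labels_source=lab_s,
        labels_target=lab_t,
        full_pairs=full_correspondence(spec.n_source),
        latent_source=z_s,
        latent_target=z_t,
    )


def plant_outliers(
    Yhat: ModalityMatrix, fraction: float, amplitude: float, seed: int
) -> tuple[ModalityMatrix, np.ndarray]:
    """Replace ceil(fraction * n) target cells with pure Gaussian noise.

    Emulates target cells from a population absent in the source data;
    returns the corrupted matrix and the planted-cell mask.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    rng = np.random.Generator(np.random.Philox(seed))
    n = Yhat.n_cells
    n_plant = int(np.ceil(fraction * n))
    idx = rng.choice(n, size=n_plant, replace=False)
    vals = Yhat.values.copy()
    vals[idx, :] = amplitude * rng.standard_normal((n_plant, Yhat.n_features))
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return Yhat.with_values(vals), mask
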