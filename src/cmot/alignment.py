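"""Nonlinear manifold alignment of two partially corresponding modalities.

Two source modalities X and Y measured on (partially) the same cells are
projected onto a shared d-dimensional manifold. Within-modality geometry is
encoded by K-nearest-neighbor graphs W_X, W_Y; known cell-to-cell pairings by
a binary correspondence matrix W. The joint embedding minimizes

    mu * sum_ik |phi_X(x_i) - phi_X(x_k)|^2 W_X[i,k]
  + mu * sum_jm |phi_Y(y_j) - phi_Y(y_m)|^2 W_Y[j,m]
  + (1 - mu) * sum_ij |phi_X(x_i) - phi_Y(y_j)|^2 W[i,j]

subject to P^T D P = I, where P stacks the X embedding over the Y embedding
and D is the degree diagonal of the joint graph. The solution is the
generalized eigenproblem L v = gamma D v on the joint graph Laplacian
L = D - W_joint; trivial near-zero components are discarded and the next d
eigenvectors form the embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph
from scipy.spatial.distance import cdist

from .matrix import ModalityMatrix

__all__ = [
    "CorrespondenceMap",
    "SimilarityGraph",
    "JointEmbedding",
    "full_correspondence",
    "build_knn_similarity",
    "correspondence_matrix",
    "subsample_correspondence",
    "align",
    "match_aligned",
]

#: relative eigenvalue threshold below which a component is treated as the
#: trivial (constant-per-component) null direction and dropped
_NULL_EIGENVALUE_RTOL = 1e-9


@dataclass
class CorrespondenceMap:
    """Known cell-to-cell pairings between modality X and modality Y.

    ``pairs`` holds (x_cell_index, y_cell_index) tuples; ``p`` records the
    fraction of cells for which correspondence is assumed available.
    """

    pairs: list[tuple[int, int]]
    p: float = 1.0

    def __post_init__(self) -> None:
        xs = [i for i, _ in self.pairs]
        ys = [j for _, j in self.pairs]
        if len(set(xs)) != len(xs) or len(set(ys)) != len(ys):
            raise ValueError("a cell index appears in more than one pair")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p={self.p} not in [0, 1]")


def full_correspondence(n: int) -> CorrespondenceMap:
    """Identity pairing on ``n`` jointly profiled cells (p = 100%)."""
    return CorrespondenceMap([(i, i) for i in range(n)], p=1.0)


@dataclass
class SimilarityGraph:
    """Symmetric binary K-NN adjacency over the cells of one modality."""

    weights: np.ndarray
    k_neighbors: int


@dataclass
class JointEmbedding:
    """Aligned coordinates of both modalities plus solver diagnostics."""

    coords_X: np.ndarray
    coords_Y: np.ndarray
    eigenvalues: np.ndarray
    mu: float
    objective: float
    n_components_dropped: int = 0
    degree: np.ndarray | None = field(default=None, repr=False)


def build_knn_similarity(m: ModalityMatrix, K: int) -> SimilarityGraph:
    """Binary K-nearest-neighbor graph, symmetrized by max(A, A^T).

    Neighbors ranked by Euclidean distance; ties broken by lower cell index
    (stable argsort), so duplicate cells are linked first.
    """
    n = m.n_cells
    if K >= n:
        raise ValueError(f"K={K} must be < n_cells={n}")
    d = cdist(m.values, m.values)
    np.fill_diagonal(d, np.inf)
    adj = np.zeros((n, n))
    order = np.argsort(d, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), K)
    adj[rows, order[:, :K].ravel()] = 1.0
    adj = np.maximum(adj, adj.T)
    return SimilarityGraph(weights=adj, k_neighbors=K)


def correspondence_matrix(cmap: CorrespondenceMap, s_X: int, s_Y: int) -> np.ndarray:
    """Binary s_X x s_Y matrix with a 1 at every known pairing.

    A full pairing in matched order yields the identity matrix.
    """
    W = np.zeros((s_X, s_Y))
    for i, j in cmap.pairs:
        if not (0 <= i < s_X and 0 <= j < s_Y):
            raise IndexError(f"pair ({i}, {j}) out of range for {s_X}x{s_Y}")
        W[i, j] = 1.0
    return W


def subsample_correspondence(
    full: CorrespondenceMap, p: float, seed: int
) -> CorrespondenceMap:
    """Keep a uniform random subset of round(p * n_pairs) pairs.

    Models partial joint profiling: only a fraction p of cells is assumed to
    have known cross-modality correspondence.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p={p} must be in (0, 1]")
    n_keep = int(round(p * len(full.pairs)))
    rng = np.random.Generator(np.random.Philox(seed))
    idx = np.sort(rng.choice(len(full.pairs), size=n_keep, replace=False))
    return CorrespondenceMap([full.pairs[i] for i in idx], p=p)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Make each eigenvector's first nonzero coordinate positive."""
    out = vecs.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            out[:, c] = -col
    return out


def align(
    X: ModalityMatrix,
    Y: ModalityMatrix,
    cmap: CorrespondenceMap,
    K: int = 5,
    d: int = 20,
    mu: float = 0.5,
) -> JointEmbedding:
    """Joint spectral embedding of X and Y cells onto a shared manifold.

    mu weights within-modality geometry preservation, (1 - mu) the
    cross-modality correspondence term; mu = 0.5 balances them. Returns the
    d nontrivial generalized eigenvectors of (L, D) split into per-modality
    coordinate blocks; eigenvectors are D-orthonormal so P^T D P = I, and the
    objective is the sum of retained eigenvalues.
    """
    X.check_finite("alignment input X")
    Y.check_finite("alignment input Y")
    s_X, s_Y = X.n_cells, Y.n_cells
    if not cmap.pairs:
        warnings.warn(
            "no correspondence pairs: the joint graph is disconnected across "
            "modalities and the embeddings are not comparable"
        )
    W_X = build_knn_similarity(X, K).weights
    W_Y = build_knn_similarity(Y, K).weights
    W = correspondence_matrix(cmap, s_X, s_Y)

    n = s_X + s_Y
    W_joint = np.zeros((n, n))
    W_joint[:s_X, :s_X] = mu * W_X
    W_joint[s_X:, s_X:] = mu * W_Y
    W_joint[:s_X, s_X:] = (1.0 - mu) * W
    W_joint[s_X:, :s_X] = (1.0 - mu) * W.T

    n_comp, _ = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(W_joint != 0), directed=False
    )
    if n_comp > 1:
        warnings.warn(
            f"joint graph has {n_comp} connected components; each contributes "
            "a trivial null direction which is dropped"
        )

    deg = W_joint.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("isolated cell in joint graph (zero degree)")
    L = np.diag(deg) - W_joint
    # dense generalized symmetric eigensolver; eigenvectors D-orthonormal
    eigvals, eigvecs = scipy.linalg.eigh(L, np.diag(deg))

    thresh = _NULL_EIGENVALUE_RTOL * max(abs(eigvals[-1]), 1.0)
    usable = np.flatnonzero(eigvals > thresh)
    dropped = n - usable.size
    if usable.size < d:
        raise ValueError(
            f"only {usable.size} usable eigenpairs (after dropping {dropped} "
            f"trivial components) but d={d} requested; reduce d"
        )
    keep = usable[:d]
    P = _fix_signs(eigvecs[:, keep])
    vals = eigvals[keep]
    return JointEmbedding(
        coords_X=P[:s_X, :],
        coords_Y=P[s_X:, :],
        eigenvalues=vals,
        mu=mu,
        objective=float(vals.sum()),
        n_components_dropped=dropped,
        degree=deg,
    )


def match_aligned(emb: JointEmbedding) -> list[tuple[int, int]]:
    """Nearest aligned X cell for every Y cell in embedding space.

    Returns (y_index, x_index) pairs; ties broken by lower x index.
    """
    if not (
        np.all(np.isfinite(emb.coords_X)) and np.all(np.isfinite(emb.coords_Y))
    ):
        raise ValueError("non-finite embedding coordinates")
    dists = cdist(emb.coords_Y, emb.coords_X)
    return [(j, int(np.argmin(dists[j]))) for j in range(dists.shape[0])]
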