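"""Regularized optimal transport between source and target cells.

Source cells Y and target cells Yhat share one modality (matched features).
The coupling pi minimizes

    <pi, C>_F  - lambda * Omega_s(pi)  + eta * Omega_c(pi)

over couplings with fixed marginals, where Omega_s is the transport entropy
(-sum pi log pi) and Omega_c the group-lasso label penalty
sum_j sum_c ||pi(I_c, j)||_1^q with q = 0.5, which concentrates each target
cell's column mass within a single source class.

The entropic problem is solved by Sinkhorn scaling (log-domain stabilized
when the entropic weight is small relative to the cost scale); the label
penalty is handled by majorization-minimization, linearizing the concave
group penalty around the previous coupling each outer iteration.

The user-facing regularization strength ``lambda`` follows the convention
that larger lambda yields sharper, closer-to-LP couplings: the solver's
internal entropic weight is ``epsilon = 1 / lambda`` (overridable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.ensemble import IsolationForest

from .matrix import ModalityMatrix, require_matched_features

__all__ = [
    "TransportPlan",
    "OutlierReport",
    "cost_matrix",
    "sinkhorn",
    "sinkhorn_label_reg",
    "induce_labels",
    "barycentric_map",
    "flag_outlier_targets",
]

#: below epsilon < _LOG_DOMAIN_FACTOR * mean(C) the scaling iterations
#: underflow in linear space; switch to log-domain updates
_LOG_DOMAIN_FACTOR = 1e-2

#: additive guard inside the group-norm linearization (q - 1 < 0 exponent)
_GROUP_NORM_GUARD = 1e-16


@dataclass
class TransportPlan:
    """A coupling pi with its cost matrix, marginals and convergence record."""

    pi: np.ndarray
    cost: np.ndarray
    a: np.ndarray
    b: np.ndarray
    n_iter: int
    converged: bool
    log_domain: bool = False
    epsilon: float = float("nan")
    outer_iters: int = 0
    marginal_violation: float = float("nan")

    @property
    def transport_cost(self) -> float:
        """Frobenius inner product <pi, C>."""
        return float(np.sum(self.pi * self.cost))


@dataclass
class OutlierReport:
    """Per-target-cell poorly-mapped flags from the isolation-forest screen."""

    flags: np.ndarray
    score: np.ndarray
    skipped: bool = False

    @property
    def fraction_flagged(self) -> float:
        return float(np.mean(self.flags)) if self.flags.size else 0.0


def cost_matrix(Y: ModalityMatrix, Yhat: ModalityMatrix) -> np.ndarray:
    """Pairwise squared Euclidean cost, scale-normalized to [0, 1]."""
    require_matched_features(Y, Yhat)
    Y.check_finite("cost_matrix source")
    Yhat.check_finite("cost_matrix target")
    C = cdist(Y.values, Yhat.values, metric="sqeuclidean")
    cmax = C.max()
    if cmax > 0:
        C = C / cmax
    return C


def uniform_marginals(s_Y: int, s_Yhat: int) -> tuple[np.ndarray, np.ndarray]:
    return np.full(s_Y, 1.0 / s_Y), np.full(s_Yhat, 1.0 / s_Yhat)


def _sinkhorn_linear(C, a, b, eps, max_iter, tol):
    K = np.exp(-C / eps)
    u = np.ones_like(a)
    v = np.ones_like(b)
    for it in range(1, max_iter + 1):
        u = a / (K @ v)
        v = b / (K.T @ u)
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            return None, it  # underflow: caller retries in log domain
        if it % 10 == 0 or it == max_iter:
            pi = u[:, None] * K * v[None, :]
            err = max(
                np.abs(pi.sum(axis=1) - a).max(), np.abs(pi.sum(axis=0) - b).max()
            )
            if err < tol:
                return (pi, err), it
    pi = u[:, None] * K * v[None, :]
    err = max(np.abs(pi.sum(axis=1) - a).max(), np.abs(pi.sum(axis=0) - b).max())
    return (pi, err), max_iter


def _sinkhorn_log(C, a, b, eps, max_iter, tol):
    log_a = np.log(a)
    log_b = np.log(b)
    f = np.zeros_like(a)
    g = np.zeros_like(b)
    M = -C / eps
    for it in range(1, max_iter + 1):
        # f_i <- eps*(log a_i - logsumexp_j (M_ij + g_j/eps))
        f = eps * (log_a - _logsumexp(M + g[None, :] / eps, axis=1))
        g = eps * (log_b - _logsumexp(M + f[:, None] / eps, axis=0))
        if it % 10 == 0 or it == max_iter:
            log_pi = M + f[:, None] / eps + g[None, :] / eps
            pi = np.exp(log_pi)
            err = max(
                np.abs(pi.sum(axis=1) - a).max(), np.abs(pi.sum(axis=0) - b).max()
            )
            if err < tol:
                return pi, err, it
    pi = np.exp(M + f[:, None] / eps + g[None, :] / eps)
    err = max(np.abs(pi.sum(axis=1) - a).max(), np.abs(pi.sum(axis=0) - b).max())
    return pi, err, max_iter


def _logsumexp(M, axis):
    mx = M.max(axis=axis, keepdims=True)
    return (mx + np.log(np.sum(np.exp(M - mx), axis=axis, keepdims=True))).squeeze(
        axis
    )


def sinkhorn(
    C: np.ndarray,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    lambda_entropy: float = 200.0,
    max_iter: int = 1000,
    tol: float = 1e-9,
    epsilon: float | None = None,
) -> TransportPlan:
    """Entropically regularized optimal transport by Sinkhorn scaling.

    Parameters
    ----------
    C
        Nonnegative cost matrix (source x target).
    a, b
        Strictly positive marginals summing to 1; uniform when omitted.
    lambda_entropy
        Sharpness of the coupling; internal entropic weight is
        ``1 / lambda_entropy`` unless ``epsilon`` is given explicitly.
        Larger lambda approaches the exact linear-program coupling.
    tol
        Maximum allowed marginal violation at convergence.
    """
    C = np.asarray(C, dtype=np.float64)
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite cost matrix")
    if a is None or b is None:
        ua, ub = uniform_marginals(*C.shape)
        a = ua if a is None else a
        b = ub if b is None else b
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("marginals must be strictly positive")
    if epsilon is None:
        if lambda_entropy <= 0:
            raise ValueError("lambda_entropy must be > 0")
        epsilon = 1.0 / lambda_entropy
    mean_c = C.mean() if C.size else 0.0
    use_log = epsilon < _LOG_DOMAIN_FACTOR * max(mean_c, np.finfo(float).tiny)
    if not use_log:
        result, it = _sinkhorn_linear(C, a, b, epsilon, max_iter, tol)
        if result is not None:
            pi, err = result
            return TransportPlan(
                pi, C, a, b, it, err < tol, False, epsilon,
                marginal_violation=float(err),
            )
        # fall through to log domain on underflow
    pi, err, it = _sinkhorn_log(C, a, b, epsilon, max_iter, tol)
    return TransportPlan(
        pi, C, a, b, it, err < tol, True, epsilon,
        marginal_violation=float(err),
    )


def sinkhorn_label_reg(
    C: np.ndarray,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    lambda_entropy: float = 200.0,
    eta: float = 1.0,
    q: float = 0.5,
    outer_iter: int = 10,
    max_iter: int = 1000,
    tol: float = 1e-9,
    outer_tol: float = 1e-9,
    epsilon: float | None = None,
) -> TransportPlan:
    """Entropic transport with a group-lasso penalty on source-class blocks.

    Each outer iteration linearizes the concave penalty
    ``sum_j sum_c ||pi(I_c, j)||_1^q`` around the previous coupling, adding
    ``eta * q * (||pi_prev(I_c(i), j)||_1 + delta)^(q-1)`` to the cost of
    entry (i, j), and re-solves the entropic problem; this is the standard
    majorization-minimization scheme for label-regularized domain adaptation.
    ``eta = 0`` reduces exactly to :func:`sinkhorn`.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    if eta == 0 or labels is None:
        return sinkhorn(C, a, b, lambda_entropy, max_iter, tol, epsilon)
    C = np.asarray(C, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.shape[0] != C.shape[0]:
        raise ValueError(
            f"{labels.shape[0]} labels for {C.shape[0]} source cells"
        )
    classes = np.unique(labels)
    class_rows = [np.flatnonzero(labels == c) for c in classes]
    row_class = np.searchsorted(classes, labels)

    plan = sinkhorn(C, a, b, lambda_entropy, max_iter, tol, epsilon)
    n_outer = 1
    for _ in range(outer_iter - 1):
        prev = plan.pi
        # column mass per class: (n_classes x n_targets)
        mass = np.vstack([prev[rows, :].sum(axis=0) for rows in class_rows])
        grad = q * (mass + _GROUP_NORM_GUARD) ** (q - 1.0)
        C_maj = C + eta * grad[row_class, :]
        plan = sinkhorn(C_maj, a, b, lambda_entropy, max_iter, tol, epsilon)
        n_outer += 1
        if np.abs(plan.pi - prev).max() < outer_tol:
            break
    # report against the original cost, keeping convergence diagnostics
    return TransportPlan(
        plan.pi, C, plan.a, plan.b, plan.n_iter, plan.converged,
        plan.log_domain, plan.epsilon, outer_iters=n_outer,
        marginal_violation=plan.marginal_violation,
    )


def induce_labels(Y: ModalityMatrix, n_clusters: int = 2) -> np.ndarray:
    """Hierarchical (Ward) clustering to induce source-cell class labels.

    Used when no prior cell-type annotation exists; the default of two
    clusters captures the dominant bipartition of the training cells.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > Y.n_cells:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds n_cells={Y.n_cells}"
        )
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    return model.fit_predict(Y.values)


def barycentric_map(plan: TransportPlan, Yhat: ModalityMatrix) -> ModalityMatrix:
    """Transport source cells into target space: Y_t = diag(pi 1)^-1 pi Yhat.

    Each transported source cell is the coupling-weighted convex combination
    of target cells; with unit row sums this is exactly ``pi @ Yhat``.
    """
    pi = plan.pi
    if pi.shape[1] != Yhat.n_cells:
        raise ValueError(
            f"plan has {pi.shape[1]} target cells, Yhat has {Yhat.n_cells}"
        )
    rowsum = pi.sum(axis=1)
    if np.any(rowsum <= 0):
        bad = np.flatnonzero(rowsum <= 0)
        raise ValueError(
            f"zero-mass rows in coupling (unmatched source cells): {bad[:5]}"
        )
    Yt = (pi / rowsum[:, None]) @ Yhat.values
    return ModalityMatrix(
        Yt,
        cell_ids=[f"src:{i}" for i in range(pi.shape[0])],
        feature_ids=list(Yhat.feature_ids),
        modality=Yhat.modality,
    )


def flag_outlier_targets(
    plan: TransportPlan,
    variance_keep: float = 0.95,
    contamination: str | float = "auto",
    seed: int = 0,
) -> OutlierReport:
    """Flag target cells the coupling maps poorly (e.g. unseen cell types).

    Forms P = pi^T * C^T elementwise (each target cell's row holds the cost it
    actually pays to every source cell, weighted by the mass it receives),
    projects P onto the principal components explaining ``variance_keep`` of
    the variance, and runs a seeded isolation forest on the projection.
    """
    n_targets = plan.pi.shape[1]
    if n_targets < 5:
        warnings.warn(
            f"only {n_targets} target cells: outlier screen skipped "
            "(ensemble meaningless)"
        )
        return OutlierReport(
            flags=np.zeros(n_targets, dtype=bool),
            score=np.zeros(n_targets),
            skipped=True,
        )
    P = plan.pi.T * plan.cost.T
    n_comp = min(P.shape[0] - 1, P.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    proj = pca.fit_transform(P)
    cum = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(cum, variance_keep) + 1)
    keep = min(keep, proj.shape[1])
    forest = IsolationForest(contamination=contamination, random_state=seed)
    pred = forest.fit_predict(proj[:, :keep])
    flags = pred == -1
    score = -forest.score_samples(proj[:, :keep])
    if flags.any():
        warnings.warn(
            f"{100.0 * flags.mean():.1f}% of target cells are poorly mapped "
            "and may be removed"
        )
    return OutlierReport(flags=flags, score=score)
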