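"""Missing-modality inference by distance-weighted k-nearest neighbors,
plus the end-to-end pipeline orchestration.

After transport, each target cell finds its k nearest transported source
cells; the missing modality is the weighted average of those cells'
profiles in the other modality, with raw weight ``exp(-dist)`` normalized
to sum to one, so every inferred profile is a convex combination of
source profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .alignment import (
    CorrespondenceMap,
    align,
    full_correspondence,
    match_aligned,
    subsample_correspondence,
)
from .matrix import ModalityMatrix, require_matched_features
from .runlog import RunLog
from .transport import (
    OutlierReport,
    barycentric_map,
    cost_matrix,
    flag_outlier_targets,
    induce_labels,
    sinkhorn_label_reg,
)

__all__ = ["InferenceResult", "CMOTConfig", "knn_infer", "run_cmot"]


@dataclass
class InferenceResult:
    """Inferred missing modality with its neighbor sets and diagnostics."""

    Xhat: ModalityMatrix
    neighbors: np.ndarray  # (n_targets, k) source indices
    weights: np.ndarray  # (n_targets, k), rows sum to 1
    outlier_flags: np.ndarray | None = None
    outlier_report: OutlierReport | None = None
    log: RunLog | None = field(default=None, repr=False)


@dataclass
class CMOTConfig:
    """Pipeline parameters.

    Defaults follow a typical high-dimensional chromatin/expression run:
    K = 5 similarity neighbors and d = 20 manifold dimensions for alignment,
    lambda = 200 / eta = 1 for transport, k = 600 inference neighbors
    (clamped to the number of source cells on small data).
    """

    p: float = 1.0
    K: int = 5
    d: int = 20
    mu: float = 0.5
    lambda_entropy: float = 200.0
    eta: float = 1.0
    epsilon: float | None = None
    k: int = 600
    n_clusters: int = 2
    search_features: list[str] | None = None
    no_align: bool = False
    flag_outliers: bool = True
    contamination: str | float = "auto"
    max_iter: int = 1000
    tol: float = 1e-9
    outer_iter: int = 10
    seed: int = 0


def knn_infer(
    Yt: ModalityMatrix,
    Yhat: ModalityMatrix,
    X_aligned: ModalityMatrix,
    k: int,
    search_features: list[str] | None = None,
) -> InferenceResult:
    """Infer each target cell's missing modality from its k nearest
    transported source cells.

    Distances are Euclidean between target cells and transported source
    cells ``Yt``, optionally restricted to ``search_features`` (e.g. the top
    highly variable genes). Neighbor ties break toward the lower source
    index. Weight for neighbor l of target j is ``exp(-dist(j, l))``,
    normalized over the k neighbors.
    """
    if Yt.n_cells != X_aligned.n_cells:
        raise ValueError(
            f"Yt has {Yt.n_cells} source cells but X_aligned has "
            f"{X_aligned.n_cells}; they must be row-aligned"
        )
    if k > Yt.n_cells:
        raise ValueError(f"k={k} exceeds number of source cells {Yt.n_cells}")
    if search_features is not None:
        if len(search_features) == 0:
            raise ValueError("search_features is empty")
        Yt = Yt.subset_features_by_id(search_features)
        Yhat = Yhat.subset_features_by_id(search_features)
    require_matched_features(Yt, Yhat)

    dists = cdist(Yhat.values, Yt.values)
    order = np.argsort(dists, axis=1, kind="stable")[:, :k]
    ndist = np.take_along_axis(dists, order, axis=1)
    raw = np.exp(-ndist)
    wsum = raw.sum(axis=1, keepdims=True)
    # all-underflowed rows (huge distances): fall back to uniform weights
    uniform = np.full_like(raw, 1.0 / k)
    weights = np.where(wsum > 0, raw / np.where(wsum == 0, 1.0, wsum), uniform)

    Xvals = X_aligned.values[order, :]  # (n_targets, k, d_X)
    Xhat_vals = np.einsum("tk,tkf->tf", weights, Xvals)
    Xhat = ModalityMatrix(
        Xhat_vals,
        cell_ids=list(Yhat.cell_ids),
        feature_ids=list(X_aligned.feature_ids),
        modality=X_aligned.modality,
    )
    return InferenceResult(Xhat=Xhat, neighbors=order, weights=weights)


def run_cmot(
    X: ModalityMatrix,
    Y: ModalityMatrix,
    Yhat: ModalityMatrix,
    config: CMOTConfig | None = None,
    labels: np.ndarray | None = None,
    pairs: CorrespondenceMap | None = None,
    log: RunLog | None = None,
) -> InferenceResult:
    """Full pipeline: (optional) alignment, regularized transport, outlier
    screen, barycentric mapping, and kNN inference.

    X and Y profile the same source cells in two modalities (row i of X and
    row i of Y are the same cell); Yhat holds target cells measured only in
    Y's modality. With full correspondence (p = 1) alignment is skipped and
    X is used directly; with p < 1 the pairing is subsampled, both source
    modalities are aligned on a shared manifold, and each Y cell borrows the
    X profile of its nearest aligned X cell.
    """
    cfg = config or CMOTConfig()
    log = log or RunLog()
    require_matched_features(Y, Yhat)
    if X.n_cells != Y.n_cells:
        raise ValueError(
            f"X has {X.n_cells} cells, Y has {Y.n_cells}; source modalities "
            "must profile the same cells"
        )

    # --- Step A: alignment (skipped under full correspondence) -------------
    if cfg.p >= 1.0 or cfg.no_align:
        X_aligned = X
        log.record("align", "skipped", reason="full correspondence", p=cfg.p)
    else:
        if pairs is None:
            pairs = full_correspondence(Y.n_cells)
        sub = subsample_correspondence(pairs, cfg.p, cfg.seed)
        try:
            emb = align(X, Y, sub, K=cfg.K, d=cfg.d, mu=cfg.mu)
        except Exception as exc:
            raise RuntimeError(f"alignment stage failed: {exc}") from exc
        matches = match_aligned(emb)
        # several Y cells may borrow the same X cell; re-key rows by Y's ids
        X_aligned = ModalityMatrix(
            X.values[[x_idx for _, x_idx in matches], :],
            cell_ids=list(Y.cell_ids),
            feature_ids=list(X.feature_ids),
            modality=X.modality,
        )
        log.record(
            "align", "done", p=cfg.p, K=cfg.K, d=cfg.d, mu=cfg.mu,
            objective=emb.objective,
            n_components_dropped=emb.n_components_dropped,
        )

    # --- Step B: regularized optimal transport -----------------------------
    if labels is None and cfg.eta > 0:
        labels = induce_labels(Y, cfg.n_clusters)
        log.record("transport", "labels_induced", n_clusters=cfg.n_clusters)
    try:
        C = cost_matrix(Y, Yhat)
        plan = sinkhorn_label_reg(
            C,
            labels=labels,
            lambda_entropy=cfg.lambda_entropy,
            eta=cfg.eta,
            outer_iter=cfg.outer_iter,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            epsilon=cfg.epsilon,
        )
    except Exception as exc:
        raise RuntimeError(f"transport stage failed: {exc}") from exc
    log.record(
        "transport", "done", lam=cfg.lambda_entropy, eta=cfg.eta,
        epsilon=plan.epsilon, n_iter=plan.n_iter, converged=plan.converged,
        marginal_violation=plan.marginal_violation,
    )

    report = None
    if cfg.flag_outliers:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            report = flag_outlier_targets(
                plan, contamination=cfg.contamination, seed=cfg.seed
            )
        for w in caught:
            log.warning("outliers", str(w.message))
        log.record(
            "outliers", "done",
            fraction_flagged=report.fraction_flagged, skipped=report.skipped,
        )

    Yt = barycentric_map(plan, Yhat)

    # --- Step C: weighted kNN inference ------------------------------------
    k = cfg.k
    if k > Y.n_cells:
        log.record("infer", "k_clamped", requested=cfg.k, used=Y.n_cells)
        k = Y.n_cells
    try:
        result = knn_infer(
            Yt, Yhat, X_aligned, k=k, search_features=cfg.search_features
        )
    except Exception as exc:
        raise RuntimeError(f"inference stage failed: {exc}") from exc
    log.record("infer", "done", k=k)

    result.outlier_report = report
    result.outlier_flags = report.flags if report is not None else None
    result.log = log
    return result
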