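"""Feature selection and normalization applied before alignment and transport.

All transforms are deterministic, operate on :class:`~cmot.matrix.ModalityMatrix`
and never introduce NaN/Inf on finite nonnegative input.
"""

from __future__ import annotations

import warnings

import numpy as np

from .matrix import ModalityMatrix

__all__ = [
    "select_highly_variable",
    "highly_variable_features",
    "tfidf_transform",
    "clr_normalize",
    "lognorm",
    "binarize",
    "filter_min_cells",
]

_COUNT_LIKE = ("rna", "atac")


def highly_variable_features(m: ModalityMatrix, n_features: int) -> list[str]:
    """Rank features by cross-cell variance and return the top ``n_features`` ids.

    Count-like modalities (rna, atac) are log1p-transformed before the variance
    is computed, so selection is not dominated by a handful of high-count
    features. Ties are broken lexicographically by feature id so the ranking
    is stable across platforms.
    """
    if not 1 <= n_features <= m.n_features:
        raise ValueError(
            f"n_features={n_features} out of range for matrix with "
            f"{m.n_features} features"
        )
    vals = m.values
    if m.modality in _COUNT_LIKE:
        if np.min(vals) < 0:
            # already normalized / residual data: use as-is
            pass
        else:
            vals = np.log1p(vals)
    var = vals.var(axis=0)
    if np.all(var == 0):
        warnings.warn(
            "all features have zero variance; returning first features in id order"
        )
    # sort by (-variance, feature_id): descending variance, stable id tie-break
    order = sorted(range(m.n_features), key=lambda j: (-var[j], m.feature_ids[j]))
    return [m.feature_ids[j] for j in order[:n_features]]


def select_highly_variable(
    m: ModalityMatrix,
    n_features: int,
    reference: list[str] | None = None,
) -> ModalityMatrix:
    """Subset to the most variable features, in descending-variance order.

    When ``reference`` is given (a feature-id list computed on another matrix,
    e.g. selecting one dataset's genes by another's highly variable genes),
    the selection is re-applied by id instead of being recomputed.
    """
    ids = reference[:n_features] if reference is not None else None
    if ids is None:
        ids = highly_variable_features(m, n_features)
    return m.subset_features_by_id(ids)


def tfidf_transform(m: ModalityMatrix) -> ModalityMatrix:
    """Term frequency-inverse document frequency reweighting of a peak matrix.

    Entry (i, j) becomes ``TF(i,j) * IDF(j)`` with ``TF = count / rowsum`` and
    ``IDF(j) = log(1 + n_cells / (1 + n_cells_with_feature_j))``. All-zero
    cells map to all-zero rows.
    """
    m.check_finite("tfidf input")
    x = m.values
    if np.min(x) < 0:
        raise ValueError("tfidf_transform requires nonnegative values")
    rowsum = x.sum(axis=1, keepdims=True)
    safe = np.where(rowsum == 0, 1.0, rowsum)
    tf = x / safe
    df = np.count_nonzero(x, axis=0)
    idf = np.log(1.0 + x.shape[0] / (1.0 + df))
    return m.with_values(tf * idf)


def clr_normalize(m: ModalityMatrix) -> ModalityMatrix:
    """Centered log-ratio normalization per cell: log1p then row-center.

    Each output row sums to zero. This is the per-cell (margin over features)
    convention used for antibody-capture protein counts.
    """
    m.check_finite("clr input")
    if np.min(m.values) < 0:
        raise ValueError("clr_normalize requires nonnegative values")
    logged = np.log1p(m.values)
    return m.with_values(logged - logged.mean(axis=1, keepdims=True))


def lognorm(m: ModalityMatrix, target_sum: float = 1e4) -> ModalityMatrix:
    """Library-size normalization to ``target_sum`` per cell, then log1p."""
    m.check_finite("lognorm input")
    if np.min(m.values) < 0:
        raise ValueError("lognorm requires nonnegative counts")
    rowsum = m.values.sum(axis=1)
    zero = rowsum == 0
    if np.any(zero):
        ids = [m.cell_ids[i] for i in np.flatnonzero(zero)]
        warnings.warn(f"cells with zero total counts left as zeros: {ids}")
    safe = np.where(zero, 1.0, rowsum)
    scaled = m.values * (target_sum / safe)[:, None]
    return m.with_values(np.log1p(scaled))


def binarize(m: ModalityMatrix, cutoff: float = 0.5, strict: bool = False) -> ModalityMatrix:
    """Threshold to a 0/1 matrix.

    ``value >= cutoff`` maps to 1 by default; ``strict=True`` uses ``>``
    (the "set all values greater than 0 to 1" convention for raw peak counts).
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if strict:
        out = (m.values > cutoff).astype(np.float64)
    else:
        out = (m.values >= cutoff).astype(np.float64)
    return m.with_values(out)


def filter_min_cells(m: ModalityMatrix, min_cells: int = 3) -> ModalityMatrix:
    """Drop features detected (nonzero) in fewer than ``min_cells`` cells."""
    keep = np.flatnonzero(np.count_nonzero(m.values, axis=0) >= min_cells)
    if keep.size == 0:
        raise ValueError(f"no feature occurs in at least {min_cells} cells")
    return m.subset_features(keep.tolist())
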