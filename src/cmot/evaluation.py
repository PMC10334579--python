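"""Metrics for judging an inferred modality against measurement.

Cell-wise and feature-wise Pearson correlation, one-sided rank-sum
comparison of score vectors, one-vs-all AUPRC with its positive-rate
baseline, per-peak AUROC, and the silhouette score

    S(m) = (E(m) - e(m)) / max(E(m), e(m))

with e(m) the mean distance to the other cells of m's cluster and E(m)
the mean distance to the closest other cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu, rankdata

__all__ = [
    "PearsonSummary",
    "cellwise_pearson",
    "featurewise_pearson",
    "improved_feature_count",
    "wilcoxon_onesided",
    "auprc_one_vs_all",
    "peakwise_auroc",
    "silhouette",
]


@dataclass
class PearsonSummary:
    """Per-unit correlations with zero-variance units reported as NaN."""

    r: np.ndarray
    n_undefined: int

    @property
    def median(self) -> float:
        valid = self.r[~np.isnan(self.r)]
        return float(np.median(valid)) if valid.size else float("nan")


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, int]:
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((Ac**2).sum(axis=1))
    nb = np.sqrt((Bc**2).sum(axis=1))
    bad = (na == 0) | (nb == 0)
    denom = np.where(bad, 1.0, na * nb)
    r = (Ac * Bc).sum(axis=1) / denom
    r[bad] = np.nan
    return np.clip(r, -1.0, 1.0, where=~bad, out=r), int(bad.sum())


def _as_pair(inferred, measured) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(getattr(inferred, "values", inferred), dtype=np.float64)
    B = np.asarray(getattr(measured, "values", measured), dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return A, B


def cellwise_pearson(inferred, measured) -> PearsonSummary:
    """Pearson r between inferred and measured profiles of each cell (rows)."""
    A, B = _as_pair(inferred, measured)
    if A.shape[1] < 2:
        raise ValueError("need at least 2 features for cell-wise correlation")
    r, bad = _rowwise_pearson(A, B)
    return PearsonSummary(r=r, n_undefined=bad)


def featurewise_pearson(inferred, measured) -> PearsonSummary:
    """Pearson r between inferred and measured values of each feature
    (columns) across cells."""
    A, B = _as_pair(inferred, measured)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 cells for feature-wise correlation")
    r, bad = _rowwise_pearson(A.T, B.T)
    return PearsonSummary(r=r, n_undefined=bad)


def improved_feature_count(r_a: np.ndarray, r_b: np.ndarray) -> int:
    """Number of features where method A's correlation beats method B's."""
    r_a = np.asarray(r_a, dtype=np.float64)
    r_b = np.asarray(r_b, dtype=np.float64)
    ok = ~(np.isnan(r_a) | np.isnan(r_b))
    return int(np.sum(r_a[ok] > r_b[ok]))


def wilcoxon_onesided(scores_a, scores_b) -> float:
    """One-sided Wilcoxon rank-sum p-value that ``a`` exceeds ``b``.

    Normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all values tied; p-value undefined, returning 0.5")
        return 0.5
    _, p = mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(p)


def auprc_one_vs_all(scores, positives) -> tuple[float, float]:
    """Area under the precision-recall curve, plus the positive-rate baseline.

    The curve is swept over descending score thresholds; ties are processed
    as one block. The area uses step interpolation (no linear segments).
    Baseline = n_positives / n_total, the precision of a random classifier.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(positives, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_tot = y.size
    if n_pos == 0 or n_pos == n_tot:
        raise ValueError("need at least one positive and one negative")
    baseline = n_pos / n_tot
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # collapse score ties: keep the last index of each tied block
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp = tp[distinct]
    fp = fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    auprc = float(np.sum((recall - prev_recall) * precision))
    return auprc, baseline


def peakwise_auroc(inferred_scores, measured_binary) -> np.ndarray:
    """Per-peak (per-column) AUROC of inferred accessibility scores against
    measured binary peaks, via the rank statistic U / (n1 * n0).

    Peaks where the measurement has only one class are returned as NaN.
    """
    S, Yb = _as_pair(inferred_scores, measured_binary)
    if not np.isin(Yb, (0.0, 1.0)).all():
        raise ValueError("measured matrix must be binary (0/1)")
    n_cells, n_peaks = S.shape
    out = np.full(n_peaks, np.nan)
    for j in range(n_peaks):
        y = Yb[:, j].astype(bool)
        n1 = int(y.sum())
        n0 = n_cells - n1
        if n1 == 0 or n0 == 0:
            continue
        ranks = rankdata(S[:, j])
        u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
        out[j] = u / (n1 * n0)
    return out


def silhouette(
    data, cluster_labels
) -> tuple[np.ndarray, float]:
    """Per-cell silhouette scores and their median, Euclidean distance.

    For cell m in cluster C_M, e(m) is the mean distance to the other
    members of C_M and E(m) the smallest mean distance to any other
    cluster; S(m) = (E(m) - e(m)) / max(E(m), e(m)). Cells in singleton
    clusters score 0 by convention; coincident clusters score ~0.
    """
    Xv = np.asarray(getattr(data, "values", data), dtype=np.float64)
    labels = np.asarray(cluster_labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(Xv, Xv)
    n = Xv.shape[0]
    scores = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    for m in range(n):
        own = members[labels[m]]
        if own.size == 1:
            scores[m] = 0.0
            continue
        e = D[m, own].sum() / (own.size - 1)
        E = min(
            D[m, members[c]].mean() for c in uniq if c != labels[m]
        )
        denom = max(E, e)
        scores[m] = 0.0 if denom == 0 else (E - e) / denom
    return scores, float(np.median(scores))
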