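"""Core cells-by-features container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

MODALITIES = ("rna", "atac", "protein", "other")


@dataclass
class ModalityMatrix:
    """A cells x features numeric matrix with identifiers and a modality tag.

    Parameters
    ----------
    values
        2-D float array, rows are cells, columns are features.
    cell_ids
        Unique string identifier per row.
    feature_ids
        Unique string identifier per column.
    modality
        One of ``rna``, ``atac``, ``protein``, ``other``.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)
    modality: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        n, m = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"feat{j}" for j in range(m)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.cell_ids) != n:
            raise ValueError(
                f"{len(self.cell_ids)} cell_ids for {n} rows"
            )
        if len(self.feature_ids) != m:
            raise ValueError(
                f"{len(self.feature_ids)} feature_ids for {m} columns"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell_ids")
        if len(set(self.feature_ids)) != m:
            raise ValueError("duplicate feature_ids")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def check_finite(self, context: str = "") -> None:
        if not np.all(np.isfinite(self.values)):
            where = context or "matrix"
            raise ValueError(f"non-finite values in {where}")

    def with_values(self, values: np.ndarray) -> "ModalityMatrix":
        """Copy with new values of identical shape (ids and tag preserved)."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.values.shape:
            raise ValueError(
                f"shape {values.shape} != {self.values.shape}"
            )
        return replace(self, values=values)

    def subset_cells(self, idx: Sequence[int]) -> "ModalityMatrix":
        idx = list(idx)
        return ModalityMatrix(
            self.values[idx, :],
            [self.cell_ids[i] for i in idx],
            list(self.feature_ids),
            self.modality,
        )

    def subset_features(self, idx: Sequence[int]) -> "ModalityMatrix":
        idx = list(idx)
        return ModalityMatrix(
            self.values[:, idx],
            list(self.cell_ids),
            [self.feature_ids[j] for j in idx],
            self.modality,
        )

    def subset_features_by_id(self, ids: Sequence[str]) -> "ModalityMatrix":
        """Reorder/subset columns to the given feature ids (all must exist)."""
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise KeyError(f"features not present: {missing[:5]}")
        return self.subset_features([pos[f] for f in ids])


def require_matched_features(a: ModalityMatrix, b: ModalityMatrix) -> None:
    if a.feature_ids != b.feature_ids:
        raise ValueError(
            "feature_ids differ between matrices "
            f"({a.n_features} vs {b.n_features} features; order included)"
        )
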