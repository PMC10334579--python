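"""Readers and writers for the formats the toolkit exchanges.

Matrices travel as delimited text (header row = feature ids, first column =
cell ids), matrix-market triplets with ``.cells``/``.features`` id sidecars,
or the AnnData HDF5 container (``.h5ad``). Orientation is fixed as cells x
features everywhere. Embedding and transport-plan archives use plain HDF5
with a documented group layout.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .alignment import JointEmbedding
from .matrix import ModalityMatrix
from .transport import TransportPlan

__all__ = [
    "load_matrix",
    "save_matrix",
    "save_embedding",
    "load_embedding",
    "save_plan",
    "load_plan",
    "load_pairs",
    "save_pairs",
    "load_labels",
    "save_labels",
]


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    if suffix in (".h5ad", ".h5"):
        return "h5"
    raise ValueError(f"cannot infer format from {path.name}; pass format=")


def load_matrix(
    path: str | Path, format: str = "auto", modality: str = "other"
) -> ModalityMatrix:
    """Load a cells x features matrix with identifiers from csv/mtx/h5ad."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt == "csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValueError(f"duplicate feature ids in {path.name}")
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.has_duplicates:
            raise ValueError(f"duplicate cell ids in {path.name}")
        return ModalityMatrix(
            df.to_numpy(dtype=np.float64),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            modality,
        )
    if fmt == "mtx":
        cells_file = path.with_suffix(".cells")
        feats_file = path.with_suffix(".features")
        for sidecar in (cells_file, feats_file):
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"missing id sidecar {sidecar.name} next to {path.name}"
                )
        mat = scipy.io.mmread(path)
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat,
            dtype=np.float64,
        )
        cells = cells_file.read_text().split()
        feats = feats_file.read_text().split()
        if dense.shape != (len(cells), len(feats)):
            raise ValueError(
                f"matrix {dense.shape} does not match {len(cells)} cells x "
                f"{len(feats)} features in sidecars"
            )
        return ModalityMatrix(dense, cells, feats, modality)
    if fmt == "h5":
        import anndata as ad

        adata = ad.read_h5ad(path)
        Xv = adata.X
        if scipy.sparse.issparse(Xv):
            Xv = np.asarray(Xv.todense())
        return ModalityMatrix(
            np.asarray(Xv, dtype=np.float64),
            [str(i) for i in adata.obs_names],
            [str(v) for v in adata.var_names],
            modality,
        )
    raise ValueError(f"unknown format {fmt!r}")


def save_matrix(m: ModalityMatrix, path: str | Path, format: str = "auto") -> None:
    path = Path(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt == "csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        pd.DataFrame(
            m.values, index=m.cell_ids, columns=m.feature_ids
        ).to_csv(path, sep=sep)
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values))
        path.with_suffix(".cells").write_text("\n".join(m.cell_ids) + "\n")
        path.with_suffix(".features").write_text(
            "\n".join(m.feature_ids) + "\n"
        )
    elif fmt == "h5":
        import anndata as ad

        ad.AnnData(
            X=m.values,
            obs=pd.DataFrame(index=m.cell_ids),
            var=pd.DataFrame(index=m.feature_ids),
        ).write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# HDF5 archives: /embedding{coords_X,coords_Y,eigenvalues} with mu/objective
# attrs; /plan{pi,cost,a,b} with convergence attrs.


def save_embedding(emb: JointEmbedding, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("embedding")
        g.create_dataset("coords_X", data=emb.coords_X)
        g.create_dataset("coords_Y", data=emb.coords_Y)
        g.create_dataset("eigenvalues", data=emb.eigenvalues)
        g.attrs["mu"] = emb.mu
        g.attrs["objective"] = emb.objective
        g.attrs["n_components_dropped"] = emb.n_components_dropped


def load_embedding(path: str | Path) -> JointEmbedding:
    with h5py.File(path, "r") as fh:
        g = fh["embedding"]
        return JointEmbedding(
            coords_X=g["coords_X"][()],
            coords_Y=g["coords_Y"][()],
            eigenvalues=g["eigenvalues"][()],
            mu=float(g.attrs["mu"]),
            objective=float(g.attrs["objective"]),
            n_components_dropped=int(g.attrs["n_components_dropped"]),
        )


def save_plan(plan: TransportPlan, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("plan")
        g.create_dataset("pi", data=plan.pi)
        g.create_dataset("cost", data=plan.cost)
        g.create_dataset("a", data=plan.a)
        g.create_dataset("b", data=plan.b)
        g.attrs["n_iter"] = plan.n_iter
        g.attrs["converged"] = plan.converged
        g.attrs["log_domain"] = plan.log_domain
        g.attrs["epsilon"] = plan.epsilon
        g.attrs["outer_iters"] = plan.outer_iters
        g.attrs["marginal_violation"] = plan.marginal_violation


def load_plan(path: str | Path) -> TransportPlan:
    with h5py.File(path, "r") as fh:
        g = fh["plan"]
        return TransportPlan(
            pi=g["pi"][()],
            cost=g["cost"][()],
            a=g["a"][()],
            b=g["b"][()],
            n_iter=int(g.attrs["n_iter"]),
            converged=bool(g.attrs["converged"]),
            log_domain=bool(g.attrs["log_domain"]),
            epsilon=float(g.attrs["epsilon"]),
            outer_iters=int(g.attrs["outer_iters"]),
            marginal_violation=float(g.attrs["marginal_violation"]),
        )


# ---------------------------------------------------------------------------
# small sidecar tables


def load_pairs(path: str | Path, x_ids: list[str], y_ids: list[str]):
    """Two-column cell-id pairing file -> CorrespondenceMap."""
    from .alignment import CorrespondenceMap

    df = pd.read_csv(path, sep="\t", header=None, names=["x", "y"])
    x_pos = {c: i for i, c in enumerate(x_ids)}
    y_pos = {c: i for i, c in enumerate(y_ids)}
    pairs = []
    for _, row in df.iterrows():
        try:
            pairs.append((x_pos[str(row["x"])], y_pos[str(row["y"])]))
        except KeyError as exc:
            raise KeyError(f"unknown cell id in pairs file: {exc}") from exc
    p = len(pairs) / max(min(len(x_ids), len(y_ids)), 1)
    return CorrespondenceMap(pairs, p=min(p, 1.0))


def save_pairs(cmap, x_ids: list[str], y_ids: list[str], path: str | Path):
    rows = [(x_ids[i], y_ids[j]) for i, j in cmap.pairs]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def load_labels(path: str | Path, cell_ids: list[str]) -> np.ndarray:
    """Two-column cell-id / label file, reordered to ``cell_ids``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "label"])
    mapping = {str(c): l for c, l in zip(df["cell"], df["label"])}
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise KeyError(f"labels missing for cells: {missing[:5]}")
    return np.asarray([mapping[c] for c in cell_ids])


def save_labels(labels, cell_ids: list[str], path: str | Path) -> None:
    pd.DataFrame({"cell": cell_ids, "label": list(labels)}).to_csv(
        path, sep="\t", header=False, index=False
    )
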