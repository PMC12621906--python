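"""Readers and writers for expression matrices and run artifacts.

Matrix Market (MTX) triplets with ``genes.tsv`` / ``barcodes.tsv`` sidecars
are read through ``scipy.io`` (both genes-as-rows and cells-as-rows
orientations); dense CSV/TSV matrices through pandas. An HDF5-backed
container bundles the raw/lognorm/scaled layers of one run.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import ExpressionMatrix, ValidationError


def read_mtx(
    matrix_path,
    genes_path,
    barcodes_path,
    orientation: str = "genes_by_cells",
    layer_tag: str = "raw",
) -> ExpressionMatrix:
    """Read an MTX triplet. ``orientation`` names what the MTX rows are."""
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:
        raise ValidationError(f"malformed MTX file {matrix_path}: {exc}") from exc
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
    if orientation == "genes_by_cells":
        mat = mat.T
    elif orientation != "cells_by_genes":
        raise ValidationError(f"unknown orientation {orientation!r}")
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(cells), len(genes)):
        raise ValidationError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(cells)} cells x {len(genes)} genes)"
        )
    return ExpressionMatrix(mat, genes.astype(object), cells.astype(object), layer_tag)


def write_mtx(X: ExpressionMatrix, out_dir, orientation: str = "genes_by_cells") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(X.values if sp.issparse(X.values) else sp.csr_matrix(X.values))
    if orientation == "genes_by_cells":
        mat = mat.T
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), mat)
    pd.Series(X.gene_ids).to_csv(out_dir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(X.cell_ids).to_csv(out_dir / "barcodes.tsv", sep="\t", index=False, header=False)


def read_dense(path, sep: str | None = None, layer_tag: str = "raw") -> ExpressionMatrix:
    """Dense CSV/TSV with a gene-name header row and cell ids in column 0."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ValidationError(f"failed to parse {path}: {exc}") from exc
    return ExpressionMatrix(
        df.to_numpy(dtype=np.float64),
        df.columns.to_numpy(dtype=object),
        df.index.astype(str).to_numpy(dtype=object),
        layer_tag,
    )


def write_dense(X: ExpressionMatrix, path, sep: str = ",") -> None:
    pd.DataFrame(X.dense(), index=X.cell_ids, columns=X.gene_ids).to_csv(path, sep=sep)


def read_matrix(
    path,
    fmt: str = "auto",
    orientation: str = "genes_by_cells",
    genes_path=None,
    barcodes_path=None,
    layer_tag: str = "raw",
) -> ExpressionMatrix:
    """Dispatching reader over mtx / csv / tsv / internal h5 formats."""
    path = Path(path)
    if fmt == "auto":
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".h5": "h5"}.get(
            path.suffix.lower(), "csv"
        )
    if fmt == "mtx":
        genes_path = genes_path or path.parent / "genes.tsv"
        barcodes_path = barcodes_path or path.parent / "barcodes.tsv"
        return read_mtx(path, genes_path, barcodes_path, orientation, layer_tag)
    if fmt in ("csv", "tsv"):
        return read_dense(path, sep="\t" if fmt == "tsv" else ",", layer_tag=layer_tag)
    if fmt == "h5":
        store = read_h5(path)
        if layer_tag not in store:
            raise ValidationError(f"layer {layer_tag!r} not present in {path}")
        return store[layer_tag]
    raise ValidationError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# internal HDF5 container: one file holding multiple layers
# ---------------------------------------------------------------------------

def write_h5(layers: dict[str, ExpressionMatrix], path, extra: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        for tag, X in layers.items():
            grp = fh.create_group(tag)
            grp.create_dataset("values", data=X.dense(), compression="gzip")
            grp.create_dataset(
                "gene_ids", data=np.array(X.gene_ids, dtype="S")
            )
            grp.create_dataset(
                "cell_ids", data=np.array(X.cell_ids, dtype="S")
            )
            grp.attrs["layer_tag"] = X.layer_tag
        for key, arr in (extra or {}).items():
            fh.create_dataset(f"extra/{key}", data=arr)


def read_h5(path) -> dict[str, ExpressionMatrix]:
    out: dict[str, ExpressionMatrix] = {}
    with h5py.File(path, "r") as fh:
        for tag in fh:
            if tag == "extra":
                continue
            grp = fh[tag]
            out[tag] = ExpressionMatrix(
                grp["values"][...],
                np.array([g.decode() for g in grp["gene_ids"][...]], dtype=object),
                np.array([c.decode() for c in grp["cell_ids"][...]], dtype=object),
                grp.attrs["layer_tag"],
            )
    return out


# ---------------------------------------------------------------------------
# small tabular artifacts
# ---------------------------------------------------------------------------

def write_clusters(assignment, path) -> None:
    pd.DataFrame(
        {"cell_id": assignment.cell_ids, "cluster": assignment.cluster_of}
    ).to_csv(path, sep="\t", index=False)


def read_clusters(path):
    from .cluster import ClusterAssignment

    df = pd.read_csv(path, sep="\t")
    labels = df["cluster"].to_numpy(dtype=int)
    return ClusterAssignment(
        cell_ids=df["cell_id"].to_numpy(dtype=object),
        cluster_of=labels,
        k=int(labels.max()) + 1 if len(labels) else 0,
    )


def write_embedding(embedding: np.ndarray, cell_ids, path) -> None:
    cols = [f"dim_{i}" for i in range(embedding.shape[1])]
    pd.DataFrame(embedding, index=cell_ids, columns=cols).to_csv(path)


def read_embedding(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64), df.index.to_numpy(dtype=object)
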