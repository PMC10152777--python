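"""Reading and writing expression matrices, labels and graphs.

Two matrix formats are supported:

* 10x-style Matrix Market triplet directories (``matrix.mtx`` plus
  ``barcodes.tsv`` and ``features.tsv``/``genes.tsv``). 10x matrices are
  stored genes x cells and are transposed to cells x genes on read.
* Dense CSV/TSV with a header row of gene ids and a first column of cell
  ids (cells x genes by default; ``orientation="genes_by_cells"`` reads the
  transpose).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CellGraph, ExpressionMatrix

__all__ = [
    "read_mtx_dir", "write_mtx_dir", "read_dense", "write_dense",
    "read_labels", "write_labels", "write_graph", "read_matrix",
]


def read_mtx_dir(path: str | Path) -> ExpressionMatrix:
    """Read a 10x-style Matrix Market directory (genes x cells on disk)."""
    path = Path(path)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"no matrix.mtx under {path}")
    m = sparse.csr_matrix(spio.mmread(mtx))
    barcodes = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0].astype(str).tolist()
    feat_file = path / "features.tsv"
    if not feat_file.exists():
        feat_file = path / "genes.tsv"
    feats = pd.read_csv(feat_file, header=None, sep="\t")
    # 2- or 3-column features files; the first column is the gene identifier
    genes = feats[0].astype(str).tolist()
    values = np.asarray(m.todense()).T  # genes x cells on disk -> cells x genes
    return ExpressionMatrix(values, barcodes, genes)


def write_mtx_dir(X: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    m = sparse.coo_matrix(X.values.T)  # stored genes x cells, 10x convention
    spio.mmwrite(path / "matrix.mtx", m)
    (path / "barcodes.tsv").write_text("\n".join(X.cell_ids) + "\n")
    feats = "\n".join(f"{g}\t{g}" for g in X.gene_ids) + "\n"
    (path / "features.tsv").write_text(feats)


def read_dense(path: str | Path, orientation: str = "cells_by_genes") -> ExpressionMatrix:
    """Read a dense CSV/TSV matrix with header gene ids and index cell ids."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes_by_cells":
        df = df.T
    elif orientation != "cells_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(df.to_numpy(dtype=float),
                            [str(c) for c in df.index],
                            [str(g) for g in df.columns])


def write_dense(X: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids).to_csv(path, sep=sep)


def read_matrix(path: str | Path, fmt: str | None = None,
                orientation: str = "cells_by_genes") -> ExpressionMatrix:
    """Dispatch on format: a directory is a 10x MTX triplet, a file is dense."""
    path = Path(path)
    if fmt == "mtx10x" or (fmt is None and path.is_dir()):
        return read_mtx_dir(path)
    return read_dense(path, orientation=orientation)


def read_labels(path: str | Path) -> pd.Series:
    """Read labels from a one- or two-column CSV (cell_id,label or label)."""
    df = pd.read_csv(path)
    if df.shape[1] == 1:
        return df.iloc[:, 0]
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def write_labels(labels, path: str | Path, cell_ids=None) -> None:
    if cell_ids is None:
        pd.DataFrame({"cluster": np.asarray(labels)}).to_csv(path, index=False)
    else:
        pd.DataFrame({"cell_id": list(cell_ids),
                      "cluster": np.asarray(labels)}).to_csv(path, index=False)


def write_graph(G: CellGraph, path: str | Path, fmt: str = "edgelist") -> None:
    """Write the graph as a weighted edge-list TSV or Matrix Market file."""
    path = Path(path)
    if fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(G.adjacency))
        return
    rows, cols = np.nonzero(G.adjacency)
    with open(path, "w") as fh:
        fh.write("cell_i\tcell_j\tweight\n")
        for i, j in zip(rows, cols):
            if i < j:  # undirected: emit each edge once
                fh.write(f"{G.cell_ids[i]}\t{G.cell_ids[j]}\t{G.adjacency[i, j]:.8g}\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
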