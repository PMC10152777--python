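"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionMatrix", "Embedding", "CellGraph", "SimilarityMatrix"]


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with string identifiers.

    On pipeline input `values` holds raw nonnegative counts; after
    normalization it holds log-transformed values. Identifiers must be
    unique and match the matrix dimensions.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, g = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene identifiers")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, cells=None, genes=None) -> "ExpressionMatrix":
        """Return a new matrix restricted to boolean/index selections."""
        v = self.values
        cid, gid = self.cell_ids, self.gene_ids
        if cells is not None:
            cells = np.asarray(cells)
            v = v[cells]
            cid = [cid[i] for i in np.flatnonzero(cells)] if cells.dtype == bool \
                else [cid[i] for i in cells]
        if genes is not None:
            genes = np.asarray(genes)
            v = v[:, genes]
            gid = [gid[i] for i in np.flatnonzero(genes)] if genes.dtype == bool \
                else [gid[i] for i in genes]
        return ExpressionMatrix(v, cid, gid)


@dataclass
class SimilarityMatrix:
    """Symmetric cell-cell similarity with an explicit zero diagonal."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("similarity matrix must be square")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity entries must be finite")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class CellGraph:
    """Sparse nonnegative cell-cell adjacency after KNN sparsification."""

    adjacency: np.ndarray
    k: int
    cell_ids: list[str]

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if (self.adjacency < 0).any():
            raise ValueError("graph weights must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def support(self, self_loops: bool = True) -> np.ndarray:
        """Boolean edge support, optionally with the diagonal forced on."""
        s = self.adjacency > 0
        if self_loops:
            s = s | np.eye(self.n_cells, dtype=bool)
        return s


@dataclass
class Embedding:
    """A cells x d latent representation."""

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.values.shape[0])]
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding values must be finite")

    @property
    def d(self) -> int:
        return self.values.shape[1]
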