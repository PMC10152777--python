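"""Quality-control filtering and normalization of raw count matrices.

Three filters, applied in a fixed order by :func:`preprocess`:

1. genes expressed (strictly positive) in fewer than ``min_cells`` cells
   are removed;
2. cells whose total UMI count or detected-gene count falls outside the
   Tukey fences [Q1 - m*IQR, Q3 + m*IQR] are removed;
3. genes whose aggregate expression (total counts over the remaining
   cells) strictly exceeds the chosen quantile of the per-gene aggregate
   distribution are removed (drops ubiquitously high genes such as
   housekeeping genes).

Cell QC runs on the cleaned gene set, while the high-expression quantile is
computed on QC-passed cells only. Library-size normalization with a log1p
transform is provided as the default transformation before similarity and
encoding; raw counts can be kept by skipping it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix

__all__ = [
    "FilterReport", "filter_genes_min_cells", "filter_genes_high_expression",
    "filter_cells_quartile_fence", "library_normalize_log", "preprocess",
]


@dataclass
class FilterReport:
    """Counts of removed genes/cells and the thresholds that removed them."""

    genes_removed_min_cells: int = 0
    genes_removed_high_expression: int = 0
    cells_removed: int = 0
    thresholds_used: dict = field(default_factory=dict)
    filter_order: list = field(default_factory=list)

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            self.genes_removed_min_cells + other.genes_removed_min_cells,
            self.genes_removed_high_expression + other.genes_removed_high_expression,
            self.cells_removed + other.cells_removed,
            {**self.thresholds_used, **other.thresholds_used},
            self.filter_order + other.filter_order,
        )

    def to_dict(self) -> dict:
        return {
            "genes_removed_min_cells": self.genes_removed_min_cells,
            "genes_removed_high_expression": self.genes_removed_high_expression,
            "cells_removed": self.cells_removed,
            "thresholds_used": self.thresholds_used,
            "filter_order": self.filter_order,
        }


def filter_genes_min_cells(
    X: ExpressionMatrix, min_cells: int = 3
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes with a strictly positive count in at least `min_cells` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    n_expressing = (X.values > 0).sum(axis=0)
    keep = n_expressing >= min_cells
    if not keep.any():
        raise ValueError(
            f"all {X.n_genes} genes expressed in fewer than {min_cells} cells; "
            "relax min_cells")
    report = FilterReport(
        genes_removed_min_cells=int((~keep).sum()),
        thresholds_used={"min_cells": min_cells},
        filter_order=["genes_min_cells"],
    )
    return X.subset(genes=keep), report


def filter_genes_high_expression(
    X: ExpressionMatrix, quantile: float = 0.75, statistic: str = "sum"
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove genes whose aggregate expression strictly exceeds a quantile.

    The aggregate is the per-gene total (``statistic="sum"``, default) or
    mean over cells; the cutoff is the linear-interpolation quantile of the
    aggregate distribution. Ties at the cutoff are retained.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    if X.n_genes < 2:
        raise ValueError("need at least 2 genes to compute a quantile cutoff")
    if statistic == "sum":
        agg = X.values.sum(axis=0)
    elif statistic == "mean":
        agg = X.values.mean(axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    cutoff = float(np.quantile(agg, quantile))  # linear interpolation
    keep = agg <= cutoff
    report = FilterReport(
        genes_removed_high_expression=int((~keep).sum()),
        thresholds_used={"high_expression_quantile": quantile,
                         "high_expression_cutoff": cutoff,
                         "high_expression_statistic": statistic},
        filter_order=["genes_high_expression"],
    )
    return X.subset(genes=keep), report


def filter_cells_quartile_fence(
    X: ExpressionMatrix, fence_multiplier: float = 1.5
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove cells outside the Tukey fences of total UMI or detected genes.

    For each cell the total count and the number of detected genes are
    computed; a cell is dropped if either statistic lies outside
    [Q1 - m*IQR, Q3 + m*IQR] of its own distribution.
    """
    if X.n_cells < 4:
        raise ValueError("need at least 4 cells for quartile fences")
    if fence_multiplier < 0:
        raise ValueError("fence_multiplier must be >= 0")

    keep = np.ones(X.n_cells, dtype=bool)
    bounds = {}
    for name, stat in (("total_umi", X.values.sum(axis=1)),
                       ("detected_genes", (X.values > 0).sum(axis=1))):
        q1, q3 = np.quantile(stat, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - fence_multiplier * iqr, q3 + fence_multiplier * iqr
        keep &= (stat >= lo) & (stat <= hi)
        bounds[name] = {"q1": float(q1), "q3": float(q3),
                        "lower": float(lo), "upper": float(hi)}
    if not keep.any():
        raise ValueError("quartile fence removed every cell; relax fence_multiplier")
    report = FilterReport(
        cells_removed=int((~keep).sum()),
        thresholds_used={"fence_multiplier": fence_multiplier,
                         "cell_fences": bounds},
        filter_order=["cells_quartile_fence"],
    )
    return X.subset(cells=keep), report


def library_normalize_log(X: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Divide each cell by its total count, scale, and apply log1p."""
    totals = X.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [X.cell_ids[i] for i in zero[:5]]
        raise ValueError(f"cells with zero total count: {names}"
                         + ("..." if zero.size > 5 else ""))
    v = np.log1p(X.values / totals[:, None] * scale)
    return ExpressionMatrix(v, X.cell_ids, X.gene_ids)


def preprocess(
    X: ExpressionMatrix,
    min_cells: int = 3,
    high_expression_quantile: float = 0.75,
    fence_multiplier: float = 1.5,
    normalize: bool = True,
    scale: float = 1e4,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Full QC in the fixed order gene-min-cells -> cell-fence -> gene-high-expr,
    optionally followed by library normalization + log1p."""
    X, r1 = filter_genes_min_cells(X, min_cells)
    X, r2 = filter_cells_quartile_fence(X, fence_multiplier)
    X, r3 = filter_genes_high_expression(X, high_expression_quantile)
    report = r1.merge(r2).merge(r3)
    if normalize:
        X = library_normalize_log(X, scale)
        report.thresholds_used["normalize_scale"] = scale
        report.filter_order.append("library_normalize_log")
    return X, report
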