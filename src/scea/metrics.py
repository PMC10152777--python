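"""Clustering agreement metrics: Adjusted Rand Index and NMI.

Both are computed from the contingency table of the two partitions. ARI is
the chance-corrected pair-counting index

    ARI = (sum_ij C(n_ij,2) - E) / (max - E),
    E   = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2),
    max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2,

with all pair counts in exact integer arithmetic. NMI normalizes the mutual
information I(X;Y); the default divides by the arithmetic mean of the
marginal entropies (2I / (H(X)+H(Y)), which reaches 1 for a perfect
clustering), and an alternative ``logkc`` normalization
I / (2(log K + log c)) over the cluster/class counts is exposed as well.
Logs are natural; the mean-normalized value is base-invariant.
"""

from __future__ import annotations

import numpy as np

__all__ = ["contingency", "ari", "nmi", "mutual_information", "entropy", "metrics_report"]


def contingency(labels_a, labels_b) -> np.ndarray:
    """r x c co-assignment count table of two equal-length labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"label vectors must be equal-length 1-d, got {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty label vectors")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def _comb2(x) -> int:
    x = int(x)
    return x * (x - 1) // 2


def ari(labels_true, labels_pred) -> float:
    """Adjusted Rand Index in [-1, 1]; 1 iff identical up to relabeling."""
    t = contingency(labels_true, labels_pred)
    n = int(t.sum())
    sum_ij = sum(_comb2(v) for v in t.ravel())
    sum_a = sum(_comb2(v) for v in t.sum(axis=1))
    sum_b = sum(_comb2(v) for v in t.sum(axis=0))
    total = _comb2(n)
    if total == 0:
        return 1.0
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:  # both partitions trivial (all singletons / one block)
        return 1.0
    return float((sum_ij - expected) / (maximum - expected))


def entropy(labels) -> float:
    """Shannon entropy (nats) of a labeling's empirical distribution."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(labels_a, labels_b) -> float:
    """I(X;Y) in nats from the contingency table."""
    t = contingency(labels_a, labels_b).astype(float)
    n = t.sum()
    p = t / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def nmi(labels_true, labels_pred, normalization: str = "mean") -> float:
    """Normalized mutual information in [0, 1].

    ``mean``: 2I / (H(X) + H(Y)). ``logkc``: I / (2(log K + log c))
    with K, c the numbers of predicted clusters and true classes.
    """
    a = np.asarray(labels_true)
    b = np.asarray(labels_pred)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if normalization == "mean":
        # the entropy identity I = H(X) + H(Y) - H(X,Y) keeps the perfect-
        # agreement case exactly 1 in floating point (2h / (h + h))
        hx, hy = entropy(a), entropy(b)
        hxy = entropy([f"{x}\x1f{y}" for x, y in zip(a, b)])
        if hx + hy == 0:  # both partitions constant: identical by convention
            return 1.0
        mi = hx + hy - hxy
        if mi <= 0:
            return 0.0
        return float(min(2.0 * mi / (hx + hy), 1.0))
    mi = mutual_information(a, b)
    if normalization == "logkc":
        K = len(np.unique(b))
        c = len(np.unique(a))
        denom = 2.0 * (np.log(K) + np.log(c))
        if denom == 0:
            return 1.0 if mi == 0 else 0.0
        return float(mi / denom)
    raise ValueError(f"unknown normalization {normalization!r}")


def metrics_report(labels_true, labels_pred, normalization: str = "mean") -> dict:
    """Bundle ARI/NMI with partition sizes for the run manifest."""
    a = np.asarray(labels_true)
    b = np.asarray(labels_pred)
    return {
        "ari": ari(a, b),
        "nmi": nmi(a, b, normalization),
        "n_cells": int(a.size),
        "K_true": int(len(np.unique(a))),
        "K_pred": int(len(np.unique(b))),
        "normalization": normalization,
    }
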