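"""Synthetic cluster-structured scRNA-seq count generation.

Every downstream stage of the pipeline is testable against matrices from
this module: gamma-Poisson (negative binomial) counts with per-cluster
multiplicative fold changes on a random subset of differentially expressed
genes, followed by independent Bernoulli zero-masking that emulates
technical dropout. Ground-truth cluster labels are returned alongside the
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate_counts", "generate_partition_pair"]


@dataclass
class SyntheticSpec:
    """Parameters of the count simulator.

    n_cells, n_genes, n_clusters
        Matrix dimensions and the number of ground-truth groups.
    de_fraction
        Fraction of genes given a cluster-specific fold change, per cluster.
    log_fold_change
        Natural-log fold change applied (up or down, random direction) to
        each differentially expressed gene; larger values separate clusters
        more strongly.
    dropout_rate
        Probability that any entry is force-zeroed after sampling,
        independently of its value (technical zeros).
    dispersion
        Negative-binomial over-dispersion phi, so var = mu + phi * mu^2.
    """

    n_cells: int
    n_genes: int
    n_clusters: int
    de_fraction: float = 0.2
    log_fold_change: float = 2.0
    dropout_rate: float = 0.4
    dispersion: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be a positive integer")
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be a positive integer")
        if self.n_clusters > self.n_cells:
            raise ValueError("n_clusters must not exceed n_cells")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.n_clusters > 1 and self.de_fraction * self.n_genes < 1:
            raise ValueError(
                "de_fraction too small: no differentially expressed gene "
                f"(de_fraction*n_genes = {self.de_fraction * self.n_genes:.3g} < 1)")
        if self.log_fold_change < 0:
            raise ValueError("log_fold_change must be nonnegative")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def generate_counts(spec: SyntheticSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw a counts matrix and its ground-truth labels.

    Per-gene base means are log-normal; each cluster multiplies a random
    ``de_fraction`` subset of genes by ``exp(+/- log_fold_change)``; counts
    are gamma-Poisson draws around the resulting means; dropout is an
    independent Bernoulli mask applied last. All randomness flows through
    one generator seeded by ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g, K = spec.n_cells, spec.n_genes, spec.n_clusters

    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=g)

    # cluster-specific mean profiles: multiplicative fold change on a random
    # DE gene subset per cluster, direction chosen at random per gene
    n_de = int(round(spec.de_fraction * g))
    cluster_means = np.tile(base_mean, (K, 1))
    for k in range(K):
        if n_de > 0 and spec.log_fold_change > 0:
            de_genes = rng.choice(g, size=n_de, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_de)
            cluster_means[k, de_genes] *= np.exp(signs * spec.log_fold_change)

    # balanced label assignment, shuffled so clusters are not contiguous
    labels = np.arange(n) % K
    rng.shuffle(labels)

    mu = cluster_means[labels]  # n x g
    shape = 1.0 / spec.dispersion
    lam = rng.gamma(shape=shape, scale=mu * spec.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    if spec.dropout_rate > 0:
        mask = rng.random(size=(n, g)) < spec.dropout_rate
        counts[mask] = 0

    cell_ids = [f"cell_{i}" for i in range(n)]
    gene_ids = [f"gene_{j}" for j in range(g)]
    return ExpressionMatrix(counts, cell_ids, gene_ids), labels


def generate_partition_pair(
    n: int, K: int, noise: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """A partition of n items into K groups and a noisy copy.

    The copy reassigns ``floor(noise * n)`` positions uniformly at random
    over the K labels (a reassignment may redraw the original label, so the
    observable number of differing positions is at most the floor).
    noise=0 returns identical partitions; noise=1 returns an independent
    partition.
    """
    if not 1 <= K <= n:
        raise ValueError(f"need 1 <= K <= n, got K={K}, n={n}")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    # guarantee every label appears, then shuffle
    a = np.concatenate([np.arange(K), rng.integers(0, K, size=n - K)])
    rng.shuffle(a)
    b = a.copy()
    m = int(np.floor(noise * n))
    if m > 0:
        idx = rng.choice(n, size=m, replace=False)
        b[idx] = rng.integers(0, K, size=m)
    return a, b
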