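# Methods

## Overview

`scea` clusters single-cell RNA-seq count matrices in four stages:

1. **Quality control.** Genes expressed (count > 0) in fewer than 3 cells
   are removed; cells whose total UMI count or detected-gene count falls
   outside the Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of either
   statistic are removed; genes whose total count strictly exceeds the 75th
   percentile of the per-gene total distribution are removed (this drops
   ubiquitously expressed genes, e.g. housekeeping genes, that carry no
   cluster signal). Counts are then library-size normalized
   (counts / cell total × 10⁴) and log1p-transformed.
2. **Cell graph.** Pearson correlation between cell expression profiles
   forms the initial similarity matrix (diagonal zeroed, negatives clipped
   to 0). Network Enhancement denoises it: the matrix is localized to each
   cell's `k_ne` strongest neighbors, scaled to doubly stochastic T by
   symmetric Sinkhorn iteration, and the diffusion fixed point of
   W ← αTWTᵀ + (1−α)T is computed. KNN sparsification then keeps each
   cell's k strongest edges (union-symmetrized).
3. **Dimension reduction.** A three-layer tanh MLP (4096 → 2048 → 1024)
   is pretrained as a mirrored autoencoder under mean absolute error (MAE)
   and its encoder half embeds cells into 1024 dimensions, optionally
   standardized per dimension ((x − mean)/sd, population sd). A two-layer
   multi-head graph attention autoencoder over the cell graph then
   compresses to a 64-dimensional latent code, again under MAE.
4. **Clustering.** k-means (10 restarts) initializes K centers in the
   latent space; a Student-t kernel q_ij ∝ (1 + ‖z_i − μ_j‖²)⁻¹ gives soft
   memberships; the sharpened target p_ij ∝ q_ij²/f_j (f_j = Σ_i q_ij) is
   recomputed every `update_interval` epochs; network parameters and
   centers are jointly refined under MAE + λ·KL(P‖Q) until fewer than
   `tol` of cells change hard label between target updates. Final labels
   are argmax of Q (a terminal k-means on the refined latent is available
   as a flag).

Agreement with ground truth is scored by the adjusted Rand index (exact
integer pair counting) and normalized mutual information (natural logs;
default normalization 2I/(H(X)+H(Y))).

## Model assumptions

- Cluster identity is expressed as multiplicative shifts of gene means;
  Pearson correlation on log-normalized profiles is therefore an
  informative similarity.
- Technical zeros (dropout) are noise to be tolerated, not modeled: no
  imputation is performed; the graph diffusion and the attention
  aggregation average over neighborhoods instead.
- The number of clusters K is a required input; no model selection is
  attempted.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_cells` | 3 | a gene must be expressed in ≥ 3 cells |
| `high_expression_quantile` | 0.75 | per-gene total above this quantile ⇒ removed; linear-interpolation quantile; ties retained |
| `fence_multiplier` | 1.5 | Tukey fence width for cell QC; a bare [Q1, Q3] interval would discard half the cells |
| `ne_alpha` | 0.9 | diffusion retention; eigenvalues map to (1−α)d/(1−αd^order), a contraction for |d| < 1 |
| `ne_order` | 2 | diffusion order; 2 runs the literal iteration, other orders use the equivalent spectral map |
| `k_ne` | min(20, ⌈n/10⌉) | NE localization neighborhood |
| `knn_k` | ⌈n/2K⌉ clipped to [3, 30] | final graph degree; falls back to 15 when K is unknown |
| `encoder_dims` | (4096, 2048, 1024) | MLP widths; inputs with fewer genes than 4096 warn (the first layer widens) but run |
| `encoder_lr` | 2e-4 | Adam on full-batch MAE; 1e-3 overshoots at these layer widths (loss rises), 2e-4 gives a decreasing trace |
| `gat_hidden`, `gat_latent` | 256, 64 | latent width comfortably exceeds typical cluster counts; per-head width is ⌈hidden/heads⌉ so any head count runs |
| `n_heads` | 8 | the sweep {2,4,6,8,10} is exposed as a pure config change |
| `leaky_slope` | 0.2 | LeakyReLU slope in attention scores |
| `lambda_kld` | 1.0 | weight of the clustering KL term against reconstruction |
| `update_interval`, `tol` | 20, 0.001 | target-distribution refresh cadence and label-stability stopping rule |
| epochs | 30 / 120 / 150 | encoder / GAT / refinement; chosen so a 500-cell run completes in minutes on one CPU with full-batch Adam |

## Synthetic data

The generator draws per-gene base means from LogNormal(0, 1), applies a
multiplicative fold change e^±lfc to a random `de_fraction` subset of genes
per cluster (direction random per gene), samples gamma-Poisson (negative
binomial, var = μ + φμ²) counts, and force-zeroes each entry independently
with probability `dropout_rate`. Defaults (500 cells, 2000 genes, K = 5,
lfc = 2, 40% dropout, φ = 0.3) produce matrices with ~60–70% zeros and
cluster structure comparable to curated benchmark datasets of similar size.

What it emulates: sparsity, over-dispersion, balanced cluster sizes,
cluster-specific differential expression. What it does not: batch effects,
trajectories/continuous states, cell-size covariation, gene–gene
correlation beyond cluster structure, or empty droplets. Passing tests on
this generator demonstrate the pipeline's mechanics and recovery of planted
partitions, not performance on real tissue atlases.

## Numerical choices

- All training runs on an in-package reverse-mode autodiff core over numpy
  arrays (float32 by default), with Adam; randomness enters only through
  seeded `numpy.random.Generator` initialization, so fixed seeds give
  bit-identical runs on fixed BLAS settings.
- Attention softmax is computed on the graph support only (self-loops
  always added), with row-max stabilization; isolated cells attend to
  themselves with weight exactly 1.
- Sinkhorn scaling iterates D^(−1/2) W D^(−1/2) (preserves symmetry),
  tolerance 1e−6 on row/column sums, max 1000 iterations; non-convergence
  raises with the last residual.
- Quantiles use the linear-interpolation definition throughout.
- KNN ties at the k-th value break toward the smaller column index;
  soft-assignment ties break toward the smaller cluster index.
- Standardization uses population sd (ddof = 0); zero-sd dimensions map to
  all-zeros.
- ARI pair counts use exact integer arithmetic (no overflow for any
  realistic n); NMI's default normalization is computed via the entropy
  identity I = H(X) + H(Y) − H(X,Y) so perfect agreement is exactly 1 in
  floating point.

## Design decisions on genuinely open points

- **Encoder training signal.** The MLP is pretrained as a mirrored
  autoencoder under MAE and the decoder is discarded, rather than trained
  end-to-end with the attention stage; this keeps the stages separately
  testable and the embedding reusable.
- **Normalization before correlation.** Library-size + log1p normalization
  is applied by default before Pearson similarity and encoding
  (`normalize=False` disables it); correlations on raw counts are dominated
  by library size.
- **High-expression filter statistic.** "Expression above the 75th
  percentile" is read as a per-gene aggregate (total counts), the only
  reading that removes ubiquitously high genes rather than arbitrary matrix
  entries; the statistic (sum/mean) and quantile are configurable and the
  realized cutoff is recorded in the filter report.
- **NE edge weights vs. attention.** The denoised, sparsified graph enters
  the attention layers as a binary support mask; attention coefficients are
  learned, not seeded from edge weights.
- **Head merging.** Concatenation on hidden layers, averaging on the layers
  producing the latent code and the reconstruction.
- **Final labels.** Argmax of the soft assignment, with `terminal_kmeans`
  re-clustering the refined latent as an alternative endpoint.

## Known limitations

- The two quantile-based QC filters are not strictly idempotent: removing
  the tail shifts the recomputed quantile, so a second application can
  remove more. Each pass is a fixed point with respect to its recorded
  cutoff; re-apply with that cutoff for strict idempotence.
- Dense n × n similarity/attention matrices bound practical problem size to
  a few thousand cells per run on one CPU.
- Full-batch MAE training with Adam is deliberately conservative
  (lr 2e-4); reconstruction improves slowly, which suffices because the
  clustering signal lives in the embedding geometry, not reconstruction
  fidelity.
- NMI's literal `logkc` normalization I/(2(log K + log c)) cannot reach
  1 even for a perfect clustering; it is provided for comparability but the
  arithmetic-mean normalization is the default and the one reported.
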