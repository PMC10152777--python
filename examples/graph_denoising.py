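"""Network Enhancement on a noisy two-community similarity matrix.

Builds a 40-cell similarity matrix with two communities blurred by
cross-community noise, denoises it, and prints the eigengap of the
degree-normalized matrix before and after. A larger gap means the community
structure is spectrally cleaner, which is what the downstream attention
stage relies on.
"""

import numpy as np

from scea.containers import SimilarityMatrix
from scea.graph import knn_sparsify, network_enhancement, normalized_eigengap

rng = np.random.default_rng(0)
n, half = 40, 20
S = rng.uniform(0.0, 0.1, size=(n, n))
S[:half, :half] += rng.uniform(0.5, 0.9, size=(half, half))
S[half:, half:] += rng.uniform(0.5, 0.9, size=(half, half))
S = (S + S.T) / 2.0
np.fill_diagonal(S, 0.0)

Sm = SimilarityMatrix(S, [f"cell_{i}" for i in range(n)])

# localization wider than the communities keeps the graph connected: the
# diffusion contracts every sub-leading eigenvalue, widening the gap
W = network_enhancement(Sm, k_ne=25, alpha=0.9, order=2)
print(f"normalized eigengap before NE: {normalized_eigengap(S):.4f}")
print(f"normalized eigengap after NE:  {normalized_eigengap(W.values):.4f}")

# localization below the community size drops the weak cross edges entirely
W10 = network_enhancement(Sm, k_ne=10, alpha=0.9, order=2)
frac_before = S[:half, half:].sum() / S.sum()
frac_after = W10.values[:half, half:].sum() / W10.values.sum()
print(f"cross-community weight share (k_ne=10): {frac_before:.3f} -> "
      f"{frac_after:.3f}")

G = knn_sparsify(W10, k=8)
print(f"KNN graph: {int((G.adjacency > 0).sum() // 2)} undirected edges, "
      "all within the two communities")
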