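"""Attention-head count and standardization sweep on one dataset.

Runs the pipeline's two headline configuration studies as pure config
changes — the number of attention heads in {2,4,6,8,10} and the encoder
output standardization on/off — reusing the shared preprocessing, graph and
encoder stages, and prints one (ARI, NMI) row per setting.
"""

from scea import PipelineConfig, SyntheticSpec, generate_counts
from scea.pipeline import config_sweep

spec = SyntheticSpec(n_cells=300, n_genes=800, n_clusters=4,
                     log_fold_change=3.0, dropout_rate=0.4, seed=2)
X, truth = generate_counts(spec)

base = PipelineConfig(K=4, seed=2, encoder_epochs=6, gat_epochs=20,
                      refine_epochs=10, update_interval=5)
table = config_sweep(X, truth, base, heads=(2, 4, 6, 8, 10),
                     standardize_modes=(True, False))
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nEach row is an independent training run differing only in the named"
      "\nsetting; on well-separated synthetic data the spread between settings"
      "\nis small, matching the sweep's role as a robustness check.")
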