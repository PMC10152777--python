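"""Second-stage dimension reduction: a multi-head graph attention autoencoder.

Two attention layers encode the MLP embedding into a low-dimensional latent
space over the denoised cell graph; a structurally symmetric decoder (its
own parameters) reconstructs the input, and the pair is trained under mean
absolute error. Per head, edge scores are
``e_ij = LeakyReLU(a^T [W h_i || W h_j])`` softmax-normalized over each
node's neighborhood (self-loops always included), so every attention map is
row-stochastic on the graph support. Heads are merged by concatenation on
hidden layers and by averaging on the layers that produce the latent code
and the reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Adam, Parameter, Tensor, concat, masked_softmax
from .containers import CellGraph, Embedding

__all__ = [
    "GATConfig", "GATState", "attention_layer", "init_head_params",
    "train_gat_autoencoder", "gat_forward", "mae_loss",
]


@dataclass
class GATConfig:
    input_dim: int = 1024
    hidden_dim: int = 256
    latent_dim: int = 64
    n_heads: int = 8
    leaky_slope: float = 0.2
    epochs: int = 120
    learning_rate: float = 1e-3
    seed: int = 0
    dtype: str = "float32"

    def validate(self, n_clusters: int | None = None) -> None:
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if min(self.input_dim, self.hidden_dim, self.latent_dim) < 1:
            raise ValueError("layer widths must be positive")
        if n_clusters is not None and self.latent_dim < n_clusters:
            import warnings
            warnings.warn("latent_dim is smaller than the cluster count")


def init_head_params(rng: np.random.Generator, in_dim: int, out_dim: int,
                     n_heads: int, dtype=np.float32) -> list[dict]:
    """Per-head weights: feature map W and split attention vector (a_src, a_dst)."""
    heads = []
    bound = 1.0 / np.sqrt(in_dim)
    ab = 1.0 / np.sqrt(out_dim)
    for _ in range(n_heads):
        heads.append({
            "W": Parameter(rng.uniform(-bound, bound, (in_dim, out_dim)).astype(dtype)),
            "a_src": Parameter(rng.uniform(-ab, ab, (out_dim, 1)).astype(dtype)),
            "a_dst": Parameter(rng.uniform(-ab, ab, (out_dim, 1)).astype(dtype)),
        })
    return heads


def attention_layer(
    H: Tensor | np.ndarray,
    G: CellGraph | np.ndarray,
    params: list[dict],
    merge: str = "concat",
    leaky_slope: float = 0.2,
    activation: str = "tanh",
) -> tuple[Tensor, list[np.ndarray]]:
    """One multi-head attention layer over the graph support.

    Returns the merged features (width ``n_heads * out_dim`` for concat,
    ``out_dim`` for average) and the per-head attention matrices, each
    row-stochastic on the edge support plus self-loops.
    """
    if not isinstance(H, Tensor):
        H = Tensor(np.asarray(H))
    support = G.support(self_loops=True) if isinstance(G, CellGraph) else np.asarray(G, bool)
    if H.shape[0] != support.shape[0]:
        raise ValueError(
            f"feature rows ({H.shape[0]}) must match graph nodes ({support.shape[0]})")
    support = support | np.eye(support.shape[0], dtype=bool)

    outs, maps = [], []
    for head in params:
        Wh = H @ head["W"]
        f_src = Wh @ head["a_src"]            # n x 1
        f_dst = Wh @ head["a_dst"]
        logits = (f_src + f_dst.T).leaky_relu(leaky_slope)
        A = masked_softmax(logits, support)
        outs.append(A @ Wh)
        maps.append(A.data.copy())
    merged = concat(outs, axis=1) if merge == "concat" else _mean_tensors(outs)
    if activation == "tanh":
        merged = merged.tanh()
    elif activation != "linear":
        raise ValueError(f"unknown activation {activation!r}")
    return merged, maps


def _mean_tensors(ts: list[Tensor]) -> Tensor:
    out = ts[0]
    for t in ts[1:]:
        out = out + t
    return out * (1.0 / len(ts))


@dataclass
class GATState:
    """Parameters of the four attention layers (enc x2, dec x2) plus config."""

    layers: list          # list of per-layer head-parameter lists
    config: GATConfig
    loss_trace: list = field(default_factory=list)

    def parameters(self) -> list:
        return [p for layer in self.layers for head in layer for p in head.values()]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for li, layer in enumerate(self.layers):
            for hi, head in enumerate(layer):
                for name, p in head.items():
                    arrays[f"l{li}_h{hi}_{name}"] = p.data
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(
            {"config": self.config.__dict__, "loss_trace": self.loss_trace}, indent=2))


def _build_layers(cfg: GATConfig) -> list:
    rng = np.random.default_rng(cfg.seed)
    dtype = np.dtype(cfg.dtype)
    # per-head width rounds up so any head count works; concat width is
    # per_head * n_heads (~hidden_dim)
    per_head = max(1, int(np.ceil(cfg.hidden_dim / cfg.n_heads)))
    width = per_head * cfg.n_heads
    return [
        # encoder: input -> hidden (concat), hidden -> latent (average)
        init_head_params(rng, cfg.input_dim, per_head, cfg.n_heads, dtype),
        init_head_params(rng, width, cfg.latent_dim, cfg.n_heads, dtype),
        # decoder: latent -> hidden (concat), hidden -> input (average)
        init_head_params(rng, cfg.latent_dim, per_head, cfg.n_heads, dtype),
        init_head_params(rng, width, cfg.input_dim, cfg.n_heads, dtype),
    ]


def gat_forward(state: GATState, H: Tensor, support: np.ndarray,
                collect_attention: bool = False):
    """Full forward pass; returns (reconstruction, latent, attention maps)."""
    cfg = state.config
    maps = []
    h1, m1 = attention_layer(H, support, state.layers[0], "concat",
                             cfg.leaky_slope, "tanh")
    z, m2 = attention_layer(h1, support, state.layers[1], "average",
                            cfg.leaky_slope, "linear")
    d1, m3 = attention_layer(z, support, state.layers[2], "concat",
                             cfg.leaky_slope, "tanh")
    recon, m4 = attention_layer(d1, support, state.layers[3], "average",
                                cfg.leaky_slope, "linear")
    if collect_attention:
        maps = [m1, m2, m3, m4]
    return recon, z, maps


def mae_loss(X, X_hat) -> float:
    """Mean absolute error between two equal-shape matrices."""
    a = X.data if isinstance(X, Tensor) else np.asarray(X)
    b = X_hat.data if isinstance(X_hat, Tensor) else np.asarray(X_hat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def train_gat_autoencoder(
    E: Embedding, G: CellGraph, cfg: GATConfig | None = None
) -> tuple[GATState, Embedding]:
    """Train the attention autoencoder on the cell graph; return latent codes."""
    if cfg is None:
        cfg = GATConfig(input_dim=E.d)
    cfg.validate()
    if E.values.shape[0] != G.n_cells:
        raise ValueError("embedding and graph disagree on the number of cells")
    if cfg.input_dim != E.d:
        raise ValueError(f"cfg.input_dim={cfg.input_dim} but embedding width is {E.d}")

    dtype = np.dtype(cfg.dtype)
    data = E.values.astype(dtype)
    support = G.support(self_loops=True)
    state = GATState(_build_layers(cfg), cfg)
    opt = Adam(state.parameters(), lr=cfg.learning_rate)
    X = Tensor(data)

    for epoch in range(cfg.epochs):
        recon, _, _ = gat_forward(state, X, support)
        loss = (recon - X).abs().mean()
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"non-finite GAT loss at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        state.loss_trace.append(loss.item())

    _, z, _ = gat_forward(state, X, support)
    return state, Embedding(z.data.astype(float), E.cell_ids)
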