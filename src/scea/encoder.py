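"""First-stage non-linear dimension reduction: a tanh MLP autoencoder.

The encoder maps the preprocessed gene space through three tanh layers
(4096 -> 2048 -> 1024 by default); a mirrored decoder with its own weights
reconstructs the input, and the pair is pretrained under mean absolute
error. After pretraining the decoder is discarded and the encoder half
embeds cells into the 1024-dimensional latent space. The latent output can
optionally be standardized per dimension ((x - mean)/sd), which toggles the
pipeline's "_s" vs "_ns" modes as a pure configuration change.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Adam, Parameter, Tensor
from .containers import Embedding, ExpressionMatrix

__all__ = ["EncoderConfig", "EncoderState", "pretrain_encoder", "encode", "standardize"]

DEFAULT_DIMS = (4096, 2048, 1024)


@dataclass
class EncoderConfig:
    layer_dims: tuple = DEFAULT_DIMS
    activation: str = "tanh"
    epochs: int = 30
    learning_rate: float = 2e-4
    seed: int = 0
    standardize_output: bool = True
    batch_threshold: int = 2048  # full batch up to this many cells
    batch_size: int = 256
    dtype: str = "float32"

    def validate(self) -> None:
        dims = tuple(int(d) for d in self.layer_dims)
        if any(d < 1 for d in dims):
            raise ValueError("layer dims must be positive")
        if dims[-1] < 2:
            raise ValueError("last layer dim must be >= 2")
        if any(a <= b for a, b in zip(dims, dims[1:])):
            warnings.warn("encoder layer dims are not strictly decreasing")
        if self.activation != "tanh":
            raise ValueError("only tanh activation is supported")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EncoderState:
    """Trained weights (encoder + decoder) with config and loss trace."""

    weights: list  # alternating W, b per layer, encoder then decoder
    input_dim: int
    config: EncoderConfig
    loss_trace: list = field(default_factory=list)

    @property
    def n_encoder_layers(self) -> int:
        return len(self.config.layer_dims)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "input_dim": self.input_dim,
            "config": {**self.config.__dict__,
                       "layer_dims": list(self.config.layer_dims)},
            "loss_trace": self.loss_trace,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EncoderState":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_d = sidecar["config"]
        cfg_d["layer_dims"] = tuple(cfg_d["layer_dims"])
        cfg = EncoderConfig(**cfg_d)
        with np.load(path.with_suffix(".npz")) as z:
            weights = [z[f"w{i}"] for i in range(len(z.files))]
        return cls(weights, sidecar["input_dim"], cfg, sidecar["loss_trace"])


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int, dtype):
    """Uniform fan-in scaled initialization."""
    bound = 1.0 / np.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(dtype)
    b = np.zeros(fan_out, dtype=dtype)
    return W, b


def _build_weights(input_dim: int, cfg: EncoderConfig) -> list[np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    dtype = np.dtype(cfg.dtype)
    dims = [input_dim] + list(cfg.layer_dims)
    weights = []
    for a, b in zip(dims, dims[1:]):  # encoder
        weights.extend(_init_linear(rng, a, b, dtype))
    for a, b in zip(dims[::-1], dims[::-1][1:]):  # mirrored decoder
        weights.extend(_init_linear(rng, a, b, dtype))
    return weights


def _forward(params: list[Tensor], H: Tensor, n_enc: int, upto: int | None = None):
    """Run tanh layers; decoder output layer is linear (reconstructs log counts)."""
    n_layers = len(params) // 2
    stop = n_layers if upto is None else upto
    for li in range(stop):
        W, b = params[2 * li], params[2 * li + 1]
        H = H @ W + b
        if li < n_layers - 1 or upto is not None:
            H = H.tanh()
    return H


def pretrain_encoder(X: ExpressionMatrix | np.ndarray, cfg: EncoderConfig) -> EncoderState:
    """Pretrain the mirrored MLP autoencoder under MAE reconstruction loss.

    Full-batch training for datasets up to ``cfg.batch_threshold`` cells,
    mini-batches of ``cfg.batch_size`` beyond. The loss trace records the
    epoch-mean MAE computed on the forward pass before each update.
    """
    cfg.validate()
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X)
    if values.size == 0:
        raise ValueError("empty input matrix")
    n, g = values.shape
    if g < cfg.layer_dims[0]:
        warnings.warn(
            f"input has {g} genes, fewer than the first encoder layer "
            f"({cfg.layer_dims[0]}); the layer widens rather than reduces")
    dtype = np.dtype(cfg.dtype)
    data = values.astype(dtype)
    weights = _build_weights(g, cfg)
    params = [Parameter(w) for w in weights]
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    full_batch = n <= cfg.batch_threshold

    trace: list[float] = []
    for epoch in range(cfg.epochs):
        if full_batch:
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = np.array_split(perm, int(np.ceil(n / cfg.batch_size)))
        epoch_loss, n_seen = 0.0, 0
        for idx in batches:
            xb = Tensor(data[idx])
            recon = _forward(params, xb, len(cfg.layer_dims))
            loss = (recon - xb).abs().mean()
            if not np.isfinite(loss.item()):
                raise FloatingPointError(f"non-finite pretraining loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
            n_seen += len(idx)
        trace.append(epoch_loss / n_seen)

    return EncoderState([p.data for p in params], g, cfg, trace)


def encode(state: EncoderState, X: ExpressionMatrix | np.ndarray) -> Embedding:
    """Map cells through the trained encoder half (output in (-1, 1))."""
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X)
    cell_ids = X.cell_ids if isinstance(X, ExpressionMatrix) else None
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != state.input_dim:
        raise ValueError(
            f"input width {values.shape[1]} does not match trained width "
            f"{state.input_dim}")
    params = [Tensor(w) for w in state.weights]
    H = Tensor(values.astype(state.weights[0].dtype))
    out = _forward(params, H, state.n_encoder_layers, upto=state.n_encoder_layers)
    return Embedding(out.data.astype(float), cell_ids or [])


def standardize(E: Embedding) -> Embedding:
    """Per-dimension (x - mean)/sd with population sd; constant dims -> 0."""
    v = E.values.astype(float)
    mean = v.mean(axis=0)
    sd = v.std(axis=0)  # ddof=0
    out = np.zeros_like(v)
    nz = sd > 0
    out[:, nz] = (v[:, nz] - mean[nz]) / sd[nz]
    return Embedding(out, E.cell_ids)
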