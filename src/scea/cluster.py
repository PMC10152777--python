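"""Self-optimizing clustering head over the latent embedding.

Cluster centers are initialized by k-means in the latent space; soft
memberships follow the deep-embedded-clustering convention of a Student-t
kernel ``q_ij \\propto (1 + ||z_i - mu_j||^2)^{-1}``; the target
distribution sharpens the memberships
(``p_ij \\propto q_ij^2 / f_j`` with cluster frequency ``f_j``); and
refinement jointly updates the attention autoencoder and the centers under
``MAE + lambda * KL(P || Q)``, recomputing P on a fixed interval and
stopping when hard labels stabilize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .autograd import Parameter, Adam, Tensor
from .containers import CellGraph, Embedding
from .gat import GATState, gat_forward

__all__ = [
    "SoftAssignment", "RefineConfig", "kmeans_init", "soft_assign",
    "target_distribution", "kld_loss", "refine", "hard_labels",
]


@dataclass
class SoftAssignment:
    """Row-stochastic membership matrix Q with its cluster centers."""

    Q: np.ndarray
    centers: np.ndarray

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if (self.Q < 0).any():
            raise ValueError("soft assignments must be nonnegative")
        if np.abs(self.Q.sum(axis=1) - 1.0).max(initial=0.0) > 1e-8:
            raise ValueError("soft assignment rows must sum to 1")
        if self.Q.shape[1] != self.centers.shape[0]:
            raise ValueError("Q columns must match the number of centers")

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def kmeans_init(
    Z: Embedding | np.ndarray, K: int, seed: int = 0, n_restarts: int = 10
) -> tuple[SoftAssignment, np.ndarray]:
    """Best-inertia k-means over restarts; returns soft assignment + labels."""
    values = Z.values if isinstance(Z, Embedding) else np.asarray(Z)
    if K > values.shape[0]:
        raise ValueError(f"K={K} exceeds the number of cells ({values.shape[0]})")
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(values)
    sa = soft_assign(values, km.cluster_centers_)
    return sa, labels.astype(int)


def soft_assign(Z: Embedding | np.ndarray, centers: np.ndarray) -> SoftAssignment:
    """Student-t (one degree of freedom) soft membership of cells to centers."""
    values = Z.values if isinstance(Z, Embedding) else np.asarray(Z)
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("centers must be nonempty")
    d2 = ((values[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    q = 1.0 / (1.0 + d2)
    q /= q.sum(axis=1, keepdims=True)
    return SoftAssignment(q, centers)


def target_distribution(Q: SoftAssignment | np.ndarray) -> np.ndarray:
    """Sharpened target: p_ij = (q_ij^2/f_j) / sum_j'(q_ij'^2/f_j')."""
    q = Q.Q if isinstance(Q, SoftAssignment) else np.asarray(Q, dtype=float)
    f = q.sum(axis=0)
    w = q ** 2 / f
    return w / w.sum(axis=1, keepdims=True)


def kld_loss(P, Q) -> float:
    """KL(P || Q) = sum_ij p log(p/q), averaged over cells (matrix rows)."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    pos = P > 0
    if (Q[pos] == 0).any():
        raise ValueError("KL divergence undefined: q = 0 where p > 0")
    terms = np.zeros_like(P)
    terms[pos] = P[pos] * np.log(P[pos] / Q[pos])
    return float(terms.sum() / P.shape[0])


def hard_labels(Q: SoftAssignment | np.ndarray) -> np.ndarray:
    """Argmax membership per cell; ties resolve to the smallest cluster index."""
    q = Q.Q if isinstance(Q, SoftAssignment) else np.asarray(Q)
    return q.argmax(axis=1).astype(int)


@dataclass
class RefineConfig:
    lambda_kld: float = 1.0
    update_interval: int = 20
    tol: float = 0.001
    max_epochs: int = 150
    learning_rate: float = 1e-3

    def validate(self) -> None:
        if self.lambda_kld < 0:
            raise ValueError("lambda_kld must be >= 0")
        if self.update_interval < 1:
            raise ValueError("update_interval must be >= 1")
        if not 0.0 <= self.tol <= 1.0:
            raise ValueError("tol must lie in [0, 1]")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


def _soft_assign_tensor(z: Tensor, centers: Tensor) -> Tensor:
    """Differentiable Student-t soft assignment (for the refinement loss)."""
    n, d = z.shape
    K = centers.shape[0]
    diff = z.reshape(n, 1, d) - centers.reshape(1, K, d)
    d2 = (diff * diff).sum(axis=2)
    q_un = (d2 + 1.0) ** -1.0
    return q_un / q_un.sum(axis=1, keepdims=True)


def refine(
    gat_state: GATState,
    E: Embedding,
    G: CellGraph,
    Q0: SoftAssignment,
    cfg: RefineConfig | None = None,
) -> tuple[np.ndarray, SoftAssignment, dict]:
    """Jointly refine the autoencoder and the cluster centers.

    Minimizes ``mae_loss + lambda_kld * kld_loss`` by gradient steps on the
    GAT parameters and the centers. The target distribution P is recomputed
    every ``update_interval`` epochs; refinement stops when the fraction of
    cells changing hard label between consecutive P-updates falls below
    ``tol``, or at ``max_epochs``. Returns argmax-of-Q labels, the final
    soft assignment, and a trace of losses and label-change fractions.
    """
    if cfg is None:
        cfg = RefineConfig()
    cfg.validate()
    dtype = np.dtype(gat_state.config.dtype)
    support = G.support(self_loops=True)
    X = Tensor(E.values.astype(dtype))
    centers = Parameter(Q0.centers.astype(dtype))
    params = gat_state.parameters() + [centers]
    opt = Adam(params, lr=cfg.learning_rate)

    def current_q() -> np.ndarray:
        _, z, _ = gat_forward(gat_state, X, support)
        return _soft_assign_tensor(z, centers).data.astype(float)

    labels_prev = hard_labels(Q0)
    P = target_distribution(current_q())
    trace = {"loss": [], "mae": [], "kld": [], "label_change": []}
    eps = np.finfo(float).tiny

    for epoch in range(cfg.max_epochs):
        if epoch > 0 and epoch % cfg.update_interval == 0:
            q_np = current_q()
            P = target_distribution(q_np)
            labels_now = hard_labels(q_np)
            frac = float((labels_now != labels_prev).mean())
            trace["label_change"].append(frac)
            labels_prev = labels_now
            if frac < cfg.tol:
                break

        recon, z, _ = gat_forward(gat_state, X, support)
        mae = (recon - X).abs().mean()
        Qt = _soft_assign_tensor(z, centers)
        Pt = Tensor(P.astype(dtype))
        logp = Tensor(np.log(np.maximum(P, eps)).astype(dtype))
        kld = (Pt * (logp - Qt.log())).sum() * (1.0 / P.shape[0])
        loss = mae + cfg.lambda_kld * kld
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"non-finite refinement loss at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace["loss"].append(loss.item())
        trace["mae"].append(mae.item())
        trace["kld"].append(float(kld.item()))

    q_final = current_q()
    sa = SoftAssignment(q_final, centers.data.astype(float))
    return hard_labels(q_final), sa, trace
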