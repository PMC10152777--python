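"""End-to-end orchestration of the four pipeline stages.

``run_scea`` executes preprocessing -> cell-graph construction -> MLP
pretraining/encoding (optionally standardized) -> graph-attention
autoencoder -> k-means initialization -> self-optimizing refinement ->
hard labels, collecting a run manifest with per-stage dimensions, loss
traces, timings and (when truth labels are supplied) ARI/NMI. A master
seed deterministically derives the per-stage seeds.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .cluster import RefineConfig, hard_labels, kmeans_init, refine
from .containers import ExpressionMatrix
from .encoder import EncoderConfig, encode, pretrain_encoder, standardize
from .gat import GATConfig, train_gat_autoencoder
from .graph import build_cell_graph, default_knn_k
from .metrics import metrics_report
from .preprocessing import preprocess

__all__ = ["PipelineConfig", "run_scea", "evaluate", "config_sweep"]


@dataclass
class PipelineConfig:
    """Everything one run needs; a master seed derives per-stage seeds."""

    K: int
    seed: int = 0
    # preprocessing
    min_cells: int = 3
    high_expression_quantile: float = 0.75
    fence_multiplier: float = 1.5
    normalize: bool = True
    # graph
    knn_k: int | None = None
    k_ne: int | None = None
    ne_alpha: float = 0.9
    ne_order: int = 2
    negative_policy: str = "clip"
    symmetrize: str = "union"
    # encoder
    encoder_dims: tuple = (4096, 2048, 1024)
    encoder_epochs: int = 30
    encoder_lr: float = 2e-4
    standardize: bool = True
    # graph attention autoencoder
    gat_hidden: int = 256
    gat_latent: int = 64
    n_heads: int = 8
    gat_epochs: int = 120
    gat_lr: float = 1e-3
    # clustering refinement
    lambda_kld: float = 1.0
    update_interval: int = 20
    tol: float = 0.001
    refine_epochs: int = 150
    kmeans_restarts: int = 10
    terminal_kmeans: bool = False  # labels from a final k-means instead of argmax Q

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError("K (number of clusters) must be >= 2")

    def stage_seeds(self) -> dict:
        ss = np.random.SeedSequence(self.seed)
        enc, gat, km = (int(s) % (2 ** 31) for s in ss.generate_state(3))
        return {"encoder": enc, "gat": gat, "kmeans": km}


def run_scea(
    X: ExpressionMatrix,
    cfg: PipelineConfig,
    truth_labels=None,
    out_dir: str | Path | None = None,
) -> tuple[np.ndarray, dict]:
    """Run the full pipeline on a counts matrix; return labels and manifest."""
    cfg.validate()
    seeds = cfg.stage_seeds()
    manifest: dict = {"config": _config_dict(cfg), "stage_seeds": seeds, "stages": {}}
    t_all = time.perf_counter()

    def stage(name):
        manifest["stages"][name] = {"t_start": time.perf_counter() - t_all}
        return time.perf_counter()

    def done(name, t0, output=None, **info):
        import gc
        gc.collect()  # large training tapes can linger across stages
        if output is not None:
            info["output_hash"] = _digest(output)
        manifest["stages"][name].update(
            seconds=round(time.perf_counter() - t0, 3), **info)

    try:
        t0 = stage("preprocessing")
        Xp, report = preprocess(
            X, cfg.min_cells, cfg.high_expression_quantile,
            cfg.fence_multiplier, cfg.normalize)
        manifest["filter_report"] = report.to_dict()
        done("preprocessing", t0, output=Xp.values, shape=list(Xp.values.shape))

        t0 = stage("cell_graph")
        G = build_cell_graph(
            Xp, k=cfg.knn_k, n_clusters=cfg.K, k_ne=cfg.k_ne,
            alpha=cfg.ne_alpha, order=cfg.ne_order,
            negative_policy=cfg.negative_policy, symmetrize=cfg.symmetrize)
        done("cell_graph", t0, output=G.adjacency, k=G.k,
             n_edges=int((G.adjacency > 0).sum() // 2))

        t0 = stage("mlp_encoder")
        enc_cfg = EncoderConfig(
            layer_dims=tuple(cfg.encoder_dims), epochs=cfg.encoder_epochs,
            learning_rate=cfg.encoder_lr, seed=seeds["encoder"],
            standardize_output=cfg.standardize)
        enc_state = pretrain_encoder(Xp, enc_cfg)
        E = encode(enc_state, Xp)
        if cfg.standardize:
            E = standardize(E)
        done("mlp_encoder", t0, output=E.values, shape=list(E.values.shape),
             loss_trace=enc_state.loss_trace)

        t0 = stage("gat_autoencoder")
        gat_cfg = GATConfig(
            input_dim=E.d, hidden_dim=cfg.gat_hidden, latent_dim=cfg.gat_latent,
            n_heads=cfg.n_heads, epochs=cfg.gat_epochs,
            learning_rate=cfg.gat_lr, seed=seeds["gat"])
        gat_cfg.validate(cfg.K)
        gat_state, Z = train_gat_autoencoder(E, G, gat_cfg)
        done("gat_autoencoder", t0, output=Z.values, shape=list(Z.values.shape),
             loss_trace=gat_state.loss_trace)

        t0 = stage("clustering")
        Q0, km_labels = kmeans_init(Z, cfg.K, seed=seeds["kmeans"],
                                    n_restarts=cfg.kmeans_restarts)
        ref_cfg = RefineConfig(
            lambda_kld=cfg.lambda_kld, update_interval=cfg.update_interval,
            tol=cfg.tol, max_epochs=cfg.refine_epochs, learning_rate=cfg.gat_lr)
        labels, sa, trace = refine(gat_state, E, G, Q0, ref_cfg)
        if cfg.terminal_kmeans:
            # Re-embed with the refined network and cluster the latent directly
            from .autograd import Tensor
            from .gat import gat_forward
            _, z_t, _ = gat_forward(
                gat_state, Tensor(E.values.astype(gat_state.config.dtype)),
                G.support())
            from .containers import Embedding
            _, labels = kmeans_init(Embedding(z_t.data.astype(float), E.cell_ids),
                                    cfg.K, seed=seeds["kmeans"],
                                    n_restarts=cfg.kmeans_restarts)
        done("clustering", t0, output=np.asarray(labels),
             kmeans_labels=[int(v) for v in km_labels],
             refine_trace={k: v for k, v in trace.items() if k != "loss"} | {
                 "n_epochs": len(trace["loss"])})
    except Exception as exc:  # annotate with the failing stage
        last = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {last!r}: {exc}") from exc

    manifest["labels"] = [int(v) for v in labels]
    manifest["cell_ids"] = Xp.cell_ids
    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)

    if truth_labels is not None:
        truth = _align_truth(truth_labels, X.cell_ids, Xp.cell_ids)
        manifest["metrics"] = metrics_report(truth, labels)
        manifest["metrics_kmeans_init"] = metrics_report(truth, km_labels)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sio.write_labels(labels, out_dir / "labels.csv", Xp.cell_ids)
        if truth_labels is not None:
            # truth restricted to QC-surviving cells, directly comparable
            # to labels.csv by `evaluate`
            sio.write_labels(truth, out_dir / "truth_labels.csv", Xp.cell_ids)
        sio.write_json(manifest, out_dir / "manifest.json")
    return labels, manifest


def _digest(arr) -> str:
    return hashlib.md5(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _align_truth(truth_labels, original_ids, kept_ids):
    """Subset truth labels to the cells that survived QC."""
    truth = np.asarray(truth_labels if not isinstance(truth_labels, pd.Series)
                       else truth_labels.to_numpy())
    if len(truth) == len(kept_ids):
        return truth
    if len(truth) != len(original_ids):
        raise ValueError(
            f"{len(truth)} truth labels for {len(original_ids)} input cells")
    pos = {c: i for i, c in enumerate(original_ids)}
    return truth[[pos[c] for c in kept_ids]]


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["encoder_dims"] = list(cfg.encoder_dims)
    return d


def evaluate(pred_path: str | Path, truth_path: str | Path,
             normalization: str = "mean") -> dict:
    """Compare two label files (matched by cell_id when present, else order)."""
    pred = sio.read_labels(pred_path)
    truth = sio.read_labels(truth_path)
    if isinstance(pred.index[0], str) and isinstance(truth.index[0], str) \
            and not pred.index.equals(pd.RangeIndex(len(pred))):
        missing = set(pred.index) ^ set(truth.index)
        if missing:
            raise ValueError(f"cell-id mismatch between label files: {sorted(missing)[:10]}")
        truth = truth.loc[pred.index]
    elif len(pred) != len(truth):
        raise ValueError(f"label files have {len(pred)} vs {len(truth)} cells")
    return metrics_report(truth.to_numpy(), pred.to_numpy(), normalization)


def config_sweep(
    X: ExpressionMatrix,
    truth_labels,
    base: PipelineConfig,
    heads: tuple = (),
    standardize_modes: tuple = (),
) -> pd.DataFrame:
    """Run head-count and standardization variants as pure config changes.

    Preprocessing, the cell graph and (for the head sweep) the encoder stage
    are computed once and reused, since those stages do not depend on the
    swept parameter. Returns one (ARI, NMI) row per setting.
    """
    base.validate()
    seeds = base.stage_seeds()
    Xp, _ = preprocess(X, base.min_cells, base.high_expression_quantile,
                       base.fence_multiplier, base.normalize)
    G = build_cell_graph(Xp, k=base.knn_k, n_clusters=base.K, k_ne=base.k_ne,
                         alpha=base.ne_alpha, order=base.ne_order)
    truth = _align_truth(truth_labels, X.cell_ids, Xp.cell_ids)

    enc_cfg = EncoderConfig(layer_dims=tuple(base.encoder_dims),
                            epochs=base.encoder_epochs, learning_rate=base.encoder_lr,
                            seed=seeds["encoder"])
    enc_state = pretrain_encoder(Xp, enc_cfg)
    E_raw = encode(enc_state, Xp)

    def downstream(E, n_heads):
        gat_cfg = GATConfig(input_dim=E.d, hidden_dim=base.gat_hidden,
                            latent_dim=base.gat_latent, n_heads=n_heads,
                            epochs=base.gat_epochs, learning_rate=base.gat_lr,
                            seed=seeds["gat"])
        gat_state, Z = train_gat_autoencoder(E, G, gat_cfg)
        Q0, _ = kmeans_init(Z, base.K, seed=seeds["kmeans"],
                            n_restarts=base.kmeans_restarts)
        ref = RefineConfig(lambda_kld=base.lambda_kld,
                           update_interval=base.update_interval, tol=base.tol,
                           max_epochs=base.refine_epochs, learning_rate=base.gat_lr)
        labels, _, _ = refine(gat_state, E, G, Q0, ref)
        return metrics_report(truth, labels)

    rows = []
    E_std = standardize(E_raw)
    for h in heads:
        rep = downstream(E_std if base.standardize else E_raw, h)
        rows.append({"setting": f"heads={h}", "n_heads": h,
                     "standardize": base.standardize,
                     "ari": rep["ari"], "nmi": rep["nmi"]})
    for mode in standardize_modes:
        rep = downstream(E_std if mode else E_raw, base.n_heads)
        rows.append({"setting": f"standardize={'on' if mode else 'off'}",
                     "n_heads": base.n_heads, "standardize": bool(mode),
                     "ari": rep["ari"], "nmi": rep["nmi"]})
    return pd.DataFrame(rows)
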