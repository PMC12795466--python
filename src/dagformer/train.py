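"""Full-batch adversarial training, prediction and evaluation.

Each epoch runs one forward pass over both domain networks through the
private and shared encoders, the inner-product decoders, the
gradient-reversed domain discriminator and the response predictor,
computes the five loss terms, and takes a single Adam step on the
weighted total. The entropy weight ramps linearly over training; the
gradient-reversal strength follows the standard sigmoidal ramp
2/(1+exp(-gamma * progress)) - 1. Optionally a fraction of target cells
is held out of every loss (they are excluded from the training-time
forward entirely, so their gradients are exactly zero) and only seen at
prediction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, average_precision_score,
                             roc_auc_score)

from ._autodiff import Adam, Tensor
from . import losses as L
from .graphs import CellGraph, build_cell_graph
from .losses import LossReport, LossWeights
from .model import DAGFormer, inner_product_decode


@dataclass
class Network:
    """A domain network: features X, prebuilt cell graph, optional labels."""

    X: np.ndarray
    graph: CellGraph
    labels: np.ndarray | None = None


@dataclass
class TrainConfig:
    epochs: int = 300
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    weight_decay: float = 1e-4
    seed: int = 0
    grl_gamma: float = 10.0
    grl_scale: float = 2.0
    use_gda: bool = True
    holdout_fraction: float = 0.0
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in [0, 1)")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")


@dataclass
class TrainingState:
    history: list = field(default_factory=list)
    seed: int = 0
    holdout_indices: np.ndarray | None = None
    train_indices: np.ndarray | None = None


@dataclass
class PredictionResult:
    psi: np.ndarray
    labels: np.ndarray
    metrics: dict | None = None


# ---------------------------------------------------------------------------
# schedules and splits


def lambda_e_schedule(epoch: int, total_epochs: int,
                      lambda_e_max: float) -> float:
    """Linear ramp of the entropy weight from 0 to lambda_e_max."""
    if not 0 <= epoch <= total_epochs:
        raise ValueError("epoch out of range")
    return lambda_e_max * epoch / total_epochs


def grl_schedule(progress: float, gamma: float = 10.0) -> float:
    """2/(1+exp(-gamma*p)) - 1: monotone ramp from 0 toward 1."""
    if not 0 <= progress <= 1:
        raise ValueError("progress must be in [0, 1]")
    return 2.0 / (1.0 + math.exp(-gamma * progress)) - 1.0


def holdout_split(n_or_X, fraction: float, seed: int = 0):
    """Disjoint (train_idx, holdout_idx); holdout size = floor(fraction*n)."""
    n = n_or_X if isinstance(n_or_X, (int, np.integer)) else \
        np.asarray(getattr(n_or_X, "values", n_or_X)).shape[0]
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_hold = int(math.floor(fraction * n))
    if n_hold == 0 or n_hold == n:
        raise ValueError("fraction yields an empty partition")
    perm = np.random.default_rng(seed).permutation(n)
    holdout = np.sort(perm[:n_hold])
    train = np.sort(perm[n_hold:])
    return train, holdout


# ---------------------------------------------------------------------------
# loss assembly (exposed so the hold-out gradient contract is probe-able)


def compute_losses(model: DAGFormer, source: Network, Xt_full: Tensor,
                   train_idx: np.ndarray, graph_target: CellGraph,
                   cfg: TrainConfig, lambda_e: float, lambda_grl: float):
    """One full-batch forward over both domains; returns (total, parts)."""
    Xs = Tensor(source.X) if not isinstance(source.X, Tensor) else source.X
    Xt = Xt_full.take_rows(train_idx)
    Gs, Gt = source.graph, graph_target

    h_pr_s = model.encode(Xs, Gs, "source_private", training=True)
    h_pr_t = model.encode(Xt, Gt, "target_private", training=True)
    h_sh_s = model.encode(Xs, Gs, "shared", training=True)
    h_sh_t = model.encode(Xt, Gt, "shared", training=True)

    psi_s = model.predict_response(h_sh_s)
    psi_t = model.predict_response(h_sh_t)
    cls = L.classification_loss(psi_s, source.labels)
    ent = L.entropy_loss(psi_t)
    diff = L.difference_loss(h_sh_s, h_pr_s, h_sh_t, h_pr_t)
    rec = (L.reconstruction_loss(inner_product_decode(h_pr_s, h_sh_s), Gs)
           + L.reconstruction_loss(inner_product_decode(h_pr_t, h_sh_t), Gt))

    dom = None
    if cfg.use_gda:
        d_s = model.discriminate_domain(h_sh_s, lambda_grl=lambda_grl)
        d_t = model.discriminate_domain(h_sh_t, lambda_grl=lambda_grl)
        dom = L.domain_loss(d_s, d_t)

    total = L.total_loss(cls, dom, ent, diff, rec, cfg.weights, lambda_e)
    parts = {"cls": cls, "dom": dom, "ent": ent, "diff": diff, "rec": rec}
    return total, parts


# ---------------------------------------------------------------------------
# training


def train(source: Network, target: Network, model: DAGFormer,
          cfg: TrainConfig | None = None):
    """Adversarial full-batch training; returns (model, TrainingState)."""
    cfg = cfg or TrainConfig()
    n_t = target.X.shape[0]

    if cfg.holdout_fraction > 0:
        train_idx, holdout_idx = holdout_split(n_t, cfg.holdout_fraction,
                                               cfg.seed)
        graph_t = build_cell_graph(target.X[train_idx], target.graph.method,
                                   target.graph.params)
    else:
        train_idx = np.arange(n_t)
        holdout_idx = np.array([], dtype=np.intp)
        graph_t = target.graph

    params = model.parameters(include_discriminator=cfg.use_gda)
    opt = Adam(params, lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    state = TrainingState(seed=cfg.seed, holdout_indices=holdout_idx,
                          train_indices=train_idx)
    Xt_full = Tensor(target.X)

    for epoch in range(1, cfg.epochs + 1):
        lam_e = lambda_e_schedule(epoch, cfg.epochs, cfg.weights.lambda_e_max)
        lam_grl = cfg.grl_scale * grl_schedule(epoch / cfg.epochs,
                                               cfg.grl_gamma)
        total, parts = compute_losses(model, source, Xt_full, train_idx,
                                      graph_t, cfg, lam_e, lam_grl)
        for name in ("cls", "dom", "ent", "diff", "rec"):
            t = parts[name]
            if t is not None and not np.isfinite(t.data).all():
                raise FloatingPointError(
                    f"non-finite loss term '{name}' at epoch {epoch}")
        if not np.isfinite(total.data).all():
            raise FloatingPointError(f"non-finite total loss at epoch {epoch}")

        opt.zero_grad()
        total.backward()
        opt.step()

        state.history.append(LossReport(
            epoch=epoch,
            cls=parts["cls"].item(),
            dom=parts["dom"].item() if parts["dom"] is not None else 0.0,
            ent=parts["ent"].item(),
            diff=parts["diff"].item(),
            rec=parts["rec"].item(),
            total=total.item(),
        ))
    return model, state


def predict(model: DAGFormer, target: Network,
            truth: np.ndarray | None = None) -> PredictionResult:
    """Eval-mode forward through the shared encoder and predictor."""
    if target.X.shape[1] != model.n_genes:
        raise ValueError("target gene count does not match the trained model")
    h_sh = model.encode(Tensor(target.X), target.graph, "shared",
                        training=False)
    psi = model.predict_response(h_sh).data
    labels = (psi >= 0.5).astype(int)
    metrics = compute_metrics(psi, truth) if truth is not None else None
    return PredictionResult(psi=psi, labels=labels, metrics=metrics)


def compute_metrics(psi, y_true) -> dict:
    """ACC at threshold 0.5, AUC (tie rule 1/2), AUPR (average precision)."""
    psi = np.asarray(psi, dtype=float)
    y = np.asarray(getattr(y_true, "labels", y_true), dtype=int)
    out = {"ACC": float(accuracy_score(y, (psi >= 0.5).astype(int)))}
    if len(np.unique(y)) < 2:
        out["AUC"] = None
        out["AUPR"] = None
    else:
        out["AUC"] = float(roc_auc_score(y, psi))
        out["AUPR"] = float(average_precision_score(y, psi))
    return out


def discriminator_accuracy(model: DAGFormer, source: Network,
                           target: Network) -> float:
    """Eval-mode domain-classification accuracy on shared features."""
    h_s = model.encode(Tensor(source.X), source.graph, "shared",
                       training=False)
    h_t = model.encode(Tensor(target.X), target.graph, "shared",
                       training=False)
    d_s = model.discriminate_domain(h_s).data
    d_t = model.discriminate_domain(h_t).data
    pred = np.concatenate([(d_s >= 0.5), (d_t >= 0.5)]).astype(int)
    true = np.concatenate([np.ones(len(d_s)), np.zeros(len(d_t))]).astype(int)
    return float((pred == true).mean())


def export_embeddings(model: DAGFormer, network: Network, path,
                      which: str = "shared",
                      sample_ids=None) -> pd.DataFrame:
    """Write eval-mode encoder embeddings as TSV (for external UMAP etc.)."""
    H = model.encode(Tensor(network.X), network.graph, which,
                     training=False).data
    idx = sample_ids if sample_ids is not None else range(H.shape[0])
    df = pd.DataFrame(H, index=idx,
                      columns=[f"dim{i}" for i in range(H.shape[1])])
    df.to_csv(path, sep="\t")
    return df


# ---------------------------------------------------------------------------
# ablation harness


def run_ablation(make_networks, seeds, cfg: TrainConfig | None = None,
                 model_config=None) -> pd.DataFrame:
    """Paired GDA-on / GDA-off runs per seed on identical data.

    ``make_networks(seed)`` must return (source, target, target_truth);
    both variants of a seed share that data, differing only in use_gda.
    """
    from dataclasses import replace
    from .model import ModelConfig

    seeds = list(seeds)
    if len(seeds) < 3:
        raise ValueError("run_ablation needs at least 3 seeds")
    cfg = cfg or TrainConfig()
    rows = []
    for seed in seeds:
        source, target, truth = make_networks(seed)
        for use_gda in (True, False):
            mc = replace(model_config or ModelConfig(), seed=seed)
            run_cfg = replace(cfg, seed=seed, use_gda=use_gda)
            model = DAGFormer(source.X.shape[1], mc)
            model, _ = train(source, target, model, run_cfg)
            result = predict(model, target, truth=truth)
            rows.append({"seed": seed, "use_gda": use_gda,
                         **result.metrics})
    return pd.DataFrame(rows)


def ablation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median metrics per variant plus the GDA-minus-noGDA deltas."""
    med = table.groupby("use_gda")[["ACC", "AUC", "AUPR"]].median()
    delta = med.loc[True] - med.loc[False]
    out = med.copy()
    out.loc["delta"] = delta
    return out
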