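"""End-to-end orchestration: data -> preprocess -> graphs -> train -> predict.

A single YAML/JSON config drives the run; every stage logs into a run
manifest, per-epoch losses stream to JSON lines, and predictions land in
a TSV of (cell_id, psi, label).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .graphs import build_cell_graph
from .losses import LossWeights
from .model import DAGFormer, ModelConfig
from .preprocess import (BalanceParams, QCParams, ResponseLabels,
                         balance_classes, intersect_genes, load_expression,
                         normalize_target, qc_filter_cells,
                         standardize_source, zscore_genes)
from .synthetic import generate, preset_config, write_fixture
from .train import (Network, TrainConfig, compute_metrics, predict, train)

logger = logging.getLogger("dagformer")

_SCHEMA = {
    "seed": int,
    "out_dir": str,
    "data": {"preset": str, "source": str, "target": str,
             "source_labels": str, "target_truth": str, "format": str},
    "preprocess": {"qc": bool, "min_genes_per_cell": int,
                   "min_cells_per_gene": int, "max_mito_fraction": float,
                   "mito_prefix": str, "target_sum": float, "balance": bool,
                   "smote_ratio": float, "final_ratio": float,
                   "k_smote": int},
    "graph": {"method": str, "K": int, "top_percent": float},
    "model": {"d_h": int, "n_layers": int, "n_heads": int, "d_k": int,
              "dropout": float, "ffn_hidden": int,
              "discriminator_hidden": int, "literal_ffn": bool,
              "attention_scaled": bool},
    "train": {"epochs": int, "learning_rate": float, "weight_decay": float,
              "grl_gamma": float, "grl_scale": float, "use_gda": bool,
              "holdout_fraction": float, "lambda_d": float,
              "lambda_e_max": float, "lambda_f": float, "lambda_r": float},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        cfg = yaml.safe_load(Path(path_or_dict).read_text())
    else:
        cfg = dict(path_or_dict)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    for key, val in cfg.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key: {key!r}")
        if isinstance(_SCHEMA[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            for sub in val:
                if sub not in _SCHEMA[key]:
                    raise ValueError(f"unknown config key: {key}.{sub}")


def apply_overrides(cfg: dict, overrides) -> dict:
    """Flat overrides of the form section.key=value."""
    for item in overrides or []:
        path, _, raw = item.partition("=")
        if not _:
            raise ValueError(f"override {item!r} must be key=value")
        val = yaml.safe_load(raw)
        keys = path.split(".")
        node = cfg
        for k in keys[:-1]:
            node = node.setdefault(k, {})
        node[keys[-1]] = val
    validate_config(cfg)
    return cfg


def _load_inputs(data_cfg: dict, seed: int):
    if "preset" in data_cfg:
        ds = generate(preset_config(data_cfg["preset"], seed=seed))
        return ds.source, ds.source_labels, ds.target, ds.target_truth
    fmt = data_cfg.get("format", "csv")
    source = load_expression(data_cfg["source"], fmt, "source")
    target = load_expression(data_cfg["target"], fmt, "target")
    y = ResponseLabels(pd.read_csv(data_cfg["source_labels"], index_col=0)
                       .iloc[:, 0].to_numpy())
    truth = None
    if data_cfg.get("target_truth"):
        truth = ResponseLabels(pd.read_csv(data_cfg["target_truth"],
                                           index_col=0).iloc[:, 0].to_numpy())
    return source, y, target, truth


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the configured stages; returns artifact paths and metrics."""
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "dagformer_run"))
    out.mkdir(parents=True, exist_ok=True)

    manifest = {"package_version": __version__, "config": cfg, "seed": seed,
                "stages": {}, "outputs": {}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    log_handler = logging.FileHandler(out / "run.log")
    logger.addHandler(log_handler)

    def stage(name):
        logger.info("stage %s started", name)
        manifest["stages"][name] = {"started": time.time()}

    def done(name):
        rec = manifest["stages"][name]
        rec["seconds"] = round(time.time() - rec.pop("started"), 3)
        logger.info("stage %s finished in %.3fs", name, rec["seconds"])

    # -- data -----------------------------------------------------------
    stage("data")
    source, y, target, truth = _load_inputs(cfg.get("data",
                                                    {"preset": "separable"}),
                                            seed)
    done("data")

    # -- preprocess -------------------------------------------------------
    stage("preprocess")
    pp = cfg.get("preprocess", {})
    if pp.get("qc", False):
        qcp = QCParams(
            min_genes_per_cell=pp.get("min_genes_per_cell", 200),
            min_cells_per_gene=pp.get("min_cells_per_gene", 3),
            max_mito_fraction=pp.get("max_mito_fraction", 0.2),
            mito_prefix=pp.get("mito_prefix", "MT-"))
        target, qc_report = qc_filter_cells(target, qcp)
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
        target = normalize_target(target, pp.get("target_sum", 1e4))
    else:
        target = zscore_genes(target)
    source = standardize_source(source)
    source, target = intersect_genes(source, target)
    if pp.get("balance", True):
        bp = BalanceParams(smote_ratio=pp.get("smote_ratio", 0.5),
                           final_ratio=pp.get("final_ratio", 1.0),
                           k_smote=pp.get("k_smote", 5), seed=seed)
        source, y = balance_classes(source, y, bp)
    done("preprocess")

    # -- graphs ----------------------------------------------------------
    stage("graphs")
    g = cfg.get("graph", {})
    method = g.get("method", "knn")
    gparams = {"K": g.get("K", 15), "top_percent": g.get("top_percent", 20.0)}
    graph_s = build_cell_graph(source, method, gparams)
    graph_t = build_cell_graph(target, method, gparams)
    done("graphs")

    # -- train -----------------------------------------------------------
    stage("train")
    m = cfg.get("model", {})
    model_cfg = ModelConfig(seed=seed, **m)
    t = dict(cfg.get("train", {}))
    weights = LossWeights(
        lambda_d=t.pop("lambda_d", 0.5),
        lambda_e_max=t.pop("lambda_e_max", 0.01),
        lambda_f=t.pop("lambda_f", 1e-4),
        lambda_r=t.pop("lambda_r", 0.3))
    train_cfg = TrainConfig(seed=seed, weights=weights, **t)
    src_net = Network(source.values, graph_s, y.labels)
    tgt_net = Network(target.values, graph_t)
    model = DAGFormer(source.n_genes, model_cfg)
    model, state = train(src_net, tgt_net, model, train_cfg)
    with open(out / "losses.jsonl", "w") as fh:
        for rep in state.history:
            fh.write(json.dumps(rep.to_dict()) + "\n")
    model.save(out / "model")
    done("train")

    # -- predict / evaluate ------------------------------------------------
    stage("predict")
    result = predict(model, tgt_net)
    pred_df = pd.DataFrame({"cell_id": target.sample_ids,
                            "psi": result.psi, "label": result.labels})
    pred_df.to_csv(out / "predictions.tsv", sep="\t", index=False,
                   float_format="%.10g")
    done("predict")

    metrics = None
    if truth is not None:
        stage("evaluate")
        metrics = compute_metrics(result.psi, truth)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        done("evaluate")

    manifest["outputs"] = {
        "predictions": str(out / "predictions.tsv"),
        "losses": str(out / "losses.jsonl"),
        "model": str(out / "model.npz"),
        "metrics": str(out / "metrics.json") if metrics else None,
    }
    manifest["model_config"] = asdict(model_cfg)
    manifest["final_loss"] = state.history[-1].to_dict()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.removeHandler(log_handler)
    log_handler.close()
    return {"out_dir": str(out), "metrics": metrics,
            "manifest": manifest, "predictions": pred_df}
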