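"""Loading, quality control, normalization and class balancing.

Source (bulk RNA-seq cell lines) and target (scRNA-seq cells) expression
matrices are brought onto a shared, z-scored gene space:

* target cells pass count-based QC (minimum detected genes, minimum cells
  per gene, mitochondrial-fraction cap), total-count normalization,
  log1p, and per-gene z-scoring;
* source samples are z-scored per gene;
* both domains are restricted to the intersection of their gene sets;
* the imbalanced source labels (sensitive cell lines are typically rare)
  are rebalanced by SMOTE oversampling of the minority class followed by
  random undersampling of the majority class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread
from sklearn.neighbors import NearestNeighbors

STAGES = ("raw", "qc", "normalized", "standardized")


@dataclass
class ExpressionMatrix:
    """A samples x genes expression matrix with ids and a domain tag."""

    values: np.ndarray
    sample_ids: list
    gene_ids: list
    domain: str  # "source" | "target"
    stage: str = "raw"
    zero_variance_genes: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match matrix rows")
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError("gene_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if self.domain not in ("source", "target"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage in ("normalized", "standardized") and not np.isfinite(
            self.values
        ).all():
            raise ValueError(f"non-finite values at stage {self.stage}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.gene_ids)


@dataclass
class ResponseLabels:
    """Binary drug-response labels: 1 = sensitive, 0 = resistant."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0=resistant, 1=sensitive)")

    def __len__(self):
        return len(self.labels)


@dataclass
class QCParams:
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_mito_fraction: float = 0.2
    mito_prefix: str = "MT-"

    def __post_init__(self):
        if self.min_cells_per_gene < 1:
            raise ValueError("min_cells_per_gene must be >= 1")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")


@dataclass
class BalanceParams:
    smote_ratio: float = 0.5   # minority/majority after SMOTE
    final_ratio: float = 1.0   # minority/majority after undersampling
    k_smote: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.smote_ratio <= 1:
            raise ValueError("smote_ratio must be in (0, 1]")
        if not 0 < self.final_ratio <= 1:
            raise ValueError("final_ratio must be in (0, 1]")
        if self.k_smote < 1:
            raise ValueError("k_smote must be >= 1")


# ---------------------------------------------------------------------------
# loading


def load_expression(path, format: str = "csv", domain: str = "target"
                    ) -> ExpressionMatrix:
    """Load a samples x genes matrix.

    Dense csv/tsv: rows are samples, header row holds gene ids, first
    column holds sample ids. MatrixMarket triplets follow the common
    gene-major convention (rows are genes) with companion one-id-per-line
    files ``<stem>_rows.txt`` (genes) and ``<stem>_cols.txt`` (cells), and
    are transposed on load so rows are cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValueError("duplicate gene ids")
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(df.to_numpy(dtype=np.float64),
                                list(df.index), list(df.columns), domain)
    if format == "mtx_triplet":
        stem = path.with_suffix("")
        rows_file = Path(f"{stem}_rows.txt")
        cols_file = Path(f"{stem}_cols.txt")
        for f in (rows_file, cols_file):
            if not f.exists():
                raise FileNotFoundError(f"companion id file missing: {f}")
        genes = rows_file.read_text().split()
        cells = cols_file.read_text().split()
        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw,
                         dtype=np.float64)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError("matrix shape does not match id files")
        return ExpressionMatrix(mat.T, cells, genes, domain)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# QC and normalization


def qc_filter_cells(X: ExpressionMatrix, p: QCParams | None = None):
    """Count-based QC for target cells; returns (filtered, report).

    Cell filters run first (minimum detected genes, then mitochondrial
    fraction), gene filters second (minimum cells expressing the gene).
    """
    p = p or QCParams()
    if X.domain != "target":
        raise ValueError("qc_filter_cells applies to the target domain")
    V = X.values
    if (V < 0).any():
        raise ValueError("negative counts in QC input")

    detected = (V > 0).sum(axis=1)
    low_gene = detected < p.min_genes_per_cell

    prefix = p.mito_prefix.upper()
    mito_cols = np.array([g.upper().startswith(prefix) for g in X.gene_ids])
    totals = V.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, V[:, mito_cols].sum(axis=1) /
                             np.where(totals > 0, totals, 1.0), 1.0)
    high_mito = mito_frac > p.max_mito_fraction

    keep_cells = ~(low_gene | high_mito)
    if not keep_cells.any():
        raise ValueError("QC removed all cells")

    V2 = V[keep_cells]
    cells_expressing = (V2 > 0).sum(axis=0)
    keep_genes = cells_expressing >= p.min_cells_per_gene

    report = {
        "cells_removed_low_genes": [s for s, bad in zip(X.sample_ids, low_gene)
                                    if bad],
        "cells_removed_high_mito": [
            s for s, bad, lg in zip(X.sample_ids, high_mito, low_gene)
            if bad and not lg
        ],
        "genes_removed_low_cells": [g for g, ok in
                                    zip(X.gene_ids, keep_genes) if not ok],
        "n_cells_kept": int(keep_cells.sum()),
        "n_genes_kept": int(keep_genes.sum()),
    }
    out = ExpressionMatrix(
        V2[:, keep_genes],
        [s for s, ok in zip(X.sample_ids, keep_cells) if ok],
        [g for g, ok in zip(X.gene_ids, keep_genes) if ok],
        X.domain, stage="qc",
    )
    return out, report


def _zscore_columns(V: np.ndarray):
    """Population (n-denominator) per-column z-score; constant columns -> 0."""
    mu = V.mean(axis=0)
    sd = V.std(axis=0)  # ddof=0
    zero_var = sd < 1e-12
    sd_safe = np.where(zero_var, 1.0, sd)
    Z = (V - mu) / sd_safe
    Z[:, zero_var] = 0.0
    return Z, zero_var


def normalize_target(X: ExpressionMatrix, target_sum: float = 1e4
                     ) -> ExpressionMatrix:
    """Per-cell total-count scaling, log1p, then per-gene z-score."""
    V = X.values
    if (V < 0).any():
        raise ValueError("negative counts")
    totals = V.sum(axis=1)
    if (totals == 0).any():
        bad = [s for s, t in zip(X.sample_ids, totals) if t == 0]
        raise ValueError(f"cells with zero total count: {bad[:5]}")
    scaled = V * (target_sum / totals)[:, None]
    logged = np.log1p(scaled)
    Z, zero_var = _zscore_columns(logged)
    return ExpressionMatrix(
        Z, X.sample_ids, X.gene_ids, X.domain, stage="standardized",
        zero_variance_genes=[g for g, zv in zip(X.gene_ids, zero_var) if zv],
    )


def zscore_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score (population sd) for either domain."""
    if not np.isfinite(X.values).all():
        raise ValueError("non-finite values in expression matrix")
    Z, zero_var = _zscore_columns(X.values)
    return ExpressionMatrix(
        Z, X.sample_ids, X.gene_ids, X.domain, stage="standardized",
        zero_variance_genes=[g for g, zv in zip(X.gene_ids, zero_var) if zv],
    )


def standardize_source(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score of the source matrix (population sd)."""
    if X.domain != "source":
        raise ValueError("standardize_source applies to the source domain")
    return zscore_genes(X)


def intersect_genes(Xs: ExpressionMatrix, Xt: ExpressionMatrix):
    """Restrict both matrices to their shared genes, sorted lexicographically."""
    shared = sorted(set(Xs.gene_ids) & set(Xt.gene_ids))
    if not shared:
        raise ValueError("empty gene intersection")

    def _restrict(X: ExpressionMatrix) -> ExpressionMatrix:
        pos = {g: i for i, g in enumerate(X.gene_ids)}
        cols = [pos[g] for g in shared]
        return ExpressionMatrix(
            X.values[:, cols], X.sample_ids, shared, X.domain, stage=X.stage,
            zero_variance_genes=[g for g in X.zero_variance_genes
                                 if g in set(shared)],
        )

    return _restrict(Xs), _restrict(Xt)


# ---------------------------------------------------------------------------
# class balancing


def balance_classes(X: ExpressionMatrix, y: ResponseLabels,
                    p: BalanceParams | None = None):
    """SMOTE oversampling of the minority class, then random undersampling.

    With the defaults the minority class is raised to round(0.5 x majority)
    by interpolating between a minority sample and one of its k nearest
    minority neighbors, and the majority class is then undersampled to a
    1:1 ratio.
    """
    p = p or BalanceParams()
    labels = y.labels
    if len(labels) != X.n_samples:
        raise ValueError("labels length does not match matrix rows")
    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present before balancing")
    minority = int(np.argmin(counts))
    majority = 1 - minority
    n_min, n_maj = counts[minority], counts[majority]

    rng = np.random.default_rng(p.seed)
    V, ids = X.values, list(X.sample_ids)

    # SMOTE
    target_min = int(round(p.smote_ratio * n_maj))
    n_new = max(0, target_min - n_min)
    if n_new > 0:
        if n_min < p.k_smote + 1:
            raise ValueError(
                f"minority class too small ({n_min}) for k_smote={p.k_smote}")
        min_idx = np.flatnonzero(labels == minority)
        Vmin = V[min_idx]
        nn = NearestNeighbors(n_neighbors=p.k_smote + 1).fit(Vmin)
        neigh = nn.kneighbors(Vmin, return_distance=False)[:, 1:]
        base = rng.integers(0, len(min_idx), size=n_new)
        pick = rng.integers(0, p.k_smote, size=n_new)
        gap = rng.random(n_new)
        partner = neigh[base, pick]
        synth = Vmin[base] + gap[:, None] * (Vmin[partner] - Vmin[base])
        V = np.vstack([V, synth])
        labels = np.concatenate([labels, np.full(n_new, minority)])
        ids = ids + [f"SMOTE_{i}" for i in range(n_new)]
    n_min_new = int((labels == minority).sum())

    # random undersampling of the majority
    target_maj = int(round(n_min_new / p.final_ratio))
    maj_idx = np.flatnonzero(labels == majority)
    keep = np.ones(len(labels), dtype=bool)
    if len(maj_idx) > target_maj:
        drop = rng.choice(maj_idx, size=len(maj_idx) - target_maj,
                          replace=False)
        keep[drop] = False

    out = ExpressionMatrix(V[keep], [s for s, k in zip(ids, keep) if k],
                           X.gene_ids, X.domain, stage=X.stage,
                           zero_variance_genes=list(X.zero_variance_genes))
    return out, ResponseLabels(labels[keep])


# ---------------------------------------------------------------------------
# serialization


def write_matrix(X: ExpressionMatrix, path) -> None:
    X.to_frame().to_csv(path, sep="\t")


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
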