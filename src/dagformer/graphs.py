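"""Cellular neighbor graph construction.

Nodes are samples (cell lines in the source domain, single cells in the
target domain); edges connect transcriptionally similar pairs. Three
strategies are supported:

* ``srcc`` — Spearman rank correlation, thresholded at the top 20% of
  off-diagonal pairs;
* ``pcc``  — Pearson correlation, thresholded the same way;
* ``knn``  — cosine-similarity K nearest neighbors (default, K=15).

The resulting binary adjacency is symmetrized by union, given self-loops,
and degree-normalized as D^{-1/2} A D^{-1/2}. The graph is built once,
before training, and reused every epoch (full-batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import ExpressionMatrix


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    method: str  # "srcc" | "pcc"
    constant_rows: np.ndarray = field(default_factory=lambda: np.array([], int))


@dataclass
class CellGraph:
    """Symmetric normalized cell-cell adjacency with its binary scaffold."""

    adjacency: np.ndarray       # D^{-1/2} A D^{-1/2}, A = binary + self-loops
    binary: np.ndarray          # symmetrized binary adjacency incl. self-loops
    neighbor_lists: list        # sorted neighbor indices per node (incl. self)
    method: str                 # "srcc" | "pcc" | "knn"
    params: dict
    normalized: bool = True

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class KNNParams:
    K: int = 15
    metric: str = "cosine"
    include_self: bool = False


def _values_of(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)


def _corr_of_rows(V: np.ndarray, method: str) -> CorrelationMatrix:
    sd = V.std(axis=1)
    constant = np.flatnonzero(sd < 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(V)
    C = np.asarray(C, dtype=np.float64)
    C = (C + C.T) / 2.0
    C = np.clip(C, -1.0, 1.0)
    ok = np.ones(V.shape[0], dtype=bool)
    ok[constant] = False
    C[~ok, :] = 0.0
    C[:, ~ok] = 0.0
    d = np.where(ok, 1.0, 0.0)
    np.fill_diagonal(C, d)
    return CorrelationMatrix(C, method, constant)


def spearman_matrix(X) -> CorrelationMatrix:
    """Pairwise Spearman correlation between sample rows (average ranks)."""
    V = _values_of(X)
    if V.shape[0] < 2 or V.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 genes")
    ranks = rankdata(V, axis=1)  # ties -> average rank
    return _corr_of_rows(ranks, "srcc")


def pearson_matrix(X) -> CorrelationMatrix:
    """Pairwise Pearson correlation between sample rows."""
    V = _values_of(X)
    if V.shape[0] < 2 or V.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 genes")
    return _corr_of_rows(V, "pcc")


def threshold_top_percent(C, percent: float = 20.0) -> np.ndarray:
    """Keep edges whose correlation strictly exceeds the top-`percent` cut.

    The threshold is the (100 - percent)th percentile of the off-diagonal
    upper-triangle values; self-pairs are excluded both from the threshold
    and from the edge set.
    """
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    V = C.values if isinstance(C, CorrelationMatrix) else np.asarray(C, float)
    n = V.shape[0]
    iu = np.triu_indices(n, k=1)
    theta = np.percentile(V[iu], 100.0 - percent)
    A = (V > theta).astype(np.float64)
    np.fill_diagonal(A, 0.0)
    return A


def knn_graph(X, p: KNNParams | None = None) -> np.ndarray:
    """Directed cosine-KNN adjacency; ties broken toward the smaller index."""
    p = p or KNNParams()
    V = _values_of(X)
    n = V.shape[0]
    if not 1 <= p.K < n:
        raise ValueError(f"K={p.K} must satisfy 1 <= K < n={n}")
    norms = np.linalg.norm(V, axis=1)
    if (norms == 0).any():
        ids = (X.sample_ids if isinstance(X, ExpressionMatrix)
               else [str(i) for i in range(n)])
        bad = [ids[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-norm expression vector for sample(s) {bad[:5]}")
    U = V / norms[:, None]
    S = U @ U.T
    np.fill_diagonal(S, -np.inf)  # self excluded
    # stable argsort on -S keeps the smaller index first among ties
    order = np.argsort(-S, axis=1, kind="stable")
    A = np.zeros((n, n))
    rows = np.repeat(np.arange(n), p.K)
    A[rows, order[:, :p.K].ravel()] = 1.0
    return A


def symmetrize_normalize(A: np.ndarray, method: str = "knn",
                         params: dict | None = None) -> CellGraph:
    """Union-symmetrize, add self-loops, and degree-normalize."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if (A < 0).any():
        raise ValueError("adjacency must be non-negative")
    A_sym = np.maximum(A, A.T)
    A_sym = (A_sym > 0).astype(np.float64)
    np.fill_diagonal(A_sym, 1.0)
    deg = A_sym.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    G_hat = A_sym * np.outer(d_inv_sqrt, d_inv_sqrt)
    neighbors = [np.flatnonzero(row).tolist() for row in A_sym]
    return CellGraph(G_hat, A_sym, neighbors, method, params or {})


def build_cell_graph(X, method: str = "knn", params: dict | None = None
                     ) -> CellGraph:
    """Dispatch to a construction strategy, then symmetrize and normalize."""
    params = dict(params or {})
    if isinstance(X, ExpressionMatrix) and X.stage != "standardized":
        raise ValueError("graphs are built on standardized matrices")
    if method == "knn":
        K = int(params.get("K", params.get("k", 15)))
        A = knn_graph(X, KNNParams(K=K))
        used = {"K": K, "metric": "cosine"}
    elif method in ("srcc", "pcc"):
        percent = float(params.get("top_percent", 20.0))
        C = spearman_matrix(X) if method == "srcc" else pearson_matrix(X)
        A = threshold_top_percent(C, percent)
        used = {"top_percent": percent}
    else:
        raise ValueError(f"unknown graph method {method!r}")
    return symmetrize_normalize(A, method, used)


def write_graph(graph: CellGraph, edges_path, header_path=None) -> None:
    """Serialize as a TSV edge list (node_i, node_j, weight)."""
    ii, jj = np.nonzero(graph.binary)
    df = pd.DataFrame({"node_i": ii, "node_j": jj,
                       "weight": graph.adjacency[ii, jj]})
    df.to_csv(edges_path, sep="\t", index=False)
    if header_path is not None:
        import json
        from pathlib import Path
        Path(header_path).write_text(json.dumps(
            {"method": graph.method, "params": graph.params,
             "n": graph.n_nodes}, indent=2))
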