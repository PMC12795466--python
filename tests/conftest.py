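import numpy as np
import pytest

from dagformer import (ExpressionMatrix, Network, build_cell_graph,
                       balance_classes, generate, intersect_genes,
                       preset_config, standardize_source, zscore_genes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_target(rng):
    """A tiny standardized target matrix (20 cells x 12 genes)."""
    X = rng.normal(size=(20, 12))
    return ExpressionMatrix(X, [f"c{i}" for i in range(20)],
                            [f"g{i}" for i in range(12)], "target",
                            stage="standardized")


def make_networks(preset: str, seed: int):
    """Standard data path: simulate, standardize, intersect, balance, graphs."""
    ds = generate(preset_config(preset, seed=seed))
    Xs = standardize_source(ds.source)
    Xt = zscore_genes(ds.target)
    Xs, Xt = intersect_genes(Xs, Xt)
    Xs, y = balance_classes(Xs, ds.source_labels)
    gs = build_cell_graph(Xs, "knn", {"K": 15})
    gt = build_cell_graph(Xt, "knn", {"K": 15})
    return (Network(Xs.values, gs, y.labels), Network(Xt.values, gt),
            ds.target_truth.labels)


@pytest.fixture(scope="session")
def separable_networks():
    """Seed-0 separable fixture shared by the slower end-to-end tests."""
    return make_networks("separable", 0)
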