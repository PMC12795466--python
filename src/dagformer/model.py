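"""Graph-transformer encoders, decoders, and adversarial heads.

The architecture has three parameter-disjoint encoders — one private
encoder per domain plus one shared encoder applied to both — built from
stacked graph-transformer layers whose multi-head attention is sparsified
by the cellular neighbor graph: the attention logit between nodes i and j
is the query-key dot product weighted by the normalized adjacency entry,
and the softmax runs over the neighbor set of i only. Inner-product
decoders reconstruct each domain's graph from the concatenated
private+shared embedding; a gradient-reversal layer feeds the shared
embeddings to a two-layer domain discriminator; a single linear layer
predicts drug sensitivity from the shared embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, as_tensor, concat
from .graphs import CellGraph

EPS = 1e-7  # probability clipping before any log


@dataclass
class ModelConfig:
    d_h: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_k: int = 16
    dropout: float = 0.1
    ffn_hidden: int = 128
    discriminator_hidden: int = 16
    literal_ffn: bool = True       # FFN output without a second residual
    attention_scaled: bool = False  # optional 1/sqrt(d_k) logit scaling
    seed: int = 0

    def __post_init__(self):
        if self.d_h != self.n_heads * self.d_k:
            raise ValueError("d_h must equal n_heads * d_k")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


def _glorot(shape, rng) -> Tensor:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


# ---------------------------------------------------------------------------
# building blocks


class BatchNorm:
    """Per-feature batch normalization across nodes (full-batch training)."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            if x.shape[0] < 2:
                raise ValueError(
                    "batch of size 1 under batch norm in training mode; "
                    "run in eval mode to use running statistics")
            mu = x.mean(axis=0)
            xc = x - mu
            var = (xc * xc).mean(axis=0)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xhat = xc / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - self.running_mean) / np.sqrt(
                self.running_var + self.eps)
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


def input_projection(X, W_proj) -> Tensor:
    """H0 = ReLU(X W_proj); bias-free linear lift into the hidden space."""
    return (as_tensor(X) @ as_tensor(W_proj)).relu()


def sparse_attention(H, graph: CellGraph, W_Q, W_K, W_V,
                     scaled: bool = False) -> Tensor:
    """Multi-head attention restricted to graph neighborhoods.

    Logits are the query-key dot products weighted by the normalized
    adjacency entry; the softmax is taken over each node's neighbor set
    only (self-loops guarantee it is non-empty); head outputs are
    concatenated.
    """
    H = as_tensor(H)
    W_Q, W_K, W_V = as_tensor(W_Q), as_tensor(W_K), as_tensor(W_V)
    n = H.shape[0]
    n_heads, _, d_k = W_Q.shape
    if graph.n_nodes != n:
        raise ValueError("graph node count does not match feature rows")

    Q = H @ W_Q                      # (heads, n, d_k)
    K = H @ W_K
    V = H @ W_V
    scores = Q @ K.swapaxes(-1, -2)  # (heads, n, n)
    if scaled:
        scores = scores * (1.0 / np.sqrt(d_k))
    logits = scores * graph.adjacency  # multiplicative G-hat weighting

    mask = graph.binary > 0
    neg = np.where(mask, 0.0, -np.inf)          # exclude non-neighbors
    shifted = logits + neg
    m = np.max(shifted.data, axis=-1, keepdims=True)  # row-max (constant shift)
    e = (shifted - m).exp()
    attn = e / e.sum(axis=-1, keepdims=True)
    out = attn @ V                              # (heads, n, d_k)
    return out.transpose(1, 0, 2).reshape(n, n_heads * d_k)


class GraphTransformerLayer:
    def __init__(self, cfg: ModelConfig, rng):
        H, dh, dk = cfg.n_heads, cfg.d_h, cfg.d_k
        self.cfg = cfg
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.W_Q = _glorot((H, dh, dk), rng)
        self.W_K = _glorot((H, dh, dk), rng)
        self.W_V = _glorot((H, dh, dk), rng)
        self.bn1 = BatchNorm(dh)
        self.W1 = _glorot((dh, cfg.ffn_hidden), rng)
        self.b1 = Tensor(np.zeros(cfg.ffn_hidden), requires_grad=True)
        self.W2 = _glorot((cfg.ffn_hidden, dh), rng)
        self.b2 = Tensor(np.zeros(dh), requires_grad=True)
        self.bn2 = None if cfg.literal_ffn else BatchNorm(dh)

    def _dropout(self, x: Tensor, training: bool) -> Tensor:
        p = self.cfg.dropout
        if not training or p <= 0:
            return x
        keep = (self._dropout_rng.random(x.shape) >= p) / (1.0 - p)
        return x * keep

    def __call__(self, H_in: Tensor, graph: CellGraph,
                 training: bool = False) -> Tensor:
        attn = sparse_attention(H_in, graph, self.W_Q, self.W_K, self.W_V,
                                scaled=self.cfg.attention_scaled)
        attn = self._dropout(attn, training)
        H_hat = self.bn1(attn + H_in, training)
        hidden = self._dropout((H_hat @ self.W1 + self.b1).relu(), training)
        ffn = hidden @ self.W2 + self.b2
        if self.cfg.literal_ffn:
            return ffn
        return self.bn2(ffn + H_hat, training)

    def parameters(self):
        ps = [self.W_Q, self.W_K, self.W_V, self.W1, self.b1, self.W2,
              self.b2] + self.bn1.parameters()
        if self.bn2 is not None:
            ps += self.bn2.parameters()
        return ps


def transformer_block(H_in, graph, layer: GraphTransformerLayer,
                      training: bool = False) -> Tensor:
    return layer(as_tensor(H_in), graph, training)


class GraphTransformerEncoder:
    """Input projection followed by stacked graph-transformer layers."""

    def __init__(self, n_genes: int, cfg: ModelConfig, rng):
        self.W_proj = _glorot((n_genes, cfg.d_h), rng)
        self.layers = [GraphTransformerLayer(cfg, rng)
                       for _ in range(cfg.n_layers)]

    def __call__(self, X, graph: CellGraph, training: bool = False) -> Tensor:
        H = input_projection(X, self.W_proj)
        for layer in self.layers:
            H = layer(H, graph, training)
        return H

    def parameters(self):
        ps = [self.W_proj]
        for layer in self.layers:
            ps += layer.parameters()
        return ps


# ---------------------------------------------------------------------------
# decoder and heads


def inner_product_decode(H_pr, H_sh) -> Tensor:
    """sigmoid(Z Z^T) over the concatenated private+shared embedding."""
    H_pr, H_sh = as_tensor(H_pr), as_tensor(H_sh)
    if H_pr.shape[0] != H_sh.shape[0]:
        raise ValueError("private and shared embeddings row counts differ")
    Z = concat([H_pr, H_sh], axis=1)
    return (Z @ Z.T).sigmoid().clip(EPS, 1.0 - EPS)


def gradient_reversal(H, lambda_grl: float) -> Tensor:
    """Identity forward; gradient multiplied by -lambda_grl on the way back."""
    if lambda_grl < 0:
        raise ValueError("lambda_grl must be >= 0")
    return as_tensor(H).gradient_reversal(lambda_grl)


class DomainDiscriminator:
    """Two-layer MLP scoring the probability a row came from the source."""

    def __init__(self, d_h: int, hidden: int, rng):
        self.W1 = _glorot((d_h, hidden), rng)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W2 = _glorot((hidden, 1), rng)
        self.b2 = Tensor(np.zeros(1), requires_grad=True)

    def __call__(self, H, lambda_grl: float | None = None) -> Tensor:
        H = as_tensor(H)
        if lambda_grl is not None:
            H = gradient_reversal(H, lambda_grl)
        z = (H @ self.W1 + self.b1).relu() @ self.W2 + self.b2
        return z.sigmoid().clip(EPS, 1.0 - EPS).reshape(-1)

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]


class ResponsePredictor:
    """Single linear layer + sigmoid giving P(sensitive)."""

    def __init__(self, d_h: int, rng):
        self.W = _glorot((d_h, 1), rng)
        self.b = Tensor(np.zeros(1), requires_grad=True)

    def __call__(self, H) -> Tensor:
        z = as_tensor(H) @ self.W + self.b
        return z.sigmoid().clip(EPS, 1.0 - EPS).reshape(-1)

    def parameters(self):
        return [self.W, self.b]


# ---------------------------------------------------------------------------
# full model


class DAGFormer:
    """Dual private encoders + weight-tied shared encoder with heads."""

    def __init__(self, n_genes: int, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.n_genes = n_genes
        rng = np.random.default_rng(self.config.seed)
        self.encoder_private_source = GraphTransformerEncoder(
            n_genes, self.config, rng)
        self.encoder_private_target = GraphTransformerEncoder(
            n_genes, self.config, rng)
        self.encoder_shared = GraphTransformerEncoder(n_genes, self.config, rng)
        self.discriminator = DomainDiscriminator(
            self.config.d_h, self.config.discriminator_hidden, rng)
        self.predictor = ResponsePredictor(self.config.d_h, rng)

    def encode(self, X, graph: CellGraph, which: str,
               training: bool = False) -> Tensor:
        enc = {
            "source_private": self.encoder_private_source,
            "target_private": self.encoder_private_target,
            "shared": self.encoder_shared,
        }[which]
        return enc(X, graph, training)

    def discriminate_domain(self, H_sh,
                            lambda_grl: float | None = None) -> Tensor:
        return self.discriminator(H_sh, lambda_grl)

    def predict_response(self, H_sh) -> Tensor:
        return self.predictor(H_sh)

    def parameters(self, include_discriminator: bool = True):
        ps = (self.encoder_private_source.parameters()
              + self.encoder_private_target.parameters()
              + self.encoder_shared.parameters()
              + self.predictor.parameters())
        if include_discriminator:
            ps += self.discriminator.parameters()
        return ps

    def _batchnorms(self):
        bns = []
        for enc in (self.encoder_private_source, self.encoder_private_target,
                    self.encoder_shared):
            for layer in enc.layers:
                bns.append(layer.bn1)
                if layer.bn2 is not None:
                    bns.append(layer.bn2)
        return bns

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """npz parameter container next to a JSON manifest of ModelConfig."""
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"bn{i}_mean"] = bn.running_mean
            arrays[f"bn{i}_var"] = bn.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        manifest = {"config": asdict(self.config), "n_genes": self.n_genes}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path) -> "DAGFormer":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        model = cls(manifest["n_genes"], ModelConfig(**manifest["config"]))
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"p{i}"]
        for i, bn in enumerate(model._batchnorms()):
            bn.running_mean = data[f"bn{i}_mean"]
            bn.running_var = data[f"bn{i}_var"]
        return model
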