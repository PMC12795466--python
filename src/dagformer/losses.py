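"""The five objective terms and their weighted combination.

Total objective (minimized by a single optimizer, with the adversarial
min-max realized through the gradient-reversal layer):

    L = L_cls + lambda_d * L_dom + lambda_e * L_ent
              + lambda_f * L_diff + lambda_r * L_rec

where L_cls is source cross-entropy, L_dom the domain-adversarial term,
L_ent the Bernoulli entropy of target predictions, L_diff the soft
subspace-orthogonality penalty between shared and private features, and
L_rec the graph-reconstruction cross-entropy. All logs are natural;
probabilities are clipped to [eps, 1-eps] with eps = 1e-7.

Sign convention: ``domain_loss`` returns the discriminator-maximized
quantity E[log D(src)] + E[log(1 - D(tgt))] (non-positive). Training
minimizes its negation — the standard binary cross-entropy with domain
labels source=1 / target=0 — while the gradient-reversal layer flips the
encoder-side gradient, so one backward pass realizes the min-max. The
LossReport records the signed quantity for interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor

EPS = 1e-7


@dataclass
class LossWeights:
    lambda_d: float = 0.5
    lambda_e_max: float = 0.01
    lambda_f: float = 1e-4
    lambda_r: float = 0.3

    def __post_init__(self):
        for name in ("lambda_d", "lambda_e_max", "lambda_f", "lambda_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class LossReport:
    epoch: int
    cls: float
    dom: float   # Eq.-20-signed adversarial quantity (<= 0)
    ent: float
    diff: float
    rec: float
    total: float

    def to_dict(self) -> dict:
        return {"epoch": self.epoch, "cls": self.cls, "dom": self.dom,
                "ent": self.ent, "diff": self.diff, "rec": self.rec,
                "total": self.total}


def _clip(p: Tensor) -> Tensor:
    return as_tensor(p).clip(EPS, 1.0 - EPS)


def classification_loss(psi_source, y) -> Tensor:
    """Mean binary cross-entropy of source sensitivity predictions."""
    psi = _clip(psi_source)
    labels = np.asarray(getattr(y, "labels", y), dtype=np.float64)
    if psi.shape[0] != labels.shape[0]:
        raise ValueError("predictions and labels length mismatch")
    return -(labels * psi.log() + (1.0 - labels) * (1.0 - psi).log()).mean()


def entropy_loss(psi_target) -> Tensor:
    """Mean Bernoulli entropy of target predictions; in [0, ln 2]."""
    psi = _clip(psi_target)
    return -(psi * psi.log() + (1.0 - psi) * (1.0 - psi).log()).mean()


def domain_loss(d_source, d_target) -> Tensor:
    """E[log D(source)] + E[log(1 - D(target))] (discriminator maximizes)."""
    ds = _clip(d_source)
    dt = _clip(d_target)
    return ds.log().mean() + (1.0 - dt).log().mean()


def difference_loss(h_sh_source, h_pr_source, h_sh_target, h_pr_target
                    ) -> Tensor:
    """Squared Frobenius norms of shared^T x private, summed over domains."""
    total = None
    for h_sh, h_pr in ((h_sh_source, h_pr_source),
                       (h_sh_target, h_pr_target)):
        h_sh, h_pr = as_tensor(h_sh), as_tensor(h_pr)
        if h_sh.shape[0] != h_pr.shape[0]:
            raise ValueError("shared/private row counts differ within a domain")
        cross = h_sh.T @ h_pr
        term = (cross * cross).sum()
        total = term if total is None else total + term
    return total


def reconstruction_loss(G_hat, G_binary) -> Tensor:
    """Mean BCE between reconstructed edge probabilities and the binary
    symmetrized adjacency (with self-loops) over all n^2 entries."""
    P = _clip(G_hat)
    target = np.asarray(getattr(G_binary, "binary", G_binary), dtype=np.float64)
    if not np.isin(target, (0.0, 1.0)).all():
        raise ValueError("reconstruction target must be binary")
    if P.shape != target.shape:
        raise ValueError("shape mismatch between reconstruction and target")
    return -(target * P.log() + (1.0 - target) * (1.0 - P).log()).mean()


def total_loss(cls, dom, ent, diff, rec, weights: LossWeights,
               lambda_e: float) -> Tensor:
    """Weighted sum; `dom` carries the signed adversarial quantity whose
    negation (the domain BCE) is the minimized term."""
    cls, ent, diff, rec = map(as_tensor, (cls, ent, diff, rec))
    total = cls + lambda_e * ent + weights.lambda_f * diff \
        + weights.lambda_r * rec
    if dom is not None:
        total = total + weights.lambda_d * (-as_tensor(dom))
    return total
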