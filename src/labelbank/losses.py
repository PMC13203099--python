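"""Similarity statistics and the training objective.

For a query vector z (the label-specific feature of the current sample) and a
label's stored banks, three statistics drive the contrastive constraints:

* D_pos — mean cosine similarity of z to the positive bank,
* D_neg — mean cosine similarity of z to the negative bank,
* D_cross — mean pairwise cosine similarity between the two banks
  (a property of the pool alone, independent of z).

Two hinge losses order these statistics. The align loss demands that z be
closer on average to its own-class bank:

    L_align = y * relu(D_neg - D_pos) + (1 - y) * relu(D_pos - D_neg)

and the margin loss pushes the opposite-class similarity below the banks'
mutual overlap:

    L_margin = y * relu(D_neg - D_cross) + (1 - y) * relu(D_pos - D_cross)

The classification loss is mean binary cross-entropy on logistic outputs, and
the total objective is L_cls plus the per-label contrastive terms aggregated
over labels (sum by default, mean optionally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import DataError, ValidationError

_EPS = 1e-12  # keeps the differentiable normalisation finite at the origin


# ---------------------------------------------------------------------------
# scalar (numpy) surface
# ---------------------------------------------------------------------------

def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("cosine similarity undefined for zero-norm input")
    return float(a @ b / (na * nb))


def pool_similarity(f_ext, bank) -> float:
    """Mean cosine similarity between a query and every bank row."""
    bank = np.asarray(bank, dtype=np.float64)
    if bank.ndim != 2 or bank.shape[0] == 0:
        raise ValidationError("bank must be a nonempty M x d matrix")
    norms = np.linalg.norm(bank, axis=1)
    if np.any(norms == 0):
        raise DataError("cosine similarity undefined for zero-norm bank row")
    f = np.asarray(f_ext, dtype=np.float64)
    nf = np.linalg.norm(f)
    if nf == 0:
        raise DataError("cosine similarity undefined for zero-norm query")
    return float(np.mean((bank @ f) / (norms * nf)))


def cross_pool_similarity(pos_bank, neg_bank) -> float:
    """Mean cosine similarity over all (positive, negative) row pairs."""
    pos = np.asarray(pos_bank, dtype=np.float64)
    neg = np.asarray(neg_bank, dtype=np.float64)
    for name, mat in (("positive", pos), ("negative", neg)):
        if mat.ndim != 2 or mat.shape[0] == 0:
            raise ValidationError(f"{name} bank must be a nonempty M x d matrix")
        if np.any(np.linalg.norm(mat, axis=1) == 0):
            raise DataError(f"zero-norm row in {name} bank")
    up = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    un = neg / np.linalg.norm(neg, axis=1, keepdims=True)
    return float((up @ un.T).mean())


def align_loss(d_pos: float, d_neg: float, y: int) -> float:
    _check_stat(d_pos, d_neg)
    y = _check_label(y)
    return y * max(0.0, d_neg - d_pos) + (1 - y) * max(0.0, d_pos - d_neg)


def margin_loss(d_pos: float, d_neg: float, d_cross: float, y: int) -> float:
    _check_stat(d_pos, d_neg, d_cross)
    y = _check_label(y)
    return y * max(0.0, d_neg - d_cross) + (1 - y) * max(0.0, d_pos - d_cross)


def classification_loss(logits, y) -> float:
    """Mean binary cross-entropy between logistic(logits) and labels."""
    logits = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if logits.shape != y.shape:
        raise ValidationError("logits and labels must have the same shape")
    # stable: max(x,0) - x*y + log(1 + exp(-|x|))
    return float(np.mean(np.maximum(logits, 0.0) - logits * y
                         + np.log1p(np.exp(-np.abs(logits)))))


@dataclass
class LossBundle:
    l_cls: float
    l_align: float
    l_margin: float
    l_final: float


def total_loss(l_cls: float, align_terms, margin_terms,
               aggregation: str = "sum") -> LossBundle:
    align_terms = np.asarray(align_terms, dtype=np.float64)
    margin_terms = np.asarray(margin_terms, dtype=np.float64)
    if align_terms.shape != margin_terms.shape:
        raise ValidationError("per-label loss lists must have equal length")
    if aggregation not in ("sum", "mean"):
        raise ValidationError("aggregation must be 'sum' or 'mean'")
    agg = np.sum if aggregation == "sum" else np.mean
    la, lm = float(agg(align_terms)), float(agg(margin_terms))
    return LossBundle(l_cls=float(l_cls), l_align=la, l_margin=lm,
                      l_final=float(l_cls) + la + lm)


def _check_stat(*vals):
    for v in vals:
        if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
            raise ValidationError(f"similarity statistic {v} outside [-1, 1]")


def _check_label(y) -> int:
    if y not in (0, 1):
        raise ValidationError(f"label must be 0 or 1, got {y}")
    return int(y)


# ---------------------------------------------------------------------------
# differentiable batch path
# ---------------------------------------------------------------------------

def bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, numerically stable, as a Tensor scalar."""
    y = np.asarray(y, dtype=logits.data.dtype)
    pos = ad.relu(logits)
    absx = ad.add(pos, ad.relu(ad.mul(logits, -1.0)))
    softplus = ad.log(ad.add(ad.exp(ad.mul(absx, -1.0)), 1.0))
    per = ad.add(ad.add(pos, ad.mul(ad.mul(logits, y), -1.0)), softplus)
    return per.mean()


def batch_contrastive(z: Tensor, pool, y: np.ndarray):
    """Per-sample, per-label align and margin hinge losses against the pool.

    z : Tensor (B, N, d), gradients flow through z only — the pool is a
        constant reference.
    y : (B, N) binary labels.

    Returns (align (B,N) Tensor, margin (B,N) Tensor, d_pos (B,N) array,
    d_neg (B,N) array).
    """
    dt = z.data.dtype
    y = np.asarray(y, dtype=dt)
    b, n, d = z.shape
    if y.shape != (b, n):
        raise ValidationError("labels must be (batch, n_labels)")
    mu_pos = np.stack([pool.mean_unit(i, True) for i in range(n)]).astype(dt)
    mu_neg = np.stack([pool.mean_unit(i, False) for i in range(n)]).astype(dt)
    d_cross = np.array([pool.cross_similarity(i) for i in range(n)], dtype=dt)

    norm = ad.sqrt(ad.add((z * z).sum(axis=2, keepdims=True), _EPS))
    uz = z / norm                                                   # (B,N,d)
    d_pos = (uz * Tensor(mu_pos[None])).sum(axis=2)                 # (B,N)
    d_neg = (uz * Tensor(mu_neg[None])).sum(axis=2)

    sign = 2.0 * y - 1.0  # +1 for positive labels, -1 for negative
    # align: relu(sign * (D_neg - D_pos)); margin: relu(sign*(D_neg or D_pos) - ...)
    align = ad.relu((d_neg - d_pos) * sign)
    own_opp = d_neg * y + d_pos * (1.0 - y)   # similarity to the opposite bank
    margin = ad.relu(own_opp - d_cross[None])
    return align, margin, d_pos.data.copy(), d_neg.data.copy()
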