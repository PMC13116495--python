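"""Imbalance-aware binary classification losses on logits.

Both losses operate on raw logits with numerically stable formulations
(softplus-based log-probabilities), elementwise over arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "weighted_bce_loss",
    "weighted_bce_grad",
    "focal_loss",
    "focal_grad",
    "compute_pos_weight",
    "make_sampler_weights",
]


def _softplus(t: np.ndarray) -> np.ndarray:
    # log(1 + e^t), stable for |t| up to several hundred
    return np.logaddexp(0.0, t)


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def weighted_bce_loss(logit, label, pos_weight: float = 1.0):
    """Binary cross-entropy with logits, positive term scaled by ``pos_weight``.

    ``loss = pos_weight * y * softplus(-z) + (1 - y) * softplus(z)``.
    Scalar inputs return a scalar; arrays return elementwise losses.
    """
    z = np.asarray(logit, dtype=float)
    y = np.asarray(label, dtype=float)
    loss = pos_weight * y * _softplus(-z) + (1.0 - y) * _softplus(z)
    return float(loss) if loss.ndim == 0 else loss


def weighted_bce_grad(logit, label, pos_weight: float = 1.0):
    """d loss / d logit for :func:`weighted_bce_loss`."""
    z = np.asarray(logit, dtype=float)
    y = np.asarray(label, dtype=float)
    p = _sigmoid(z)
    return pos_weight * y * (p - 1.0) + (1.0 - y) * p


def focal_loss(logit, label, alpha: float = 1.0, gamma: float = 2.0):
    """Focal loss on logits: ``-alpha_t * (1 - p_t)^gamma * log(p_t)``.

    ``p_t`` is the predicted probability of the true class; ``alpha``
    multiplies the positive-class term only, so ``gamma=0, alpha=1`` reduces
    exactly to the unweighted cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    z = np.asarray(logit, dtype=float)
    y = np.asarray(label, dtype=float)
    log_p = -_softplus(-z)   # log sigmoid(z)
    log_q = -_softplus(z)    # log (1 - sigmoid(z))
    p = _sigmoid(z)
    loss_pos = -alpha * (1.0 - p) ** gamma * log_p
    loss_neg = -(p ** gamma) * log_q
    loss = y * loss_pos + (1.0 - y) * loss_neg
    return float(loss) if loss.ndim == 0 else loss


def focal_grad(logit, label, alpha: float = 1.0, gamma: float = 2.0):
    """d loss / d logit for :func:`focal_loss` (analytic)."""
    z = np.asarray(logit, dtype=float)
    y = np.asarray(label, dtype=float)
    p = _sigmoid(z)
    q = 1.0 - p
    log_p = -_softplus(-z)
    log_q = -_softplus(z)
    p_log_p = np.where(p > 0, p * log_p, 0.0)
    q_log_q = np.where(q > 0, q * log_q, 0.0)
    # y=1: L = -alpha q^g log p  ->  dL/dz = alpha q^g (g p log p - q)
    grad_pos = alpha * q ** gamma * (gamma * p_log_p - q)
    # y=0: L = -p^g log q        ->  dL/dz = p^g (p - g q log q)
    grad_neg = p ** gamma * (p - gamma * q_log_q)
    return y * grad_pos + (1.0 - y) * grad_neg


def compute_pos_weight(labels) -> float:
    """Ratio of negative to positive samples (the BCE pos_weight default)."""
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0:
        raise ValueError("labels contain no positive samples")
    return n_neg / n_pos


def make_sampler_weights(labels) -> np.ndarray:
    """Per-sample weights proportional to inverse class frequency.

    Sampling with replacement under these weights yields an expected batch
    positive fraction of 0.5.  Weights are normalized to sum to 1.
    """
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for weighted sampling")
    w = np.where(y == 1, 1.0 / n_pos, 1.0 / n_neg)
    return w / w.sum()
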