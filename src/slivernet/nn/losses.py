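"""Loss functions returning (loss, gradient-wrt-logits) pairs."""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "bce_with_logits", "softmax_cross_entropy"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray, pos_weight=None):
    """Multi-label binary cross-entropy: summed over tasks, averaged over batch.

    ``pos_weight`` (optional, per-task) up-weights positive examples — useful
    under heavy class imbalance, off by default.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    # log(1+exp(-|z|)) formulation for stability
    log1pexp = np.log1p(np.exp(-np.abs(z)))
    per = np.maximum(z, 0.0) - z * y + log1pexp
    p = sigmoid(z)
    grad = p - y
    if pos_weight is not None:
        w = np.where(y > 0.5, np.asarray(pos_weight, dtype=np.float64), 1.0)
        per = per * w
        grad = grad * w
    n = z.shape[0]
    loss = per.sum() / n
    return float(loss), (grad / n).astype(np.float32)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """K-way cross-entropy with integer labels; mean over the batch."""
    z = logits.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    loss = -np.log(p[np.arange(n), labels] + 1e-300).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)
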