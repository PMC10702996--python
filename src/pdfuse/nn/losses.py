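"""Losses: numerically stable softmax cross-entropy and mean squared error."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "cross_entropy_loss", "mse_loss_grad"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch.  Returns (loss, dlogits)."""
    B = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = float(-np.log(p[np.arange(B), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return loss, dlogits / B


def mse_loss_grad(pred: np.ndarray, target: np.ndarray):
    """Mean over all elements of squared differences.  Returns (loss, dpred)."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size
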