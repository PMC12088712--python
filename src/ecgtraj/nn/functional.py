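"""Loss functions returning (loss, dlogits)."""
from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray,
                  class_weights: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean (optionally class-weighted) cross-entropy for integer targets."""
    n = logits.shape[0]
    p = softmax(logits)
    w = np.ones(n) if class_weights is None else class_weights[targets]
    logp = np.log(np.clip(p[np.arange(n), targets], 1e-12, None))
    loss = float(-(w * logp).sum() / w.sum())
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    dlogits *= (w / w.sum())[:, None]
    return loss, dlogits.astype(logits.dtype)


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error for a scalar prediction per sample."""
    pred = pred.reshape(-1)
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, (2.0 * diff / diff.size).astype(np.float32).reshape(-1, 1)
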