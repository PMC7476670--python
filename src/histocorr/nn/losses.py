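"""Loss functions (value + analytic gradient w.r.t. logits)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "softmax",
    "weighted_softmax_cross_entropy",
    "sigmoid",
    "bce_with_logits_map",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                                   class_weights: np.ndarray):
    """Class-weighted cross-entropy, normalized by the total weight.

    loss = sum_i w[y_i] * (-log p_i[y_i]) / sum_i w[y_i]

    Returns (loss, dloss/dlogits).
    """
    labels = np.asarray(labels, dtype=np.int64)
    w = np.asarray(class_weights, dtype=np.float64)[labels]
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    wsum = w.sum()
    loss = float(-(w * logp).sum() / wsum)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), labels] = 1.0
    dlogits = (w[:, None] * (p - onehot)) / wsum
    return loss, dlogits.astype(np.float32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits_map(logits: np.ndarray, target: float, mask: np.ndarray,
                        weight: float = 1.0):
    """Mask-gated binary cross-entropy over a spatial logit map.

    Only cells with ``mask == 1`` contribute; the loss is the weighted mean
    over those cells, ``weight * mean_masked(CE)``. Cells off the mask
    contribute exactly zero to both the value and the gradient.

    Returns (loss, dloss/dlogits). An all-zero mask yields (0.0, zeros).
    """
    mask = np.asarray(mask, dtype=np.float64)
    m = mask.sum()
    if m == 0:
        return 0.0, np.zeros_like(logits, dtype=np.float32)
    z = logits.astype(np.float64)
    # numerically stable: max(z,0) - z*y + log(1 + exp(-|z|))
    ce = np.maximum(z, 0.0) - z * target + np.log1p(np.exp(-np.abs(z)))
    loss = float(weight * (mask * ce).sum() / m)
    dlogits = weight * mask * (sigmoid(z) - target) / m
    return loss, dlogits.astype(np.float32)
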