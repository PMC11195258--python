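"""Masked weighted mean-squared error.

``L = sum(w * (p - t)^2) / max(sum(w), eps)`` — voxels with zero weight
contribute nothing to the loss nor to any parameter update.  Multi-head
losses are summed with unit head weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["masked_mse", "masked_mse_grad"]

EPS = 1e-8


def masked_mse(pred: np.ndarray, target: np.ndarray, weights: np.ndarray) -> float:
    if pred.shape != target.shape or pred.shape != weights.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape}, target {target.shape}, "
            f"weights {weights.shape}")
    w = np.asarray(weights, dtype=np.float64)
    diff = np.asarray(pred, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    return float((w * diff**2).sum() / max(w.sum(), EPS))


def masked_mse_grad(pred: np.ndarray, target: np.ndarray,
                    weights: np.ndarray) -> np.ndarray:
    """Gradient of :func:`masked_mse` with respect to ``pred``.

    Exactly zero wherever the weight is zero.
    """
    w = np.asarray(weights, dtype=np.float64)
    denom = max(w.sum(), EPS)
    grad = 2.0 * w * (np.asarray(pred, np.float64) - np.asarray(target, np.float64)) / denom
    return grad.astype(np.float32)
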