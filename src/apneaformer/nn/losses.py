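"""Numerically stable sigmoid / binary cross-entropy with logits."""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    # log(1 + exp(z)) without overflow
    return np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))


def weighted_bce_with_logits(
    logits: np.ndarray,
    targets: np.ndarray,
    weight_pos: float = 1.0,
    weight_neg: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Mean class-weighted binary cross-entropy and its gradient w.r.t.
    the logits.

    Per element: w * (softplus(z) - z*y) with w = y*weight_pos +
    (1-y)*weight_neg; gradient w * (sigmoid(z) - y) / N.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if z.shape != y.shape:
        raise ValueError(f"logits {z.shape} vs targets {y.shape}")
    w = y * weight_pos + (1.0 - y) * weight_neg
    loss = float(np.mean(w * (_softplus(z) - z * y)))
    dz = (w * (sigmoid(z) - y) / z.size).astype(np.float32)
    return loss, dz
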