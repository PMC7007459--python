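"""Minimal numpy neural-network engine for the IMU window classifier.

Implements exactly the pieces the classifier needs — valid-mode
convolutions with the per-location filter geometry, ReLU, global max
pooling over time, a dense layer with inverted dropout, softmax
cross-entropy with optional class weights, and the Adam optimizer —
with explicit forward/backward passes.  Everything is float32 and
driven by a caller-supplied ``numpy.random.Generator``, which makes
training bit-reproducible on one device.

Layer 1 slides a (9 channels × K1 frames) filter over time with a
vertical stride of 9, so every filter application covers exactly one
sensor location's accelerometer+gyroscope+magnetometer block and the
number of vertical filter positions equals the number of locations.
Layer 2 slides a K2-frame filter over each location's feature-map stack
(all layer-1 filters of that location at once), keeping locations
separate until the dense layer mixes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


# ---------------------------------------------------------------------------
# parameter initialization

def init_params(
    n_locations: int,
    n_classes: int,
    conv1_filters: int,
    conv1_time: int,
    conv2_filters: int,
    conv2_time: int,
    dense_units: int,
    rng: np.random.Generator,
    n_channels: int = 9,
) -> dict[str, np.ndarray]:
    """He-initialized parameters for the fixed architecture."""

    def he(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)

    return {
        "W1": he((n_channels * conv1_time, conv1_filters), n_channels * conv1_time),
        "b1": np.zeros(conv1_filters, dtype=DTYPE),
        "W2": he((conv1_filters * conv2_time, conv2_filters), conv1_filters * conv2_time),
        "b2": np.zeros(conv2_filters, dtype=DTYPE),
        "W3": he((n_locations * conv2_filters, dense_units), n_locations * conv2_filters),
        "b3": np.zeros(dense_units, dtype=DTYPE),
        "W4": he((dense_units, n_classes), dense_units),
        "b4": np.zeros(n_classes, dtype=DTYPE),
    }


# ---------------------------------------------------------------------------
# forward / backward

def forward(
    params: dict[str, np.ndarray],
    x: np.ndarray,
    conv1_time: int,
    conv2_time: int,
    dropout: float = 0.0,
    dropout_rng: np.random.Generator | None = None,
    n_channels: int = 9,
):
    """Forward pass.

    ``x`` has shape (B, 9·L, T).  Returns (logits, cache); dropout is
    active only when a generator is supplied (training mode).
    """
    B, rows, T = x.shape
    L = rows // n_channels
    K1, K2 = conv1_time, conv2_time
    x = np.ascontiguousarray(x, dtype=DTYPE).reshape(B, L, n_channels, T)

    # conv1: (9 × K1) filter per location block, stride 9 vertically
    p1 = sliding_window_view(x, K1, axis=3)           # (B, L, 9, T1, K1)
    T1 = T - K1 + 1
    p1 = p1.transpose(0, 1, 3, 2, 4).reshape(B, L, T1, n_channels * K1)
    a1 = p1 @ params["W1"] + params["b1"]             # (B, L, T1, F1)
    r1 = np.maximum(a1, 0.0)

    # conv2: K2-frame filter over each location's full feature stack
    p2 = sliding_window_view(r1, K2, axis=2)          # (B, L, T2, F1, K2)
    T2 = T1 - K2 + 1
    F1 = params["W1"].shape[1]
    p2 = p2.transpose(0, 1, 2, 4, 3).reshape(B, L, T2, F1 * K2)
    a2 = p2 @ params["W2"] + params["b2"]             # (B, L, T2, F2)
    r2 = np.maximum(a2, 0.0)

    # global max pooling over time, per (location, filter)
    pool_arg = np.argmax(r2, axis=2)                  # (B, L, F2)
    pooled = np.take_along_axis(r2, pool_arg[:, :, None, :], axis=2)[:, :, 0, :]
    flat = pooled.reshape(B, -1)                      # (B, L·F2)

    a3 = flat @ params["W3"] + params["b3"]
    r3 = np.maximum(a3, 0.0)
    if dropout > 0.0 and dropout_rng is not None:
        mask = (dropout_rng.random(r3.shape) >= dropout).astype(DTYPE) / DTYPE(1.0 - dropout)
        d3 = r3 * mask
    else:
        mask = None
        d3 = r3
    logits = d3 @ params["W4"] + params["b4"]

    cache = (x, p1, a1, p2, a2, r2, pool_arg, flat, a3, mask, d3, (L, T1, T2))
    return logits, cache


def backward(
    params: dict[str, np.ndarray],
    cache,
    dlogits: np.ndarray,
    conv1_time: int,
    conv2_time: int,
    n_channels: int = 9,
) -> dict[str, np.ndarray]:
    x, p1, a1, p2, a2, r2, pool_arg, flat, a3, mask, d3, (L, T1, T2) = cache
    B = x.shape[0]
    F1 = params["W1"].shape[1]
    F2 = params["W2"].shape[1]
    K1, K2 = conv1_time, conv2_time

    grads = {}
    grads["W4"] = d3.T @ dlogits
    grads["b4"] = dlogits.sum(axis=0)
    dd3 = dlogits @ params["W4"].T
    if mask is not None:
        dd3 = dd3 * mask
    da3 = dd3 * (a3 > 0)
    grads["W3"] = flat.T @ da3
    grads["b3"] = da3.sum(axis=0)
    dflat = da3 @ params["W3"].T
    dpooled = dflat.reshape(B, L, F2)

    # un-pool: route gradient to the argmax time position
    dr2 = np.zeros_like(r2)
    np.put_along_axis(dr2, pool_arg[:, :, None, :], dpooled[:, :, None, :], axis=2)
    da2 = dr2 * (a2 > 0)

    da2f = da2.reshape(-1, F2)
    grads["W2"] = p2.reshape(-1, F1 * K2).T @ da2f
    grads["b2"] = da2f.sum(axis=0)
    dp2 = (da2f @ params["W2"].T).reshape(B, L, T2, K2, F1)

    # col2im over time for conv2
    dr1 = np.zeros_like(a1)                            # (B, L, T1, F1)
    for k in range(K2):
        dr1[:, :, k : k + T2, :] += dp2[:, :, :, k, :]
    da1 = dr1 * (a1 > 0)

    da1f = da1.reshape(-1, F1)
    grads["W1"] = p1.reshape(-1, n_channels * K1).T @ da1f
    grads["b1"] = da1f.sum(axis=0)
    # input gradient is never needed (first layer); omit col2im for conv1
    return grads


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    logits: np.ndarray,
    y: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean (optionally class-weighted) cross-entropy and dL/dlogits."""
    B = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    p_true = np.clip(probs[np.arange(B), y], 1e-12, None)
    w = np.ones(B) if class_weights is None else class_weights[y]
    loss = float(np.mean(w * -np.log(p_true)))
    dlogits = probs
    dlogits[np.arange(B), y] -= 1.0
    dlogits *= (w / B)[:, None]
    return loss, dlogits.astype(DTYPE)


# ---------------------------------------------------------------------------
# optimizer

@dataclass
class Adam:
    """Adaptive-moment optimizer (per-parameter first/second moments)."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            g = g.astype(np.float64)
            m = self._m.get(k, 0.0) * b1 + (1 - b1) * g
            v = self._v.get(k, 0.0) * b2 + (1 - b2) * g * g
            self._m[k], self._v[k] = m, v
            m_hat = m / (1 - b1**self._t)
            v_hat = v / (1 - b2**self._t)
            params[k] -= (
                self.learning_rate * m_hat / (np.sqrt(v_hat) + self.epsilon)
            ).astype(DTYPE)
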