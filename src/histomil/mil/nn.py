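"""Minimal numpy neural-network primitives used by the MIL classifier.

Everything is deterministic given the RNG handed in; convolutions are
implemented as im2col + matmul so a single BLAS call does the work.
"""

from __future__ import annotations

import numpy as np


def he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def xavier_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot uniform initialization for the classification head."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def im2col3x3(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, 9C) patches of the zero-padded 3x3 window."""
    n, h, w, c = x.shape
    xp = np.zeros((n, h + 2, w + 2, c), dtype=x.dtype)
    xp[:, 1:-1, 1:-1, :] = x
    cols = np.empty((n, h, w, 9 * c), dtype=x.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            cols[..., k * c : (k + 1) * c] = xp[:, dy : dy + h, dx : dx + w, :]
            k += 1
    return cols


def conv3x3(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 convolution; weight is (9*C_in, C_out)."""
    cols = im2col3x3(x)
    return cols @ weight + bias


def maxpool(x: np.ndarray, p: int) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // p, p, w // p, p, c).max(axis=(2, 4))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class AdamW:
    """Adam with decoupled weight decay; decay skips 1-D (bias) parameters."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            m_hat = self.m[k] / bc1
            v_hat = self.v[k] / bc2
            if p.ndim > 1 and self.weight_decay > 0.0:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class EarlyStopper:
    """Stop when the validation metric fails to strictly improve for ``patience`` epochs."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best_metric = -np.inf
        self.best_epoch = 0
        self.stale = 0

    def update(self, epoch: int, metric: float) -> bool:
        """Record epoch (1-based); returns True when training should stop."""
        if metric > self.best_metric:
            self.best_metric = metric
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience
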