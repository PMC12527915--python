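"""Minimal neural-network primitives (numpy forward + hand-written backward).

Everything here operates on plain ndarrays and returns explicit caches for
the backward pass; parameters live in flat ``{name: array}`` dicts owned by
the model modules.  An Adam optimizer over such dicts is included.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) * _INV_SQRT_2PI
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * phi


def layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-5):
    """Normalize over the last axis. Returns (y, cache)."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xh = xc * inv
    return g * xh + b, (xh, inv, g)


def layer_norm_grad(dy: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (dx, dg, db)."""
    xh, inv, g = cache
    dg = (dy * xh).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxh = dy * g
    dx = inv * (
        dxh
        - dxh.mean(axis=-1, keepdims=True)
        - xh * (dxh * xh).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_grad(dy: np.ndarray, p: np.ndarray, axis: int = -1) -> np.ndarray:
    return p * (dy - (dy * p).sum(axis=axis, keepdims=True))


class Adam:
    """Adam over a dict of parameter arrays (updates in place)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        warmup_steps: int = 0,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.warmup_steps = warmup_steps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr = self.lr
        if self.warmup_steps and self.t <= self.warmup_steps:
            lr = self.lr * self.t / self.warmup_steps
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.ndim >= 2:  # decoupled; skip biases
                p -= lr * self.weight_decay * p


def bucketed_batches(
    idx: np.ndarray,
    lengths: np.ndarray,
    batch_size: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Split ``idx`` into batches of items with similar ``lengths``
    (minimizes padding), in shuffled batch order."""
    order = idx[np.argsort(lengths[idx], kind="stable")]
    batches = [order[s : s + batch_size] for s in range(0, order.size, batch_size)]
    return [batches[i] for i in rng.permutation(len(batches))]


def scatter_rows(idx: np.ndarray, vals: np.ndarray, n_rows: int) -> np.ndarray:
    """Sum rows of ``vals`` into ``out[idx]``.

    Embedding-table gradients.  For small tables a one-hot matmul is far
    faster than ``np.add.at``; large vocabularies fall back to it.
    """
    if n_rows <= 4096:
        oh = np.zeros((n_rows, idx.size), dtype=vals.dtype)
        oh[idx, np.arange(idx.size)] = 1.0
        return oh @ vals
    out = np.zeros((n_rows, vals.shape[1]), dtype=vals.dtype)
    np.add.at(out, idx, vals)
    return out


def init_linear(
    rng: np.random.Generator, fan_in: int, fan_out: int, dtype
) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return (rng.standard_normal((fan_in, fan_out)) * scale).astype(dtype)

def set_feature_stats(params, feats: np.ndarray) -> None:
    """Freeze input centering/scaling statistics from sample features."""
    a = params.arrays
    a["mu"] = feats.mean(axis=0).astype(a["mu"].dtype)
    dev = feats - a["mu"]
    a["sigma"] = np.asarray(
        max(float(np.sqrt((dev * dev).mean())), 1e-4), dtype=a["mu"].dtype
    )


def center_features(params, feats: np.ndarray, train: bool):
    """Standardize head inputs: (feats - mu) / sigma.

    Joint optimization shifts the whole feature distribution every step by
    more than the sample-to-sample spread, so training (batches >= 4) uses
    the CURRENT batch statistics, batchnorm-style.  Inference uses the
    ``mu``/``sigma`` buffers, which the training loops recalibrate from a
    full inference pass once optimization has finished.
    Returns (centered feats, sigma used, whether batch stats were used).
    """
    a = params.arrays
    if train and feats.shape[0] >= 4:
        mu_b = feats.mean(axis=0)
        dev = feats - mu_b
        sigma_b = float(np.sqrt((dev * dev).mean() + 1e-8))
        return dev / sigma_b, sigma_b, True
    return (feats - a["mu"]) / a["sigma"], float(a["sigma"]), False


def center_features_grad(d_c: np.ndarray, sigma: float, batch_stats: bool):
    """Backward of centering; the statistics are stop-gradient."""
    if batch_stats:
        return (d_c - d_c.mean(axis=0)) / sigma
    return d_c / sigma
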