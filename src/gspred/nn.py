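"""Minimal feed-forward network primitives (NumPy, hand-written backprop).

Supports the fully connected regression MLP used for genomic prediction:
ReLU hidden layers, linear scalar output, one (inverted) dropout layer
after the first hidden layer.  Shapes follow the row-per-sample
convention: ``X`` is ``(batch, p)``, ``W_k`` is ``(fan_in, fan_out)``.

Everything is a pure function of explicit parameter dicts so that training
loops stay deterministic and finite-difference gradient checks are easy.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np

Params = Dict[str, np.ndarray]


def init_theta(
    p: int,
    hidden_sizes: Tuple[int, ...],
    rng: np.random.Generator,
    dtype=np.float32,
) -> Params:
    """He-initialised weights for layer widths ``(p,) + hidden_sizes``."""
    widths = (p,) + tuple(hidden_sizes)
    theta: Params = {}
    for k in range(len(hidden_sizes)):
        fan_in, fan_out = widths[k], widths[k + 1]
        theta[f"W{k + 1}"] = (
            rng.standard_normal((fan_in, fan_out)) * math.sqrt(2.0 / fan_in)
        ).astype(dtype)
        theta[f"b{k + 1}"] = np.zeros(fan_out, dtype=dtype)
    return theta


def n_layers(theta: Params) -> int:
    return sum(1 for k in theta if k.startswith("W"))


def forward(
    theta: Params, X: np.ndarray, dropout_mask: Optional[np.ndarray] = None
):
    """Forward pass; returns (predictions, cache for backward).

    ``dropout_mask`` is an inverted-dropout multiplier for the first hidden
    layer's output (None disables dropout, as at inference).
    """
    L = n_layers(theta)
    cache = {"X": X, "h": [], "mask": dropout_mask}
    h = X
    for k in range(1, L + 1):
        z = h @ theta[f"W{k}"] + theta[f"b{k}"]
        if k < L:
            h = np.maximum(z, 0.0)
            if k == 1 and dropout_mask is not None:
                h = h * dropout_mask
        else:
            h = z
        cache["h"].append(h)
    return h[:, 0], cache


def backward(theta: Params, cache, dpred: np.ndarray):
    """Backprop; returns (parameter grads, gradient w.r.t. the input X)."""
    L = n_layers(theta)
    grads: Params = {}
    dh = dpred[:, None].astype(cache["h"][-1].dtype)
    for k in range(L, 0, -1):
        h_prev = cache["h"][k - 2] if k > 1 else cache["X"]
        if k < L:
            # ReLU (and dropout on layer 1) were applied after z_k
            act = cache["h"][k - 1]
            dh = dh * (act > 0)
            if k == 1 and cache["mask"] is not None:
                dh = dh * cache["mask"]
        grads[f"W{k}"] = h_prev.T @ dh
        grads[f"b{k}"] = dh.sum(axis=0)
        if k > 1:
            dh = dh @ theta[f"W{k}"].T
    dX = dh @ theta["W1"].T if L >= 1 else dh
    return grads, dX


class Adam:
    """Adam with the coupled (L2-in-gradient) weight-decay convention."""

    def __init__(self, params: Params, lr: float, beta1=0.9, beta2=0.99,
                 eps=1e-8, weight_decay=0.0):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Params, lr_scale: float = 1.0) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, g in grads.items():
            if self.weight_decay:
                g = g + self.weight_decay * params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            params[k] -= (self.lr * lr_scale) * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr_scale(epoch: int, max_epochs: int) -> float:
    """Cosine annealing multiplier: 1 at epoch 0 down to ~0 at max_epochs."""
    return 0.5 * (1.0 + math.cos(math.pi * epoch / max(max_epochs, 1)))
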