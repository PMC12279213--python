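"""Small neural-network toolkit on top of autograd.

Parameters live in nested dict/list pytrees of float64 numpy arrays;
`autograd.misc.flatten` turns a pytree into a flat vector so the optimizer is
a handful of array operations.  Forward functions are written with
``autograd.numpy`` and differentiated with ``autograd.grad`` — no tensors, no
sessions, deterministic given the seeds.
"""

from __future__ import annotations

import math

import autograd.numpy as anp
import numpy as np
from autograd.misc import flatten


def relu(x):
    return anp.maximum(x, 0.0)


def tanh(x):
    return anp.tanh(x)


def gelu(x):
    # tanh approximation
    return 0.5 * x * (1.0 + anp.tanh(0.7978845608028654 * (x + 0.044715 * x ** 3)))


def silu(x):
    return x / (1.0 + anp.exp(-x))


def elu(x):
    return anp.where(x > 0, x, anp.exp(anp.minimum(x, 0.0)) - 1.0)


ACTIVATIONS = {"relu": relu, "tanh": tanh, "gelu": gelu, "silu": silu, "elu": elu}


def init_mlp(sizes: list[int], rng: np.random.Generator) -> list[dict]:
    """Glorot-uniform MLP parameters for layer sizes [in, h1, ..., out]."""
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        lim = math.sqrt(6.0 / (fan_in + fan_out))
        params.append({
            "W": rng.uniform(-lim, lim, size=(fan_in, fan_out)),
            "b": np.zeros(fan_out),
        })
    return params


def mlp_forward(params, X, activation="relu"):
    act = ACTIVATIONS[activation] if isinstance(activation, str) else activation
    h = X
    for layer in params[:-1]:
        h = act(h @ layer["W"] + layer["b"])
    last = params[-1]
    return h @ last["W"] + last["b"]


def log_softmax(logits, axis=-1):
    m = anp.max(logits, axis=axis, keepdims=True)
    s = logits - m
    return s - anp.log(anp.sum(anp.exp(s), axis=axis, keepdims=True))


def cosine_lr(base_lr: float, step: int, total_steps: int, min_lr: float = 0.0) -> float:
    """Cosine annealing from base_lr down to min_lr over total_steps."""
    if total_steps <= 1:
        return base_lr
    t = min(step, total_steps - 1) / (total_steps - 1)
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + math.cos(math.pi * t))


class AdamW:
    """AdamW with decoupled weight decay, operating on a flat parameter vector."""

    def __init__(self, n_params: int, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray, lr: float | None = None) -> np.ndarray:
        lr = self.lr if lr is None else lr
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad ** 2
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        return theta - lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * theta)


class FlatModel:
    """Couples a parameter pytree with its flat view."""

    def __init__(self, params):
        self.theta, self.unflatten = flatten(params)

    @property
    def params(self):
        return self.unflatten(self.theta)

    def grad_flat(self, params_grad):
        g, _ = flatten(params_grad)
        return g


def standardize_stats(X: np.ndarray):
    """(mean, std) with std floored at 1e-8 to keep scaling invertible."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    std = np.maximum(X.std(axis=0), 1e-8)
    return mean, std
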