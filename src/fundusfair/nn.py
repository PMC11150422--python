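"""Minimal numpy neural-network kit: layers with explicit backprop,
Adam, and a one-cycle learning-rate schedule.

Layers cache what their backward pass needs on forward; `backward(grad)`
accumulates parameter gradients into `Param.grad` and returns the
gradient with respect to the layer input. Shapes are NCHW throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "Linear",
    "ReLU",
    "global_avg_pool",
    "sigmoid",
    "Adam",
    "OneCycleSchedule",
]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)
    name: str = ""

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Linear:
    """Affine map y = x W^T + b for (N, in) inputs."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        name: str = "linear",
        init_std: float | None = None,
    ):
        std = math.sqrt(2.0 / n_in) if init_std is None else init_std
        self.W = Param(rng.normal(0.0, std, size=(n_out, n_in)), name=f"{name}.W")
        self.b = Param(np.zeros(n_out), name=f"{name}.b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value

    def params(self) -> list[Param]:
        return [self.W, self.b]


class Conv2d:
    """2-D convolution (cross-correlation) via im2col, NCHW."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        padding: int,
        rng: np.random.Generator,
        name: str = "conv",
    ):
        fan_in = c_in * kernel * kernel
        std = math.sqrt(2.0 / fan_in)
        self.W = Param(rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)), name=f"{name}.W")
        self.b = Param(np.zeros(c_out), name=f"{name}.b")
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        self._cols = cols
        self._shape = (n, c, h, w, ho, wo)
        wf = self.W.value.reshape(self.W.value.shape[0], -1)
        out = cols @ wf.T + self.b.value
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        n, c, h, w, ho, wo = self._shape
        c_out = grad.shape[1]
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, c_out)
        self.W.grad += (g2.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += g2.sum(axis=0)
        wf = self.W.value.reshape(c_out, -1)
        dcols = (g2 @ wf).reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by batch statistics over (N, H, W); eval
    mode uses the running averages, so inference is deterministic and
    batch-size independent.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(c), name=f"{name}.gamma")
        self.beta = Param(np.zeros(c), name=f"{name}.beta")
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self.training = True
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        dbeta = grad.sum(axis=(0, 2, 3))
        dgamma = (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        if not self.training:
            return grad * (self.gamma.value * inv)[None, :, None, None]
        g = grad * self.gamma.value[None, :, None, None]
        return (
            inv[None, :, None, None]
            / m
            * (m * g - g.sum(axis=(0, 2, 3))[None, :, None, None]
               - xhat * (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None])
        )

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)

    def params(self) -> list[Param]:
        return []


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def global_avg_pool_backward(grad: np.ndarray, h: int, w: int) -> np.ndarray:
    return np.broadcast_to(grad[:, :, None, None] / (h * w), grad.shape + (h, w)).copy()


class Adam:
    """Adam with (PyTorch-style) L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class OneCycleSchedule:
    """Cosine one-cycle schedule: warm up to max_lr, anneal to ~0.

    `pct_start` of the run warms up from max_lr/div_factor; the remainder
    anneals to max_lr/final_div_factor.
    """

    def __init__(
        self,
        max_lr: float,
        total_steps: int,
        pct_start: float = 0.3,
        div_factor: float = 25.0,
        final_div_factor: float = 1e4,
    ):
        if total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        self.max_lr = max_lr
        self.total_steps = total_steps
        self.pct_start = pct_start
        self.initial_lr = max_lr / div_factor
        self.final_lr = max_lr / final_div_factor

    def lr_at(self, step: int) -> float:
        step = min(step, self.total_steps - 1)
        warm = max(int(round(self.pct_start * self.total_steps)), 1)
        if step < warm:
            t = step / warm
            lo, hi = self.initial_lr, self.max_lr
        else:
            t = (step - warm) / max(self.total_steps - warm, 1)
            lo, hi = self.final_lr, self.max_lr
            t = t  # anneal phase: cosine from hi down to lo
            return lo + (hi - lo) * 0.5 * (1 + math.cos(math.pi * t))
        return hi + (lo - hi) * 0.5 * (1 + math.cos(math.pi * t))
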