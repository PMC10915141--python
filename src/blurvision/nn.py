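"""Minimal feedforward conv-net framework on numpy.

Implements exactly the layer zoo the probes need — 2-D convolution, ReLU,
2x2 max/average pooling, global average pooling, flatten and linear — with
hand-written backward passes. That buys three things the analysis battery
requires from a single code path: gradient-based training (Adam), gradients
with respect to the *input* (adversarial attacks), and per-layer forward
caches (relevance propagation). Arrays are float64 NCHW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "AvgPool2",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Unfold kxk patches of NCHW `x` (same-size output) into (N, C*k*k, H*W)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, xshape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add overlapping patches)."""
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Layer:
    """Base layer: `forward` caches whatever `backward` needs."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    """Same-padding stride-1 convolution (cross-correlation), square kernel."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        rng = np.random.default_rng(rng)
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k, self.pad = k, k // 2
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._xshape = x.shape
        self._cols = _im2col(x, self.k, self.pad)  # (N, Cin*k*k, H*W)
        n, _, h, w = x.shape
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = np.einsum("of,nfp->nop", wmat, self._cols) + self.b[None, :, None]
        return out.reshape(n, self.w.shape[0], h, w)

    def backward(self, grad):
        n, co, h, w = grad.shape
        g = grad.reshape(n, co, h * w)
        wmat = self.w.reshape(co, -1)
        self.dw[...] = np.einsum("nop,nfp->of", g, self._cols).reshape(self.w.shape)
        self.db[...] = g.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", wmat, g)
        return _col2im(dcols, self._xshape, self.k, self.pad)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._xshape = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        self._arg = r.argmax(axis=-1)
        return r.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._xshape
        d = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(d, self._arg[..., None], grad[..., None], axis=-1)
        d = d.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(n, c, h, w)


class AvgPool2(Layer):
    """2x2 average pooling, stride 2."""

    def forward(self, x):
        self._xshape = x.shape
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._xshape
        return np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0


class GlobalAvgPool(Layer):
    """NCHW -> NC spatial mean."""

    def forward(self, x):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._xshape
        return np.broadcast_to(grad[:, :, None, None], self._xshape) / (h * w)


class Flatten(Layer):
    def forward(self, x):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._xshape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng=None):
        rng = np.random.default_rng(rng)
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        self.b = np.zeros(d_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.dw[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Sequential:
    """Ordered named layers with full forward/backward and activation capture."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        self.layers = list(layers)

    @property
    def layer_names(self) -> list[str]:
        return [n for n, _ in self.layers]

    def __getitem__(self, name: str) -> Layer:
        for n, l in self.layers:
            if n == name:
                return l
        raise KeyError(f"unknown layer {name!r}")

    def forward(self, x: np.ndarray, record: dict | None = None) -> np.ndarray:
        for name, layer in self.layers:
            x = layer.forward(x)
            if record is not None:
                record[name] = x
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for _, l in self.layers for p in l.params()]

    def grads(self):
        return [g for _, l in self.layers for g in l.grads()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), labels] + 1e-300).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


@dataclass
class Adam:
    """Adam over a fixed parameter/gradient list (updated in place)."""

    params: list = field(default_factory=list)
    grads: list = field(default_factory=list)
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        self._m = [np.zeros_like(p) for p in self.params]
        self._v = [np.zeros_like(p) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
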