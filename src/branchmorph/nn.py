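"""Minimal NumPy layer library with explicit, hand-written gradients.

The segmentation model in this package runs on a small set of layers
(3x3/1x1 convolution, depthwise convolution, 2x2 transpose convolution,
2x2 max pooling, dense, ReLU/Sigmoid) implemented directly on NumPy
arrays in NCHW layout.  Each layer caches what its backward pass needs
during ``forward`` and accumulates parameter gradients in
``Parameter.grad`` during ``backward``; a layer instance is used at one
site of the network graph, so a single cache slot suffices.

Keeping the numeric core in NumPy makes training bitwise-reproducible
for a fixed seed and keeps the package free of heavyweight framework
dependencies; every layer's gradient is verified against central
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "DepthwiseConv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "Dense",
    "ReLU",
    "Sigmoid",
    "sigmoid",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Module:
    """Base class: a callable with parameters and a backward pass."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    """Same-padding convolution, stride 1, odd kernel size (im2col)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("Conv2d requires an odd kernel size")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(_he_init(rng, (c_out, fan_in), fan_in, dtype), f"{name}.w")
        self.bias = Parameter(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        cols = np.ascontiguousarray(cols)
        y = cols @ self.weight.value.T + self.bias.value
        self._cache = (cols, (n, c, h, w))
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, (n, c, h, w) = self._cache
        p, k = self.k // 2, self.k
        dyc = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * w, self.c_out)
        self.weight.grad += dyc.T @ cols
        self.bias.grad += dyc.sum(axis=0)
        dcols = (dyc @ self.weight.value).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for u in range(k):
            for v in range(k):
                dxp[:, :, u:u + h, v:v + w] += dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class DepthwiseConv2d(Module):
    """Per-channel (depthwise) same-padding convolution, stride 1."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "dwconv"):
        if kernel % 2 != 1:
            raise ValueError("DepthwiseConv2d requires an odd kernel size")
        self.c, self.k = channels, kernel
        fan_in = kernel * kernel
        self.weight = Parameter(_he_init(rng, (channels, kernel, kernel), fan_in, dtype),
                                f"{name}.w")
        self.bias = Parameter(np.zeros(channels, dtype=dtype), f"{name}.b")
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        y = np.einsum("nchwuv,cuv->nchw", win, self.weight.value, optimize=True)
        y += self.bias.value[None, :, None, None]
        self._cache = (win, (n, c, h, w))
        return y

    def backward(self, dy):
        win, (n, c, h, w) = self._cache
        p, k = self.k // 2, self.k
        self.weight.grad += np.einsum("nchwuv,nchw->cuv", win, dy, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for u in range(k):
            for v in range(k):
                dxp[:, :, u:u + h, v:v + w] += dy * self.weight.value[:, u, v][None, :, None, None]
        return dxp[:, :, p:p + h, p:p + w]


class ConvTranspose2d(Module):
    """2x2 transpose convolution with stride 2 (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "upconv"):
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in  # each output position sees one input position per tap
        self.weight = Parameter(_he_init(rng, (c_in, c_out, 2, 2), fan_in, dtype), f"{name}.w")
        self.bias = Parameter(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x):
        n, c, h, w = x.shape
        y = np.empty((n, self.c_out, 2 * h, 2 * w), dtype=x.dtype)
        for u in range(2):
            for v in range(2):
                tap = np.tensordot(x, self.weight.value[:, :, u, v], axes=([1], [0]))
                y[:, :, u::2, v::2] = tap.transpose(0, 3, 1, 2)
        y += self.bias.value[None, :, None, None]
        self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        dx = np.zeros_like(x)
        for u in range(2):
            for v in range(2):
                dtap = dy[:, :, u::2, v::2]
                self.weight.grad[:, :, u, v] += np.einsum(
                    "nchw,nohw->co", x, dtap, optimize=True
                )
                dx += np.einsum("nohw,co->nchw", dtap, self.weight.value[:, :, u, v],
                                optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        return dx


class MaxPool2d(Module):
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def __init__(self):
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}x{w}")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, c, h, w))
        return y

    def backward(self, dy):
        idx, (n, c, h, w) = self._cache
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class Dense(Module):
    """Fully connected layer on (N, C_in) inputs."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "dense"):
        self.weight = Parameter(_he_init(rng, (c_out, c_in), c_in, dtype), f"{name}.w")
        self.bias = Parameter(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x):
        self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        x = self._cache
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Sigmoid(Module):
    def forward(self, x):
        self._out = sigmoid(x)
        return self._out

    def backward(self, dy):
        return dy * self._out * (1.0 - self._out)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean pixelwise cross-entropy and its gradient w.r.t. the logits.

    ``logits`` is (N, K, H, W); ``labels`` is (N, H, W) with values in
    [0, K).  Returns ``(loss, dlogits)``.
    """
    n, k, h, w = logits.shape
    p = softmax(logits, axis=1)
    onehot_idx = labels[:, None, :, :]
    picked = np.take_along_axis(p, onehot_idx, axis=1)[:, 0]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    dlogits = p.copy()
    np.put_along_axis(dlogits, onehot_idx, np.take_along_axis(dlogits, onehot_idx, axis=1) - 1.0,
                      axis=1)
    dlogits /= n * h * w
    return loss, dlogits


class Adam:
    """Adam optimizer with per-parameter state and optional freezing."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.state = {id(p): (np.zeros_like(p.value), np.zeros_like(p.value), 0)
                      for p in self.params}

    def step(self, frozen: set[int] | None = None) -> None:
        frozen = frozen or set()
        for p in self.params:
            if id(p) in frozen:
                continue
            m, v, t = self.state[id(p)]
            t += 1
            m = self.beta1 * m + (1 - self.beta1) * p.grad
            v = self.beta2 * v + (1 - self.beta2) * p.grad * p.grad
            self.state[id(p)] = (m, v, t)
            mhat = m / (1 - self.beta1**t)
            vhat = v / (1 - self.beta2**t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
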