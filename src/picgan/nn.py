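"""Minimal convolutional-network toolkit on numpy with explicit backprop.

Implements exactly the pieces the reconstruction networks need — 2-D
convolution (im2col), non-overlapping transposed convolution for 2x
upsampling, batch normalization with running statistics, ReLU, and Adam —
with hand-derived backward passes.  Forward caches are stored per layer, so
a layer instance supports one forward/backward pair at a time; gradients
accumulate across backward calls until ``zero_grad``.

Gradient correctness is established by central-difference checks in the
test suite (run in float64).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2x",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "Sequential",
    "GlobalAvgPool",
    "Adam",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. BN running stats), in a stable order."""
        return []

    def set_buffers(self, arrays: list[np.ndarray]) -> None:
        pass


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for a in range(k):
        for b in range(k):
            cols[:, :, a, b] = xp[:, :, a : a + stride * ho : stride, b : b + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo), (ho, wo)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for a in range(k):
        for b in range(k):
            xp[:, :, a : a + stride * ho : stride, b : b + stride * wo : stride] += cols[:, :, a, b]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d(Layer):
    """2-D convolution, 'same'-style padding k//2, stride 1 or 2."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, zero_init: bool = False,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        if zero_init:
            w = np.zeros((c_out, fan_in))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.w = Param(w.astype(dtype), "conv.w")
        self.b = Param(np.zeros(c_out, dtype=dtype), "conv.b")
        self.k, self.stride, self.pad = k, stride, k // 2
        self.c_in, self.c_out = c_in, c_out
        self._cache = None

    def forward(self, x, train=True):
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        y = np.einsum("of,nfl->nol", self.w.value, cols, optimize=True)
        y += self.b.value[None, :, None]
        self._cache = (cols, x.shape)
        return y.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, gy):
        cols, x_shape = self._cache
        n = x_shape[0]
        g = gy.reshape(n, self.c_out, -1)
        self.w.grad += np.einsum("nol,nfl->of", g, cols, optimize=True)
        self.b.grad += g.sum(axis=(0, 2))
        gcols = np.einsum("of,nol->nfl", self.w.value, g, optimize=True)
        return _col2im(gcols, x_shape, self.k, self.stride, self.pad)

    def params(self):
        return [self.w, self.b]


class ConvTranspose2x(Layer):
    """Transposed convolution with kernel 2, stride 2 (non-overlapping 2x
    upsampling), the standard U-Net up-convolution."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out, 2, 2))
        self.w = Param(w.astype(dtype), "convT.w")
        self.b = Param(np.zeros(c_out, dtype=dtype), "convT.b")
        self.c_in, self.c_out = c_in, c_out
        self._x = None

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        y = np.einsum("nchw,cokl->nohkwl", x, self.w.value, optimize=True)
        y = y.reshape(n, self.c_out, 2 * h, 2 * w)
        y += self.b.value[None, :, None, None]
        self._x = x
        return y

    def backward(self, gy):
        x = self._x
        n, c, h, w = x.shape
        g = gy.reshape(n, self.c_out, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
        # g: (n, o, h, w, k, l)
        self.w.grad += np.einsum("nohwkl,nchw->cokl", g, x, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        return np.einsum("nohwkl,cokl->nchw", g, self.w.value, optimize=True)

    def params(self):
        return [self.w, self.b]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gy):
        xhat, inv, train, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma.value[None, :, None, None]
        if not train:
            return gxhat * inv[None, :, None, None]
        mean_g = gxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (gxhat - mean_g - xhat * mean_gx) * inv[None, :, None, None]

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def set_buffers(self, arrays):
        self.running_mean, self.running_var = arrays[0].copy(), arrays[1].copy()


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.1):
        self.negative_slope = negative_slope
        self._mask = None

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.negative_slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.negative_slope * gy)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        n, c, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None], self._shape) / (h * w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def set_buffers(self, arrays):
        i = 0
        for l in self.layers:
            n = len(l.buffers())
            if n:
                l.set_buffers(arrays[i : i + n])
                i += n


class Adam:
    """Adam optimizer at the framework-default moments (0.9, 0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
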