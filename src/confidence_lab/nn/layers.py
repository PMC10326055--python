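"""Minimal layer library with explicit backprop.

Each layer caches what it needs during ``forward`` and returns the input
gradient from ``backward`` while accumulating parameter gradients into its
``Param`` objects. Layers follow the fan-in-scaled uniform initialization
U(-1/sqrt(fan_in), 1/sqrt(fan_in)) for weights and biases, so results do not
depend on any framework's default initializer.
"""

from __future__ import annotations

import numpy as np

from . import functional as F


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        self.w = Param(_fan_in_uniform(rng, (out_features, in_features), in_features))
        self.b = Param(_fan_in_uniform(rng, (out_features,), in_features)) if bias else None
        self._x = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        self._x = x
        out = x @ self.w.value.T
        if self.b is not None:
            out += self.b.value
        return out

    def backward(self, dout):
        self.w.grad += dout.T @ self._x
        if self.b is not None:
            self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int, pad: int, rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        self.w = Param(_fan_in_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.b = Param(_fan_in_uniform(rng, (out_ch,), fan_in))
        self.stride, self.pad = stride, pad
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        out, cols = F.conv2d_forward(x, self.w.value, self.b.value, self.stride, self.pad)
        self._cache = (x.shape, cols)
        return out

    def backward(self, dout):
        x_shape, cols = self._cache
        dx, dw, db = F.conv2d_backward(dout, x_shape, cols, self.w.value, self.stride, self.pad)
        self.w.grad += dw
        self.b.grad += db
        return dx


class ConvTranspose2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int, pad: int, rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        self.w = Param(_fan_in_uniform(rng, (in_ch, out_ch, kernel, kernel), fan_in))
        self.b = Param(_fan_in_uniform(rng, (out_ch,), fan_in))
        self.stride, self.pad = stride, pad
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        out, _ = F.conv_transpose2d_forward(x, self.w.value, self.b.value, self.stride, self.pad)
        return out

    def backward(self, dout):
        dx, dw, db = F.conv_transpose2d_backward(dout, self._x, self.w.value, self.stride, self.pad)
        self.w.grad += dw
        self.b.grad += db
        return dx


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial dims for 4-D inputs).

    Training uses batch statistics and updates exponential running averages;
    evaluation uses the running statistics (frozen network behavior).
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(num_features))
        self.beta = Param(np.zeros(num_features))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1, 1)

    def forward(self, x, train=False):
        axes, sh = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.size // x.shape[1]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            # unbiased variance in the running estimate, as is conventional
            unbiased = var * m / max(m - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv_std.reshape(sh)
        self._cache = (xhat, inv_std, train)
        return self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)

    def backward(self, dout):
        xhat, inv_std, train = self._cache
        axes, sh = self._axes(dout), self._shape(dout)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(sh)
        if not train:
            return dxhat * inv_std.reshape(sh)
        m = dout.size // dout.shape[1]
        term = dxhat - dxhat.mean(axis=axes).reshape(sh) - xhat * (dxhat * xhat).mean(axis=axes).reshape(sh)
        return inv_std.reshape(sh) * term


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        self.slope = negative_slope
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._out = np.tanh(x)
        return self._out

    def backward(self, dout):
        return dout * (1.0 - self._out**2)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = shape

    def forward(self, x, train=False):
        self._in = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, dout):
        return dout.reshape(self._in)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
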