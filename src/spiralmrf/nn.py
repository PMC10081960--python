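"""Minimal real-valued neural-network layers with manual backpropagation.

Only what the k-space interpolators need: pointwise (width-1) convolutions,
width-w 1D convolutions along the readout, graph convolutions that
aggregate with a fixed sparse propagation matrix, ReLU, residual blocks,
mean-squared-error loss, and an ADAM optimizer.  Arrays are ``(Q, channels)``
float64; one training sample is one readout's worth of stacked
real/imaginary coil channels.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Parameter",
    "PointwiseConv",
    "Conv1d",
    "GraphConv",
    "ReLU",
    "Residual",
    "Sequential",
    "Adam",
    "mse_loss",
    "glorot_uniform",
]


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class PointwiseConv(Layer):
    """Width-1 convolution: an affine map applied at every readout point."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.W = Parameter(glorot_uniform(rng, (in_ch, out_ch), in_ch, out_ch))
        self.b = Parameter(np.zeros(out_ch))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Conv1d(Layer):
    """1D convolution along the readout with zero padding (same size)."""

    def __init__(self, width: int, in_ch: int, out_ch: int, rng: np.random.Generator):
        if width % 2 != 1:
            raise ValueError("kernel width must be odd")
        self.width = width
        self.W = Parameter(
            glorot_uniform(rng, (width, in_ch, out_ch), width * in_ch, out_ch)
        )
        self.b = Parameter(np.zeros(out_ch))
        self._xpad: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        v = self.width // 2
        Q = x.shape[0]
        xpad = np.pad(x, ((v, v), (0, 0)))
        self._xpad = xpad
        y = self.b.value + np.zeros((Q, self.W.value.shape[2]))
        for k in range(self.width):
            y += xpad[k : k + Q] @ self.W.value[k]
        return y

    def backward(self, dy):
        Q = dy.shape[0]
        v = self.width // 2
        dxpad = np.zeros_like(self._xpad)
        for k in range(self.width):
            self.W.grad[k] += self._xpad[k : k + Q].T @ dy
            dxpad[k : k + Q] += dy @ self.W.value[k].T
        self.b.grad += dy.sum(axis=0)
        return dxpad[v : v + Q] if v else dxpad


class GraphConv(Layer):
    """Graph convolution ``y = P (x W) + b`` with a fixed propagation matrix."""

    def __init__(self, prop: sp.spmatrix, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.P = sp.csr_matrix(prop)
        self.PT = self.P.T.tocsr()
        self.W = Parameter(glorot_uniform(rng, (in_ch, out_ch), in_ch, out_ch))
        self.b = Parameter(np.zeros(out_ch))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return self.P @ (x @ self.W.value) + self.b.value

    def backward(self, dy):
        du = self.PT @ dy
        self.W.grad += self._x.T @ du
        self.b.grad += dy.sum(axis=0)
        return du @ self.W.value.T


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Residual(Layer):
    """``y = relu(body(x) + shortcut(x))``.

    The shortcut is the identity when input and output channel counts
    match, otherwise a learned pointwise projection.
    """

    def __init__(self, body: Layer, shortcut: Layer | None):
        self.body = body
        self.shortcut = shortcut
        self.relu = ReLU()

    def params(self):
        ps = self.body.params()
        if self.shortcut is not None:
            ps = ps + self.shortcut.params()
        return ps

    def forward(self, x):
        s = x if self.shortcut is None else self.shortcut.forward(x)
        return self.relu.forward(self.body.forward(x) + s)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        dx = self.body.backward(dy)
        if self.shortcut is None:
            return dx + dy
        return dx + self.shortcut.backward(dy)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """ADAM optimizer over a list of :class:`Parameter`."""

    def __init__(self, params: list[Parameter], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
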