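"""Minimal numpy neural-network engine.

Implements exactly the two architectures this package needs — a small
encoder/decoder segmentation network and a tiny dense classifier — with
hand-written backpropagation.  Convolutions are evaluated as a single GEMM
over a buffered im2col matrix (float32 throughout), which is the fastest
arrangement for single-threaded BLAS at these sizes.

Everything is deterministic given the integer seed used to initialise the
parameters and the RNG used for batch shuffling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "Conv1x1",
    "MaxPool2",
    "Upsample2",
    "Dense",
    "relu",
    "softmax",
    "sigmoid",
    "Adam",
    "RMSProp",
]

F32 = np.float32


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Conv3x3:
    """3x3 same-padding convolution (+ optional fused ReLU), NHWC layout."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool = True):
        scale = np.sqrt(2.0 / (9 * c_in))
        self.W = (rng.normal(0.0, scale, size=(9 * c_in, c_out))).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.c_in, self.c_out, self.relu = c_in, c_out, relu
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, ci = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        # (n, h, w, ci, 3, 3) windows -> (n*h*w, 3*3*ci) patch matrix; the
        # transpose puts the window offsets ahead of the channel axis so the
        # weight layout is (offset-major, channel-minor).
        v = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        col = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
        return col.reshape(n * h * w, 9 * ci)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        col = self._im2col(x)
        y = (col @ self.W + self.b).reshape(n, h, w, self.c_out)
        if self.relu:
            mask = y > 0
            y *= mask
            self._cache = (col, (n, h, w), mask)
        else:
            self._cache = (col, (n, h, w), None)
        return y

    def backward(self, dy: np.ndarray):
        col, (n, h, w), mask = self._cache
        if mask is not None:
            dy = dy * mask
        dyf = dy.reshape(-1, self.c_out)
        self.dW = col.T @ dyf
        self.db = dyf.sum(axis=0)
        dcol = (dyf @ self.W.T).reshape(n * h * w, 9, self.c_in)
        dxp = np.zeros((n, h + 2, w + 2, self.c_in), dtype=F32)
        k = 0
        for di in range(3):
            for dj in range(3):
                dxp[:, di:di + h, dj:dj + w, :] += dcol[:, k, :].reshape(n, h, w, self.c_in)
                k += 1
        self._cache = None
        return dxp[:, 1:-1, 1:-1, :]

    @property
    def grads(self):
        return [self.dW, self.db]


class Conv1x1:
    """1x1 convolution (a per-pixel dense layer), no activation."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.W = rng.normal(0.0, scale, size=(c_in, c_out)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.c_in, self.c_out = c_in, c_out

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray):
        xf = self._x.reshape(-1, self.c_in)
        dyf = dy.reshape(-1, self.c_out)
        self.dW = xf.T @ dyf
        self.db = dyf.sum(axis=0)
        dx = (dyf @ self.W.T).reshape(self._x.shape)
        self._x = None
        return dx

    @property
    def grads(self):
        return [self.dW, self.db]


class MaxPool2:
    """2x2 max pooling with stride 2."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        r = r.reshape(n, h // 2, w // 2, 4, c)
        self._arg = r.argmax(axis=3)
        self._shape = (n, h, w, c)
        return np.take_along_axis(r, self._arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy: np.ndarray):
        n, h, w, c = self._shape
        dr = np.zeros((n, h // 2, w // 2, 4, c), dtype=F32)
        np.put_along_axis(dr, self._arg[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = dr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        self._arg = None
        return dx.reshape(n, h, w, c)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Dense:
    """Fully connected layer with optional fused ReLU.

    Weights use Glorot-uniform initialisation, the standard choice for
    small dense softmax classifiers.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu: bool = True):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float64)
        self.b = np.zeros(n_out, dtype=np.float64)
        self.relu = relu

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x @ self.W + self.b
        if self.relu:
            mask = y > 0
            y = y * mask
            self._cache = (x, mask)
        else:
            self._cache = (x, None)
        return y

    def backward(self, dy: np.ndarray):
        x, mask = self._cache
        if mask is not None:
            dy = dy * mask
        self.dW = x.T @ dy
        self.db = dy.sum(axis=0)
        self._cache = None
        return dy @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class RMSProp:
    """RMSProp with the standard moving-average-of-squares rule."""

    def __init__(self, params, lr=1e-4, rho=0.9, eps=1e-7):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, grads) -> None:
        for p, g, c in zip(self.params, grads, self.cache):
            c *= self.rho
            c += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)
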