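"""Numpy neural-network layers with explicit forward/backward passes.

All layers operate channels-last, on arrays of shape ``(batch, length,
channels)``: with this layout the im2col matrix and the convolution output
are both contiguous, so the whole pass runs on contiguous memory with one
GEMM per convolution direction. Convolutions are stride-1 "same"-padded
with odd kernels; the transposed convolution doubles the length by
zero-interleaving before convolving. Analytic gradients are exercised
against numerical differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "DTYPE",
    "Layer",
    "Conv1d",
    "ConvTranspose1d",
    "BatchNorm1d",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "MaxPool1d",
    "Flatten",
    "Dense",
]

#: working precision of the network; single precision halves memory traffic
DTYPE = np.float32


class Layer:
    """Base layer: holds ``params``/``grads`` dicts keyed by parameter name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sublayers(self) -> list["Layer"]:
        return [self]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv1d(Layer):
    """Stride-1 same-padded 1-D convolution on (batch, length, channels).

    Weights have shape ``(c_in * kernel, c_out)`` (im2col layout); forward
    and backward are each a single GEMM plus an O(kernel) fold.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = _he_init(rng, (c_in * kernel, c_out), c_in * kernel)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, ell, c = x.shape
        k, p = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # windows over length: (B, L, C, k) -> rows of the im2col matrix
        cols = sliding_window_view(xp, k, axis=1)
        self._xmat = cols.reshape(b * ell, c * k)
        self._shape = (b, ell, c)
        y = self._xmat @ self.params["W"] + self.params["b"]
        return y.reshape(b, ell, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, ell, c = self._shape
        k, p = self.kernel, self.kernel // 2
        gmat = grad.reshape(b * ell, self.c_out)
        self.grads["b"] = gmat.sum(axis=0)
        self.grads["W"] = self._xmat.T @ gmat
        dcols = (gmat @ self.params["W"].T).reshape(b, ell, c, k)
        dxp = np.zeros((b, ell + 2 * p, c), dtype=grad.dtype)
        for t in range(k):  # fold the k taps back onto the padded length axis
            dxp[:, t : t + ell, :] += dcols[:, :, :, t]
        return dxp[:, p : p + ell, :]


class ConvTranspose1d(Layer):
    """Length-doubling transposed convolution: zero-interleave then convolve."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv1d(c_in, c_out, kernel, rng)
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, ell, c = x.shape
        z = np.zeros((b, 2 * ell, c), dtype=x.dtype)
        z[:, ::2, :] = x
        return self.conv.forward(z, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.conv.backward(grad)[:, ::2, :]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        m = grad.shape[0] * grad.shape[1]
        self.grads["gamma"] = (grad * self._xhat).sum(axis=(0, 1))
        self.grads["beta"] = grad.sum(axis=(0, 1))
        g = grad * self.params["gamma"]
        # d/dx of batch-normalized activation (training-mode statistics)
        gsum = g.sum(axis=(0, 1), keepdims=True)
        gx = (g * self._xhat).sum(axis=(0, 1), keepdims=True)
        return self._istd * (g - gsum / m - self._xhat * gx / m)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, x.dtype.type(0))
        self._mask = y > 0
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # clip logits to the exp-safe range; the output saturates there anyway
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -80.0, 80.0)))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at inference and at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling of width 2 along the length axis."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, ell, c = x.shape
        if ell % 2 != 0:
            raise ValueError(f"MaxPool1d(2) needs even length, got {ell}")
        xr = x.reshape(b, ell // 2, 2, c)
        self._argmax = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, half, c = grad.shape
        gx = np.zeros((b, half, 2, c), dtype=grad.dtype)
        np.put_along_axis(gx, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        return gx.reshape(b, half * 2, c)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer on (batch, features)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _he_init(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T
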