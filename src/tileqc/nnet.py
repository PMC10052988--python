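"""A compact numpy CNN training backend.

Implements exactly the pieces the tile-quality classifier needs — valid
convolution via im2col, ReLU, 2×2 max pooling, dense layers, inverted
dropout, a sigmoid/binary-cross-entropy head, and the Adam optimizer —
with explicit forward/backward passes.  Everything is driven by a single
``numpy.random.Generator`` so runs are reproducible bit-for-bit on the
same platform.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = ["Conv2D", "ReLU", "MaxPool2x2", "Flatten", "Dense", "Dropout",
           "Sequential", "Adam", "sigmoid", "bce_loss"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class Layer:
    params: list  # list of [value, grad] pairs

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid cross-correlation, stride 1, NHWC layout, He-initialized."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = kernel * kernel * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, filters))
        b = np.zeros(filters)
        self.kernel = kernel
        self.in_channels = in_channels
        self.filters = filters
        self.w = [w, np.zeros_like(w)]
        self.b = [b, np.zeros_like(b)]
        self.params = [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # (N, oh, ow, C, k, k) -> (N, oh, ow, k, k, C)
        win = win.transpose(0, 1, 2, 4, 5, 3)
        return np.ascontiguousarray(win)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x_shape = x.shape
        k = self.kernel
        cols = self._im2col(x).reshape(x.shape[0], -1, k * k * self.in_channels)
        self._cols = cols
        n, oh, ow = x.shape[0], x.shape[1] - k + 1, x.shape[2] - k + 1
        out = cols @ self.w[0] + self.b[0]
        return out.reshape(n, oh, ow, self.filters)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oh, ow, f = grad.shape
        k, c = self.kernel, self.in_channels
        g = grad.reshape(n, oh * ow, f)
        self.w[1] = np.einsum("npk,npf->kf", self._cols, g)
        self.b[1] = g.sum(axis=(0, 1))
        dcols = (g @ self.w[0].T).reshape(n, oh, ow, k, k, c)
        dx = np.zeros(self._x_shape)
        for di in range(k):
            for dj in range(k):
                dx[:, di:di + oh, dj:dj + ow, :] += dcols[:, :, :, di, dj, :]
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2x2(Layer):
    """2×2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        x = x[:, :oh * 2, :ow * 2, :]
        r = x.reshape(n, oh, 2, ow, 2, c)
        out = r.max(axis=(2, 4))
        # ties within a window (rare with float activations) share gradient
        self._mask = (r == out[:, :, None, :, None, :])
        return out

    def backward(self, grad):
        n, oh, ow, c = grad.shape
        g = (self._mask * grad[:, :, None, :, None, :]).reshape(
            n, oh * 2, ow * 2, c)
        dx = np.zeros(self._in_shape)
        dx[:, :oh * 2, :ow * 2, :] = g
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(in_features, out_features))
        b = np.zeros(out_features)
        self.w = [w, np.zeros_like(w)]
        self.b = [b, np.zeros_like(b)]
        self.params = [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.w[0] + self.b[0]

    def backward(self, grad):
        self.w[1] = self._x.T @ grad
        self.b[1] = grad.sum(axis=0)
        return grad @ self.w[0].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise InvalidArgumentError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential:
    """Ordered layer stack with a sigmoid/BCE head for binary outputs."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return sigmoid(x.reshape(-1))

    def backward(self, p: np.ndarray, y: np.ndarray) -> None:
        # d(BCE)/d(logit) for a sigmoid head
        grad = ((p - y) / len(y)).reshape(-1, 1)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params, learning_rate: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if learning_rate <= 0:
            raise InvalidArgumentError("learning rate must be positive")
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p[0]) for p in params]
        self.v = [np.zeros_like(p[0]) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            g = p[1]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p[0] -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
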