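"""A small NumPy sequence-model engine with reverse-mode gradients.

Implements exactly the layers the stress classifiers need — causal 1D
convolution, ReLU, layer normalization, global average pooling, LSTM,
dropout, and a dense head — together with softmax cross-entropy and the
Adam optimizer.  Shapes follow the time-series convention
``(batch, time, channels)``.

Every layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward``; the
gradient implementations are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "ReLU",
    "LayerNorm",
    "GlobalAveragePool",
    "LSTM",
    "Dropout",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter/gradient registry plus forward/backward."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Conv1D(Layer):
    """Causal 1D convolution: output length equals input length.

    The input is left-padded with ``kernel - 1`` zeros so each output step
    sees only current and past samples.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.w = glorot_uniform(
            rng, (kernel, in_channels, out_channels), kernel * in_channels, kernel * out_channels
        )
        self.b = np.zeros(out_channels)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._xp = np.pad(x, ((0, 0), (self.k - 1, 0), (0, 0)))
        t = x.shape[1]
        y = np.zeros((x.shape[0], t, self.out_channels))
        for j in range(self.k):
            y += self._xp[:, j : j + t, :] @ self.w[j]
        return y + self.b

    def backward(self, grad):
        t = grad.shape[1]
        self.grads[1] += grad.sum(axis=(0, 1))
        dxp = np.zeros_like(self._xp)
        for j in range(self.k):
            seg = self._xp[:, j : j + t, :]
            self.grads[0][j] += np.einsum("bti,bto->io", seg, grad)
            dxp[:, j : j + t, :] += grad @ self.w[j].T
        return dxp[:, self.k - 1 :, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LayerNorm(Layer):
    """Layer normalization with per-channel gain and bias.

    ``axis="features"`` normalizes across channels at each time step (the
    default); ``axis="time"`` normalizes each channel across the window.
    """

    def __init__(self, channels: int, axis: str = "features", eps: float = 1e-5):
        super().__init__()
        if axis not in ("features", "time"):
            raise ValueError("axis must be 'features' or 'time'")
        self.axis = 2 if axis == "features" else 1
        self.eps = eps
        self.g = np.ones(channels)
        self.b = np.zeros(channels)
        self.params = [self.g, self.b]
        self.grads = [np.zeros_like(self.g), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        mu = x.mean(axis=self.axis, keepdims=True)
        var = x.var(axis=self.axis, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.g + self.b

    def backward(self, grad):
        self.grads[0] += (grad * self._xhat).sum(axis=(0, 1))
        self.grads[1] += grad.sum(axis=(0, 1))
        dxhat = grad * self.g
        m1 = dxhat.mean(axis=self.axis, keepdims=True)
        m2 = (dxhat * self._xhat).mean(axis=self.axis, keepdims=True)
        return (dxhat - m1 - self._xhat * m2) * self._inv


class GlobalAveragePool(Layer):
    """Average each feature map over time: (B, T, C) -> (B, C)."""

    def forward(self, x, train=False):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._t, axis=1) / self._t


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state: (B, T, C) -> (B, H).

    Gate layout in the packed weight matrices is (input, forget, cell, output);
    the forget-gate bias starts at 1 so early training does not flush memory.
    """

    def __init__(self, in_channels: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.h = hidden
        self.in_channels = in_channels
        self.wx = glorot_uniform(rng, (in_channels, 4 * hidden), in_channels, hidden)
        self.wh = glorot_uniform(rng, (hidden, 4 * hidden), hidden, hidden)
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        b, t, _ = x.shape
        h = self.h
        self._x = x
        self._cache = []
        h_t = np.zeros((b, h))
        c_t = np.zeros((b, h))
        for step in range(t):
            a = x[:, step, :] @ self.wx + h_t @ self.wh + self.b
            i = _sigmoid(a[:, :h])
            f = _sigmoid(a[:, h : 2 * h])
            g = np.tanh(a[:, 2 * h : 3 * h])
            o = _sigmoid(a[:, 3 * h :])
            c_prev, h_prev = c_t, h_t
            c_t = f * c_prev + i * g
            tanh_c = np.tanh(c_t)
            h_t = o * tanh_c
            self._cache.append((i, f, g, o, c_prev, h_prev, tanh_c))
        return h_t

    def backward(self, grad):
        x = self._x
        b, t, _ = x.shape
        h = self.h
        dx = np.zeros_like(x)
        dh = grad
        dc = np.zeros((b, h))
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tanh_c = self._cache[step]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads[0] += x[:, step, :].T @ da
            self.grads[1] += h_prev.T @ da
            self.grads[2] += da.sum(axis=0)
            dx[:, step, :] = da @ self.wx.T
            dh = da @ self.wh.T
            dc = dc * f
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout fraction must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    """Fully connected layer (B, F) -> (B, K).

    ``zero_init=True`` starts weights and bias at zero — used for the final
    classification layer so training is exactly equivariant under class
    relabelling.
    """

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        if zero_init:
            self.w = np.zeros((in_features, out_features))
        else:
            self.w = glorot_uniform(rng, (in_features, out_features), in_features, out_features)
        self.b = np.zeros(out_features)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0] += self._x.T @ grad
        self.grads[1] += grad.sum(axis=0)
        return grad @ self.w.T


class Sequential:
    """Ordered layer container with aggregate parameter registry."""

    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient with respect to the logits."""
    p = softmax(logits)
    n = len(labels)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n, p


class Adam:
    """Adaptive moment estimation with bias correction."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
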