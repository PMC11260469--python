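"""Minimal NumPy neural-network engine: layers, backprop and Adam.

Everything is float64 and strictly deterministic: parameter initialisation
is driven by an explicit :class:`numpy.random.Generator` seed and the
forward/backward passes contain no randomness, so repeated runs with the
same seed are bit-identical on a single device.

Layers follow a simple protocol: ``forward(x)`` caches whatever the
backward pass needs, ``backward(grad_out)`` accumulates parameter
gradients in ``layer.grads`` and returns the gradient w.r.t. the input.
``layer.trainable`` gates optimizer updates (used for frozen-backbone
fine-tuning) without affecting gradient flow.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1D",
    "LSTM",
    "Flatten",
    "Adam",
    "glorot_uniform",
    "softplus",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe
    return np.logaddexp(0.0, x)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    fan_in, fan_out = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    trainable: bool = True

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Dense(Layer):
    """Fully connected layer ``y = act(x @ W + b)``."""

    def __init__(self, n_in: int, n_out: int, activation: str | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = glorot_uniform(rng, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported activation: {activation}")
        self.activation = activation

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            z = np.where(self._mask, z, 0.0)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dout = dout * self._mask
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T


class Conv1D(Layer):
    """1-D convolution over (N, L, C) input with 'same' zero padding."""

    def __init__(self, n_in: int, n_filters: int, width: int,
                 activation: str | None = "relu",
                 rng: np.random.Generator | None = None):
        if width % 2 == 0:
            raise ValueError("kernel width must be odd for 'same' padding")
        rng = rng or np.random.default_rng(0)
        self.width = width
        self.n_in = n_in
        self.W = glorot_uniform(rng, (width * n_in, n_filters))
        self.b = np.zeros(n_filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported activation: {activation}")
        self.activation = activation

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, xp: np.ndarray, L: int) -> np.ndarray:
        n, _, c = xp.shape
        w = self.width
        cols = np.empty((n, L, w * c))
        for t in range(L):
            cols[:, t, :] = xp[:, t:t + w, :].reshape(n, w * c)
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        pad = self.width // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        cols = self._im2col(xp, L)
        self._cols = cols
        self._in_shape = x.shape
        z = cols @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            z = np.where(self._mask, z, 0.0)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dout = dout * self._mask
        n, L, c = self._in_shape
        w = self.width
        pad = w // 2
        flat_cols = self._cols.reshape(n * L, w * c)
        flat_dout = dout.reshape(n * L, -1)
        self.dW += flat_cols.T @ flat_dout
        self.db += flat_dout.sum(axis=0)
        dcols = (flat_dout @ self.W.T).reshape(n, L, w, c)
        dxp = np.zeros((n, L + 2 * pad, c))
        for t in range(L):
            dxp[:, t:t + w, :] += dcols[:, t]
        return dxp[:, pad:L + pad, :]


class LSTM(Layer):
    """Single-layer LSTM over (N, T, D); returns the full (N, T, H) output.

    Gate order in the packed weight matrix is input, forget, cell, output.
    The forget-gate bias is initialised to 1 (standard practice to avoid
    early vanishing of the cell state).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_in = n_in
        self.hidden = hidden
        self.W = glorot_uniform(rng, (n_in + hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden:2 * hidden] = 1.0
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, T, d = x.shape
        h = self.hidden
        H = np.zeros((n, T, h))
        self._cache = []
        h_t = np.zeros((n, h))
        c_t = np.zeros((n, h))
        for t in range(T):
            xh = np.concatenate([x[:, t, :], h_t], axis=1)
            z = xh @ self.W + self.b
            i = sigmoid(z[:, :h])
            f = sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = sigmoid(z[:, 3 * h:])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tanh_c = np.tanh(c_t)
            h_t = o * tanh_c
            H[:, t, :] = h_t
            self._cache.append((xh, i, f, g, o, c_prev, tanh_c))
        self._in_shape = x.shape
        return H

    def backward(self, dH: np.ndarray) -> np.ndarray:
        n, T, d = self._in_shape
        h = self.hidden
        dx = np.zeros((n, T, d))
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for t in range(T - 1, -1, -1):
            xh, i, f, g, o, c_prev, tanh_c = self._cache[t]
            dh = dH[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            self.dW += xh.T @ da
            self.db += da.sum(axis=0)
            dxh = da @ self.W.T
            dx[:, t, :] = dxh[:, :d]
            dh_next = dxh[:, d:]
            dc_next = dc * f
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Adam:
    """Adam optimizer over a list of layers; skips non-trainable layers."""

    def __init__(self, layers: list[Layer], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in lay.params] for lay in layers]
        self.v = [[np.zeros_like(p) for p in lay.params] for lay in layers]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for li, lay in enumerate(self.layers):
            if not lay.trainable:
                continue
            for pi, (p, g) in enumerate(zip(lay.params, lay.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
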