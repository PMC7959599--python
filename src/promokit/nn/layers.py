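"""Minimal NumPy layers for 1D sequence models.

All activations use a channels-last layout: a batch is ``(B, T, C)`` for
float inputs or ``(B, T)`` integer tokens feeding an :class:`Embedding`.
Each layer implements ``forward(x, training)`` and ``backward(dout)`` and
exposes matching ``params`` / ``grads`` lists consumed by the optimizer.
Weights are Glorot-uniform initialised from a seeded generator in
``DEFAULT_DTYPE`` (float32; tests may switch to float64 for high-precision
finite-difference checks).
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32

__all__ = [
    "Layer",
    "Embedding",
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Dropout",
    "LSTM",
]


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DEFAULT_DTYPE)


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x, training: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Embedding(Layer):
    """Token-index lookup table: (B, T) ints -> (B, T, dim) floats.

    Row 0 serves the reserved out-of-vocabulary index, so the table has
    ``vocab_size + 1`` rows for token values in [0, vocab_size].
    """

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.W = _glorot(rng, (vocab_size + 1, dim), vocab_size + 1, dim)
        self.dW = np.zeros_like(self.W)
        self.params = [self.W]
        self.grads = [self.dW]

    def forward(self, x, training: bool = False):
        self._x = x
        return self.W[x]

    def backward(self, dout):
        self.dW[...] = 0.0
        np.add.at(self.dW, self._x, dout)
        return None  # integer inputs carry no gradient


class Conv1D(Layer):
    """Width-``w`` 1D convolution with 'same' zero padding, (B,T,Cin)->(B,T,Cout)."""

    def __init__(self, c_in: int, c_out: int, width: int, rng: np.random.Generator):
        if width % 2 == 0:
            raise ValueError("filter width must be odd for same padding")
        self.width = width
        self.c_in = c_in
        fan_in = width * c_in
        self.W = _glorot(rng, (fan_in, c_out), fan_in, c_out)
        self.b = np.zeros(c_out, dtype=self.W.dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, training: bool = False):
        B, T, C = x.shape
        p = self.width // 2
        xp = np.zeros((B, T + 2 * p, C), dtype=self.W.dtype)
        xp[:, p : p + T] = x
        # (B, T, C, width) channel-major rows match the weight layout
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.width, axis=1)
        cols = cols.reshape(B * T, C * self.width)
        self._cols = cols
        self._T = T
        out = cols @ self.W + self.b
        return out.reshape(B, T, -1)

    def backward(self, dout):
        B, T, c_out = dout.shape
        d2 = dout.reshape(B * T, c_out)
        self.dW[...] = self._cols.T @ d2
        self.db[...] = d2.sum(axis=0)
        dcols = (d2 @ self.W.T).reshape(B, T, self.c_in, self.width)
        p = self.width // 2
        dxp = np.zeros((B, T + 2 * p, self.c_in), dtype=self.W.dtype)
        for j in range(self.width):
            dxp[:, j : j + T] += dcols[:, :, :, j]
        return dxp[:, p : p + T]


class ReLU(Layer):
    def forward(self, x, training: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1D(Layer):
    """Max pooling over ``size`` positions with the given stride.

    With stride 1 the sequence only shortens by ``size - 1`` positions.
    """

    def __init__(self, size: int, stride: int = 1):
        self.size = size
        self.stride = stride

    def forward(self, x, training: bool = False):
        windows = np.lib.stride_tricks.sliding_window_view(x, self.size, axis=1)
        windows = windows[:, :: self.stride]  # (B, Tout, C, size)
        out = windows.max(axis=-1)
        self._x = x
        self._out = out
        return out

    def backward(self, dout):
        # route each gradient to the first position attaining the window max
        dx = np.zeros(self._x.shape, dtype=dout.dtype)
        B, Tout, C = dout.shape
        taken = np.zeros(dout.shape, dtype=bool)
        for j in range(self.size):
            starts_slice = (
                slice(j, j + Tout)
                if self.stride == 1
                else np.arange(Tout) * self.stride + j
            )
            eq = (self._x[:, starts_slice] == self._out) & ~taken
            contrib = dout * eq
            if self.stride == 1:
                dx[:, starts_slice] += contrib
            else:
                np.add.at(dx, (slice(None), starts_slice), contrib)
            taken |= eq
        return dx


class Flatten(Layer):
    def forward(self, x, training: bool = False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=self.W.dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, training: bool = False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None  # set by the network

    def forward(self, x, training: bool = False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state: (B,T,D) -> (B,H).

    Gate order in the packed weight matrices is input, forget, cell, output.
    Forget-gate bias starts at 1, the common initialisation that keeps
    early gradients flowing.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        H = self.units = units
        self.Wx = _glorot(rng, (d_in, 4 * H), d_in, 4 * H)
        self.Wh = _glorot(rng, (H, 4 * H), H, 4 * H)
        self.b = np.zeros(4 * H, dtype=self.Wx.dtype)
        self.b[H : 2 * H] = 1.0
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [self.dWx, self.dWh, self.db]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, x, training: bool = False):
        B, T, D = x.shape
        H = self.units
        h = np.zeros((B, H), dtype=self.Wx.dtype)
        c = np.zeros((B, H), dtype=self.Wx.dtype)
        self._x = x
        self._cache = []
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = self._sigmoid(z[:, :H])
            f = self._sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = self._sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        return h

    def backward(self, dout):
        x = self._x
        B, T, D = x.shape
        H = self.units
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dx = np.zeros_like(x, dtype=self.Wx.dtype)
        dh = dout.astype(self.Wx.dtype)
        dc = np.zeros((B, H), dtype=self.Wx.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dWx += x[:, t].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx
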