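"""A compact trainable neural-network layer library on numpy.

Implements exactly the building blocks the reconstruction and classification
networks need — dense, LSTM, 1-D and 2-D (transposed) convolutions, batch
normalization, dropout, residual blocks — with hand-derived backpropagation,
an Adam optimizer, mean-squared-error and softmax cross-entropy losses, and
a mini-batch training loop with validation-based early stopping that restores
the best-validation parameters.

Array conventions: sequences are (batch, time, features); images are
(batch, height, width, channels). Every layer exposes ``forward(x, training)``
and ``backward(dy) -> dx`` and caches whatever the backward pass needs.
All gradients are checked against central finite differences in the test
suite; the implementations favour clarity over micro-optimization but keep
the inner loops as matrix products.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

try:  # JIT-compiled LSTM kernels; the numpy path below is the reference
    from numba import njit

    _HAS_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAS_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap

#: Compute dtype for training (float32 halves memory traffic and roughly
#: doubles GEMM throughput; gradient-check tests switch to float64).
DEFAULT_DTYPE = np.float32

__all__ = [
    "Parameter",
    "Layer",
    "Dense",
    "LSTM",
    "Conv1D",
    "Conv1DTranspose",
    "Conv2D",
    "Conv2DTranspose",
    "BatchNorm",
    "Dropout",
    "ReLU",
    "Sigmoid",
    "Tanh",
    "RepeatVector",
    "TakeLast",
    "GlobalAvgPool1D",
    "Reshape",
    "Sequential",
    "Bidirectional",
    "GlobalContextConcat",
    "ResidualBlock1D",
    "Adam",
    "EarlyStopper",
    "NeuralNetwork",
    "mse_loss",
    "softmax_cross_entropy",
]


class Parameter:
    """A trainable array with its gradient accumulator.

    ``decay`` marks weight matrices eligible for L1/L2 penalties (biases and
    normalization parameters are exempt, the usual convention).
    """

    __slots__ = ("data", "grad", "decay")

    def __init__(self, data: np.ndarray, decay: bool = False):
        self.data = np.ascontiguousarray(data, dtype=DEFAULT_DTYPE)
        self.grad = np.zeros_like(self.data)
        self.decay = decay


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Parameter]:
        return []


class Dense(Layer):
    """Affine map applied to the last axis: y = x @ W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(_glorot(rng, (n_in, n_out), n_in, n_out), decay=True)
        self.b = Parameter(np.zeros(n_out))

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.data.T

    def params(self):
        return [self.W, self.b]


@njit(cache=True)
def _lstm_forward_kernel(xproj, Wh, b, H):  # pragma: no cover - exercised via LSTM
    B, T, H4 = xproj.shape
    one = np.float32(1.0)
    gates = np.empty((T, B, H4), np.float32)
    c_prev = np.empty((T, B, H), np.float32)
    h_prev = np.empty((T, B, H), np.float32)
    cs = np.empty((T, B, H), np.float32)
    tanh_cs = np.empty((T, B, H), np.float32)
    hs = np.empty((B, T, H), np.float32)
    h = np.zeros((B, H), np.float32)
    c = np.zeros((B, H), np.float32)
    for t in range(T):
        z = xproj[:, t] + np.dot(h, Wh) + b
        i = one / (one + np.exp(-z[:, :H]))
        f = one / (one + np.exp(-z[:, H : 2 * H]))
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = one / (one + np.exp(-z[:, 3 * H :]))
        h_prev[t] = h
        c_prev[t] = c
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        gates[t, :, :H] = i
        gates[t, :, H : 2 * H] = f
        gates[t, :, 2 * H : 3 * H] = g
        gates[t, :, 3 * H :] = o
        cs[t] = c
        tanh_cs[t] = tc
        hs[:, t] = h
    return gates, c_prev, h_prev, cs, tanh_cs, hs


@njit(cache=True)
def _lstm_backward_kernel(dy_seq, gates, c_prev, tanh_cs, WhT, H):  # pragma: no cover
    # only the recurrence stays in the loop; the dense gradient GEMMs are
    # hoisted out to a single large matrix product each (see LSTM.backward)
    T, B = gates.shape[0], gates.shape[1]
    one = np.float32(1.0)
    dz_all = np.empty((T, B, 4 * H), np.float32)
    dh_next = np.zeros((B, H), np.float32)
    dc_next = np.zeros((B, H), np.float32)
    for t in range(T - 1, -1, -1):
        i = gates[t, :, :H]
        f = gates[t, :, H : 2 * H]
        g = gates[t, :, 2 * H : 3 * H]
        o = gates[t, :, 3 * H :]
        tc = tanh_cs[t]
        dh = dy_seq[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (one - tc * tc) + dc_next
        dz = dz_all[t]
        dz[:, :H] = dc * g * i * (one - i)
        dz[:, H : 2 * H] = dc * c_prev[t] * f * (one - f)
        dz[:, 2 * H : 3 * H] = dc * i * (one - g * g)
        dz[:, 3 * H :] = do * o * (one - o)
        dh_next = np.dot(dz, WhT)
        dc_next = dc * f
    return dz_all


class LSTM(Layer):
    """Single LSTM layer over (batch, time, features).

    Gates are computed with one fused matrix product per step in the order
    [input, forget, cell, output]; the forget-gate bias starts at 1, the
    standard trick that eases gradient flow early in training. With
    ``return_sequences`` the layer emits the hidden state at every step,
    otherwise only the final one.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = True):
        H = units
        self.units = H
        self.return_sequences = return_sequences
        self.Wx = Parameter(_glorot(rng, (n_in, 4 * H), n_in, H), decay=True)
        self.Wh = Parameter(_glorot(rng, (H, 4 * H), H, H), decay=True)
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0
        self.b = Parameter(b)

    def forward(self, x, training=False):
        B, T, D = x.shape
        H = self.units
        x = np.ascontiguousarray(x, dtype=self.Wx.data.dtype)
        self._x = x
        if _HAS_NUMBA and x.dtype == np.float32:
            xproj = np.ascontiguousarray(x @ self.Wx.data)
            (self._gates, self._c_prev, self._h_prev, self._c,
             self._tanh_c, hs) = _lstm_forward_kernel(
                xproj, self.Wh.data, self.b.data, H
            )
            self._hs = hs
            return hs if self.return_sequences else hs[:, -1].copy()
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._gates = np.empty((T, B, 4 * H))
        self._c_prev = np.empty((T, B, H))
        self._h_prev = np.empty((T, B, H))
        self._c = np.empty((T, B, H))
        self._tanh_c = np.empty((T, B, H))
        hs = np.empty((B, T, H))
        Wx, Wh, b = self.Wx.data, self.Wh.data, self.b.data
        # all input projections at once; recurrent part per step
        xproj = x @ Wx
        for t in range(T):
            z = xproj[:, t] + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            self._h_prev[t] = h
            self._c_prev[t] = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            self._gates[t] = np.concatenate([i, f, g, o], axis=1)
            self._c[t] = c
            self._tanh_c[t] = tc
            hs[:, t] = h
        self._hs = hs
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, dy):
        x = self._x
        B, T, D = x.shape
        H = self.units
        Wx, Wh = self.Wx.data, self.Wh.data
        if _HAS_NUMBA and x.dtype == np.float32:
            if self.return_sequences:
                dy_seq = np.ascontiguousarray(dy, dtype=np.float32)
            else:
                dy_seq = np.zeros((B, T, H), dtype=np.float32)
                dy_seq[:, -1] = dy
            dz_all = _lstm_backward_kernel(
                dy_seq, self._gates, self._c_prev, self._tanh_c,
                np.ascontiguousarray(Wh.T), H
            )
            dz_flat = dz_all.reshape(T * B, 4 * H)
            self.Wx.grad += x.transpose(1, 0, 2).reshape(T * B, D).T @ dz_flat
            self.Wh.grad += self._h_prev.reshape(T * B, H).T @ dz_flat
            self.b.grad += dz_flat.sum(axis=0)
            return np.einsum("tbh,dh->btd", dz_all, Wx, optimize=True)
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        if self.return_sequences:
            dy_seq = dy
        else:
            dy_seq = np.zeros((B, T, H))
            dy_seq[:, -1] = dy
        for t in range(T - 1, -1, -1):
            gates = self._gates[t]
            i, f = gates[:, :H], gates[:, H : 2 * H]
            g, o = gates[:, 2 * H : 3 * H], gates[:, 3 * H :]
            tc = self._tanh_c[t]
            dh = dy_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * self._c_prev[t]
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += self._h_prev[t].T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.Wx.grad += dWx
        self.Wh.grad += dWh
        self.b.grad += db
        return dx

    def params(self):
        return [self.Wx, self.Wh, self.b]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _same_pad(n: int, kernel: int, stride: int) -> tuple[int, int]:
    """Keras-style 'same' padding: output length ceil(n / stride)."""
    n_out = -(-n // stride)
    total = max((n_out - 1) * stride + kernel - n, 0)
    return total // 2, total - total // 2


class Conv1D(Layer):
    """1-D convolution over (batch, time, channels) with 'same' padding."""

    def __init__(self, n_in: int, filters: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1):
        self.kernel = kernel
        self.stride = stride
        fan_in, fan_out = kernel * n_in, kernel * filters
        self.W = Parameter(
            _glorot(rng, (kernel, n_in, filters), fan_in, fan_out), decay=True
        )
        self.b = Parameter(np.zeros(filters))

    def forward(self, x, training=False):
        B, T, C = x.shape
        k, s = self.kernel, self.stride
        pl, pr = _same_pad(T, k, s)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        T_out = -(-T // s)
        self._xp_shape = xp.shape
        self._xp = xp
        self._T = T
        self._pl = pl
        idx = np.arange(T_out) * s
        y = np.tile(self.b.data, (B, T_out, 1))
        for j in range(k):  # one matmul per kernel offset
            y += xp[:, idx + j, :] @ self.W.data[j]
        return y

    def backward(self, dy):
        B, T_out, F = dy.shape
        k, s = self.kernel, self.stride
        xp = self._xp
        dxp = np.zeros_like(xp)
        idx = np.arange(T_out) * s
        for j in range(k):
            xs = xp[:, idx + j, :]  # (B, T_out, C)
            self.W.grad[j] += np.einsum("btc,btf->cf", xs, dy)
            # indices idx+j are unique for fixed j, so fancy += accumulates once each
            dxp[:, idx + j, :] += dy @ self.W.data[j].T
        self.b.grad += dy.sum(axis=(0, 1))
        pl = self._pl
        return dxp[:, pl : pl + self._T, :]

    def params(self):
        return [self.W, self.b]


class Conv1DTranspose(Layer):
    """Length-upsampling transposed 1-D convolution (output time = input * stride).

    Implemented as zero-stuffing by the stride followed by a stride-1 'same'
    convolution, which is the standard equivalence.
    """

    def __init__(self, n_in: int, filters: int, kernel: int,
                 rng: np.random.Generator, stride: int = 2):
        self.stride = stride
        self.conv = Conv1D(n_in, filters, kernel, rng, stride=1)

    def forward(self, x, training=False):
        B, T, C = x.shape
        s = self.stride
        up = np.zeros((B, T * s, C))
        up[:, ::s] = x
        return self.conv.forward(up, training)

    def backward(self, dy):
        dup = self.conv.backward(dy)
        return dup[:, :: self.stride]

    def params(self):
        return self.conv.params()


class Conv2D(Layer):
    """2-D convolution over (batch, height, width, channels), 'same' padding."""

    def __init__(self, n_in: int, filters: int, kernel: tuple[int, int],
                 rng: np.random.Generator, stride: tuple[int, int] = (1, 1)):
        self.kernel = kernel
        self.stride = stride
        kh, kw = kernel
        fan_in, fan_out = kh * kw * n_in, kh * kw * filters
        self.W = Parameter(
            _glorot(rng, (kh, kw, n_in, filters), fan_in, fan_out), decay=True
        )
        self.b = Parameter(np.zeros(filters))

    def forward(self, x, training=False):
        B, H, W_, C = x.shape
        (kh, kw), (sh, sw) = self.kernel, self.stride
        pt, pb = _same_pad(H, kh, sh)
        pl, pr = _same_pad(W_, kw, sw)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        Ho, Wo = -(-H // sh), -(-W_ // sw)
        self._xp = xp
        self._pads = (pt, pl)
        self._in_shape = (H, W_)
        hi = np.arange(Ho) * sh
        wi = np.arange(Wo) * sw
        y = np.tile(self.b.data, (B, Ho, Wo, 1))
        for a in range(kh):
            for b_ in range(kw):
                patch = xp[:, hi[:, None] + a, wi[None, :] + b_, :]
                y += patch @ self.W.data[a, b_]
        return y

    def backward(self, dy):
        B, Ho, Wo, F = dy.shape
        (kh, kw), (sh, sw) = self.kernel, self.stride
        xp = self._xp
        dxp = np.zeros_like(xp)
        hi = np.arange(Ho) * sh
        wi = np.arange(Wo) * sw
        for a in range(kh):
            for b_ in range(kw):
                patch = xp[:, hi[:, None] + a, wi[None, :] + b_, :]
                self.W.grad[a, b_] += np.einsum("bhwc,bhwf->cf", patch, dy)
                dxp[:, hi[:, None] + a, wi[None, :] + b_, :] += dy @ self.W.data[a, b_].T
        self.b.grad += dy.sum(axis=(0, 1, 2))
        pt, pl = self._pads
        H, W_ = self._in_shape
        return dxp[:, pt : pt + H, pl : pl + W_, :]

    def params(self):
        return [self.W, self.b]


class Conv2DTranspose(Layer):
    """Transposed 2-D convolution: output spatial dims = input * stride."""

    def __init__(self, n_in: int, filters: int, kernel: tuple[int, int],
                 rng: np.random.Generator, stride: tuple[int, int] = (2, 2)):
        self.stride = stride
        self.conv = Conv2D(n_in, filters, kernel, rng, stride=(1, 1))

    def forward(self, x, training=False):
        B, H, W_, C = x.shape
        sh, sw = self.stride
        up = np.zeros((B, H * sh, W_ * sw, C))
        up[:, ::sh, ::sw] = x
        return self.conv.forward(up, training)

    def backward(self, dy):
        dup = self.conv.backward(dy)
        sh, sw = self.stride
        return dup[:, ::sh, ::sw]

    def params(self):
        return self.conv.params()


class BatchNorm(Layer):
    """Batch normalization over all axes except the last (feature) axis."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features, dtype=DEFAULT_DTYPE)
        self.running_var = np.ones(n_features, dtype=DEFAULT_DTYPE)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._xhat = xhat
        self._inv = inv
        self._training = training
        self._m = x.size // x.shape[-1]
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.data
        if not self._training:
            return dxhat * inv
        m = self._m
        return (
            inv / m
            * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        )

    def params(self):
        return [self.gamma, self.beta]


class Dropout(Layer):
    """Inverted dropout; identity at inference. Needs ``rng`` set before training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng not set")
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class ReLU(Layer):
    def forward(self, x, training=False):
        self._pos = x > 0
        return x * self._pos

    def backward(self, dy):
        return dy * self._pos


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = _sigmoid(x)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y * self._y)


class RepeatVector(Layer):
    """(batch, features) -> (batch, T, features) by tiling."""

    def __init__(self, T: int):
        self.T = T

    def forward(self, x, training=False):
        return np.repeat(x[:, None, :], self.T, axis=1)

    def backward(self, dy):
        return dy.sum(axis=1)


class TakeLast(Layer):
    """(batch, T, features) -> (batch, features): last time step."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x[:, -1]

    def backward(self, dy):
        dx = np.zeros(self._shape, dtype=dy.dtype)
        dx[:, -1] = dy
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x, training=False):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._T, axis=1) / self._T


class Reshape(Layer):
    """Reshape the non-batch dimensions."""

    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x, training=False):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._in)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Bidirectional(Layer):
    """Run two recurrent layers over the sequence, one in each time
    direction, and concatenate their features.

    Both sublayers must share the ``return_sequences`` mode; with sequences
    the backward layer's output is re-reversed so features align per stamp,
    with final-state mode the concatenated state summarizes the sequence
    from both ends.
    """

    def __init__(self, forward_layer: LSTM, backward_layer: LSTM):
        if forward_layer.return_sequences != backward_layer.return_sequences:
            raise ValueError("both directions must share return_sequences")
        self.fwd = forward_layer
        self.bwd = backward_layer
        self.return_sequences = forward_layer.return_sequences

    def forward(self, x, training=False):
        yf = self.fwd.forward(x, training)
        yb = self.bwd.forward(np.ascontiguousarray(x[:, ::-1]), training)
        if self.return_sequences:
            yb = yb[:, ::-1]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dy):
        H = self.fwd.units
        dyf = dy[..., :H]
        dyb = dy[..., H:]
        if self.return_sequences:
            dyb = np.ascontiguousarray(dyb[:, ::-1])
        dx = self.fwd.backward(np.ascontiguousarray(dyf))
        dx_b = self.bwd.backward(dyb)
        return dx + dx_b[:, ::-1]

    def params(self):
        return self.fwd.params() + self.bwd.params()


class GlobalContextConcat(Layer):
    """Concatenate each stamp's features with a global summary of the sequence.

    An encoder (any layer mapping (B, T, F) -> (B, H)) compresses the whole
    sequence to one latent vector, which is tiled across time and appended
    to the per-stamp features: output (B, T, F + H). This hands every time
    step acausal, segment-wide context while keeping local detail intact.
    """

    def __init__(self, encoder: Layer):
        self.encoder = encoder

    def forward(self, x, training=False):
        self._F = x.shape[-1]
        lat = self.encoder.forward(x, training)
        rep = np.repeat(lat[:, None, :], x.shape[1], axis=1)
        return np.concatenate([x, rep], axis=-1)

    def backward(self, dy):
        F = self._F
        dlat = dy[:, :, F:].sum(axis=1)
        return dy[:, :, :F] + self.encoder.backward(dlat)

    def params(self):
        return self.encoder.params()


class ResidualBlock1D(Layer):
    """One residual block of a 1-D ResNet: three conv+BN stages with ReLUs and
    an identity shortcut, projected by a 1x1 convolution exactly when the
    channel counts differ."""

    def __init__(self, n_in: int, filters: int, kernels: tuple[int, int, int],
                 rng: np.random.Generator):
        k1, k2, k3 = kernels
        self.body = Sequential(
            [
                Conv1D(n_in, filters, k1, rng),
                BatchNorm(filters),
                ReLU(),
                Conv1D(filters, filters, k2, rng),
                BatchNorm(filters),
                ReLU(),
                Conv1D(filters, filters, k3, rng),
                BatchNorm(filters),
            ]
        )
        if n_in != filters:
            self.shortcut: Layer | None = Sequential(
                [Conv1D(n_in, filters, 1, rng), BatchNorm(filters)]
            )
        else:
            self.shortcut = None
        self.out_relu = ReLU()

    def forward(self, x, training=False):
        y = self.body.forward(x, training)
        s = x if self.shortcut is None else self.shortcut.forward(x, training)
        return self.out_relu.forward(y + s, training)

    def backward(self, dy):
        dsum = self.out_relu.backward(dy)
        dx_body = self.body.backward(dsum)
        dx_short = dsum if self.shortcut is None else self.shortcut.backward(dsum)
        return dx_body + dx_short

    def params(self):
        ps = self.body.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every output entry, and its gradient."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff / diff.size


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=-1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.sum(onehot * np.log(p + 1e-12)) / n)
    return loss, (p - onehot) / n


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Optimization and training
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
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
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class EarlyStopper:
    """Stop once the monitored loss has failed to improve for ``patience``
    consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = math.inf
        self.best_epoch = -1
        self.bad = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record one epoch's monitored loss; return True to stop."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = epoch
            self.bad = 0
            return False
        self.bad += 1
        return self.bad >= self.patience


class NeuralNetwork:
    """A network plus its loss, optimizer settings and training loop."""

    def __init__(self, net: Layer, loss: str = "mse", seed: int = 0):
        if loss not in ("mse", "softmax_ce"):
            raise ValueError(f"unknown loss {loss!r}")
        self.net = net
        self.loss_name = loss
        self.rng = np.random.default_rng(seed)
        for layer in self._walk(net):
            if isinstance(layer, Dropout):
                layer.rng = self.rng

    @staticmethod
    def _walk(layer: Layer):
        yield layer
        for attr in ("layers",):
            for sub in getattr(layer, attr, []):
                yield from NeuralNetwork._walk(sub)
        for attr in ("body", "shortcut", "out_relu", "conv", "encoder", "fwd", "bwd"):
            sub = getattr(layer, attr, None)
            if isinstance(sub, Layer):
                yield from NeuralNetwork._walk(sub)

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[Parameter]:
        return self.net.params()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.data[...] = w

    # -- inference ----------------------------------------------------------
    def predict(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [
            self.net.forward(X[i : i + batch_size], training=False)
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def _loss_fn(self) -> Callable:
        return mse_loss if self.loss_name == "mse" else softmax_cross_entropy

    def evaluate(self, X: np.ndarray, Y: np.ndarray, batch_size: int = 64) -> float:
        loss_fn = self._loss_fn()
        total = 0.0
        for i in range(0, len(X), batch_size):
            xb, yb = X[i : i + batch_size], Y[i : i + batch_size]
            loss, _ = loss_fn(self.net.forward(xb, training=False), yb)
            total += loss * len(xb)
        return total / len(X)

    # -- training -----------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        X_val: np.ndarray,
        Y_val: np.ndarray,
        batch_size: int = 32,
        max_epochs: int = 500,
        patience: int = 20,
        lr: float = 1e-3,
        l1: float = 0.0,
        l2: float = 0.0,
        verbose: bool = False,
    ) -> dict[str, list[float]]:
        """Mini-batch Adam training with early stopping on validation loss.

        Returns the history {'train_loss': [...], 'val_loss': [...]}; on exit
        the network parameters are those of the best validation epoch.
        """
        loss_fn = self._loss_fn()
        dtype = self.params()[0].data.dtype if self.params() else DEFAULT_DTYPE
        X = np.ascontiguousarray(X, dtype=dtype)
        Y = np.ascontiguousarray(Y, dtype=dtype)
        X_val = np.ascontiguousarray(X_val, dtype=dtype)
        Y_val = np.ascontiguousarray(Y_val, dtype=dtype)
        opt = Adam(self.params(), lr=lr)
        stopper = EarlyStopper(patience)
        history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        best_weights = self.get_weights()
        n = len(X)
        for epoch in range(max_epochs):
            order = self.rng.permutation(n)
            total = 0.0
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                xb, yb = X[idx], Y[idx]
                opt.zero_grad()
                pred = self.net.forward(xb, training=True)
                loss, dloss = loss_fn(pred, yb)
                if not math.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss}"
                    )
                self.net.backward(dloss)
                if l1 or l2:
                    for p in opt.params:
                        if p.decay:
                            if l2:
                                p.grad += 2.0 * l2 * p.data
                            if l1:
                                p.grad += l1 * np.sign(p.data)
                opt.step()
                total += loss * len(idx)
            train_loss = total / n
            val_loss = self.evaluate(X_val, Y_val, batch_size)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if verbose:
                print(f"epoch {epoch + 1}: train {train_loss:.5f} val {val_loss:.5f}")
            if val_loss < stopper.best:
                best_weights = self.get_weights()
            if stopper.update(epoch, val_loss):
                break
        self.set_weights(best_weights)
        self.best_epoch = stopper.best_epoch
        return history
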