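"""Minimal neural-network layers on numpy with explicit backpropagation.

Everything needed by the head-map regressors: 2D convolution (stride 1,
'same' or 'valid' padding) via im2col and BLAS matmul, 2x2 max pooling,
dense, ReLU, inverted dropout, 1D convolution over feature sequences, and a
single-layer LSTM (standard form, optional diagonal peepholes).  Data layout
is channels-last: images are [N, H, W, C], sequences [N, T, D].

Each layer exposes ``params`` / ``grads`` (aligned lists of arrays),
``forward(x, training=False)`` and ``backward(dout)``; gradients accumulate
into ``grads`` and flow back through the return value.  All layers are
dtype-polymorphic (float32 for speed, float64 for numeric gradient checks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv2D", "MaxPool2D", "Dense", "ReLU", "Dropout", "Flatten",
           "Conv1D", "LSTM", "Sequential"]


class Layer:
    """Base class: parameterless identity."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """[N, H, W, C] -> [N, OH, OW, k*k*C] patch matrix (stride 1, valid)."""
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # N, OH, OW, C, k, k
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        x.shape[0], x.shape[1] - k + 1, x.shape[2] - k + 1, -1
    )


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride 1, 'same' (1-pixel zero pad) or 'valid'."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 padding: str = "same", rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * in_channels
        self.W = (rng.standard_normal((fan_in, out_channels)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.k = kernel
        self.pad = (kernel - 1) // 2 if padding == "same" else 0
        self.padding = padding
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad), (0, 0)))
        self._xp_shape = x.shape
        cols = _im2col(x, self.k)
        self._out_hw = cols.shape[1:3]
        self._cols = cols.reshape(-1, cols.shape[-1])
        y = self._cols @ self.W + self.b
        return y.reshape(x.shape[0], *self._out_hw, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N = dout.shape[0]
        oh, ow = self._out_hw
        flat = dout.reshape(-1, self.out_channels)
        self.grads[0] += self._cols.T @ flat
        self.grads[1] += flat.sum(axis=0)
        # input gradient by col2im: one matmul into patch space, then
        # scatter-add each of the k*k patch offsets back onto the padded image
        dcols = (flat @ self.W.T).reshape(N, oh, ow, self.k, self.k, self.in_channels)
        dxp = np.zeros(self._xp_shape, dtype=dout.dtype)
        for a in range(self.k):
            for b in range(self.k):
                dxp[:, a : a + oh, b : b + ow, :] += dcols[:, :, :, a, b, :]
        if self.pad:
            dxp = dxp[:, self.pad : -self.pad, self.pad : -self.pad, :]
        return dxp


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2; odd extents are 'same'-padded with -inf."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.p = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p = self.p
        N, H, W, C = x.shape
        ph, pw = (-H) % p, (-W) % p
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), constant_values=-np.inf)
        self._in_shape = (N, H, W, C)
        H2, W2 = x.shape[1] // p, x.shape[2] // p
        xt = x.reshape(N, H2, p, W2, p, C).transpose(0, 1, 3, 5, 2, 4).reshape(N, H2, W2, C, p * p)
        self._argmax = xt.argmax(axis=-1)
        return xt.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self.p
        N, H, W, C = self._in_shape
        H2, W2 = dout.shape[1], dout.shape[2]
        scat = np.zeros((N, H2, W2, C, p * p), dtype=dout.dtype)
        np.put_along_axis(scat, self._argmax[..., None], dout[..., None], axis=-1)
        dx = scat.reshape(N, H2, W2, C, p, p).transpose(0, 1, 4, 2, 5, 3).reshape(N, H2 * p, W2 * p, C)
        return dx[:, :H, :W, :]


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = rng.uniform(-limit, limit, (in_dim, out_dim)).astype(dtype)
        self.b = np.zeros(out_dim, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ dout
        self.grads[1] += dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; active only when ``training=True``."""

    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Conv1D(Layer):
    """1D convolution over a [N, T, C] sequence, stride 1, valid padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = kernel * in_channels
        self.W = (rng.standard_normal((fan_in, out_channels)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.k = kernel
        self.in_channels, self.out_channels = in_channels, out_channels

    def _cols(self, x: np.ndarray) -> np.ndarray:
        win = sliding_window_view(x, self.k, axis=1)  # N, OT, C, k
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], x.shape[1] - self.k + 1, -1
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] < self.k:
            raise ValueError(f"sequence length {x.shape[1]} shorter than kernel {self.k}")
        self._x = x
        cols = self._cols(x)
        y = cols.reshape(-1, cols.shape[-1]) @ self.W + self.b
        return y.reshape(x.shape[0], -1, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        flat = dout.reshape(-1, self.out_channels)
        cols = self._cols(self._x).reshape(-1, self.k * self.in_channels)
        self.grads[0] += cols.T @ flat
        self.grads[1] += flat.sum(axis=0)
        W3 = self.W.reshape(self.k, self.in_channels, self.out_channels)
        Wf = np.ascontiguousarray(W3[::-1].transpose(0, 2, 1)).reshape(-1, self.in_channels)
        p = self.k - 1
        dpad = np.pad(dout, ((0, 0), (p, p), (0, 0)))
        win = sliding_window_view(dpad, self.k, axis=1)
        cols_b = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(-1, self.k * self.out_channels)
        return (cols_b @ Wf).reshape(self._x.shape)


class LSTM(Layer):
    """Single-layer LSTM returning the last hidden state.

    Gates (order i, f, g, o):

        i_t = sigmoid(W_xi x_t + W_hi h_{t-1} [+ p_i . c_{t-1}] + b_i)
        f_t = sigmoid(W_xf x_t + W_hf h_{t-1} [+ p_f . c_{t-1}] + b_f)
        c_t = f_t c_{t-1} + i_t tanh(W_xc x_t + W_hc h_{t-1} + b_c)
        o_t = sigmoid(W_xo x_t + W_ho h_{t-1} [+ p_o . c_t] + b_o)
        h_t = o_t tanh(c_t)

    The bracketed diagonal peephole terms are enabled by ``peephole=True``;
    the default is the common framework form without them.  The forget-gate
    bias starts at 1.
    """

    def __init__(self, in_dim: int, units: int, peephole: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        lim_w = np.sqrt(6.0 / (in_dim + 4 * units))
        lim_u = np.sqrt(6.0 / (units + 4 * units))
        self.W = rng.uniform(-lim_w, lim_w, (in_dim, 4 * units)).astype(dtype)
        self.U = rng.uniform(-lim_u, lim_u, (units, 4 * units)).astype(dtype)
        self.b = np.zeros(4 * units, dtype=dtype)
        self.b[units : 2 * units] = 1.0  # forget-gate bias
        self.params = [self.W, self.U, self.b]
        if peephole:
            self.p_i = np.zeros(units, dtype=dtype)
            self.p_f = np.zeros(units, dtype=dtype)
            self.p_o = np.zeros(units, dtype=dtype)
            self.params += [self.p_i, self.p_f, self.p_o]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.units = units
        self.in_dim = in_dim
        self.peephole = peephole

    @staticmethod
    def _sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, T, _ = x.shape
        H = self.units
        h = np.zeros((N, H), dtype=x.dtype)
        c = np.zeros((N, H), dtype=x.dtype)
        self._x = x
        self._cache = []
        for t in range(T):
            pre = x[:, t] @ self.W + h @ self.U + self.b
            if self.peephole:
                pre[:, :H] += c * self.p_i
                pre[:, H : 2 * H] += c * self.p_f
            i = self._sigmoid(pre[:, :H])
            f = self._sigmoid(pre[:, H : 2 * H])
            g = np.tanh(pre[:, 2 * H : 3 * H])
            c_new = f * c + i * g
            pre_o = pre[:, 3 * H :]
            if self.peephole:
                pre_o = pre_o + c_new * self.p_o
            o = self._sigmoid(pre_o)
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, c_new, tanh_c))
            h, c = h_new, c_new
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        N, T, _ = self._x.shape
        H = self.units
        dx = np.zeros_like(self._x)
        dh = dh_last.astype(self._x.dtype)
        dc = np.zeros((N, H), dtype=self._x.dtype)
        dW, dU, db = self.grads[0], self.grads[1], self.grads[2]
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, c_new, tanh_c = self._cache[t]
            do = dh * tanh_c * o * (1 - o)
            dc = dc + dh * o * (1 - tanh_c**2)
            if self.peephole:
                self.grads[5] += (do * c_new).sum(axis=0)  # p_o
                dc = dc + do * self.p_o
            di = dc * g * i * (1 - i)
            df = dc * c_prev * f * (1 - f)
            dg = dc * i * (1 - g**2)
            dgates = np.concatenate([di, df, dg, do], axis=1)
            dW += self._x[:, t].T @ dgates
            dU += h_prev.T @ dgates
            db += dgates.sum(axis=0)
            dc_prev = dc * f
            if self.peephole:
                self.grads[3] += (di * c_prev).sum(axis=0)  # p_i
                self.grads[4] += (df * c_prev).sum(axis=0)  # p_f
                dc_prev = dc_prev + di * self.p_i + df * self.p_f
            dx[:, t] = dgates @ self.W.T
            dh = dgates @ self.U.T
            dc = dc_prev
        return dx


class Sequential(Layer):
    """A stack of layers applied in order; params/grads aggregate over layers."""

    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:  # type: ignore[override]
        return [p for lay in self.layers for p in lay.params]

    @params.setter
    def params(self, value) -> None:  # base-class __init__ compatibility
        if value:
            raise AttributeError("Sequential params are derived from its layers")

    @property
    def grads(self) -> list[np.ndarray]:  # type: ignore[override]
        return [g for lay in self.layers for g in lay.grads]

    @grads.setter
    def grads(self, value) -> None:
        if value:
            raise AttributeError("Sequential grads are derived from its layers")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout
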