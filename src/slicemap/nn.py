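"""Minimal seeded neural-network layers on numpy.

Implements exactly the pieces the slice-map classifiers need: dense,
2D/1D convolution (im2col + BLAS matmul), non-overlapping max pooling,
ReLU, inverted dropout, last-state LSTM/GRU recurrences, and Adam.
Every layer carries its own parameters and analytic gradients; the test
suite checks each backward pass against central finite differences.

Conventions
-----------
* Batches lead: 2D conv tensors are ``(N, C, H, W)``, 1D conv tensors
  ``(N, C, L)``, recurrent inputs ``(N, T, D)``.
* ``forward`` caches whatever ``backward`` needs; ``backward`` takes the
  gradient w.r.t. its output and returns the gradient w.r.t. its input
  (``None`` when the layer was told the input gradient is not needed,
  e.g. the first layer of a network whose input is data).
* Weight initialisation is Glorot-uniform from a caller-supplied
  ``numpy.random.Generator`` so a seed fully determines the network.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit as sigmoid

__all__ = [
    "Param",
    "Dense",
    "ReLU",
    "Dropout",
    "Flatten",
    "Conv2D",
    "MaxPool2D",
    "Conv1D",
    "MaxPool1D",
    "LSTMLast",
    "GRULast",
    "Adam",
    "sigmoid",
]


class Param:
    """A trainable array with its accumulated gradient.

    ``is_weight`` marks multiplicative parameters (subject to L2 decay);
    biases and gains are excluded from the penalty.
    """

    __slots__ = ("value", "grad", "is_weight", "name")

    def __init__(self, value: np.ndarray, *, is_weight: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.is_weight = is_weight
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: stateless unless it owns ``Param``s."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray, need_input_grad: bool = True):  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        self.W = Param(glorot(rng, (n_in, n_out), n_in, n_out), name=f"{name}.W")
        self.b = Param(np.zeros(n_out), is_weight=False, name=f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout, need_input_grad=True):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T if need_input_grad else None


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout, need_input_grad=True):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout, need_input_grad=True):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, need_input_grad=True):
        return dout.reshape(self._shape)


# ---------------------------------------------------------------------------
# convolution helpers


def _conv2d_cols(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, OH, OW, C, kh, kw) view."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N, C, OH', OW', kh, kw)
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray | None, stride: int = 1):
    """'Same'-padded 2D convolution. W: (C, kh, kw, F)."""
    C, kh, kw, F = W.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _conv2d_cols(xp, kh, kw, stride)  # (N, OH, OW, C, kh, kw)
    N, OH, OW = cols.shape[:3]
    y = cols.reshape(N * OH * OW, C * kh * kw) @ W.reshape(C * kh * kw, F)
    if b is not None:
        y += b
    y = y.reshape(N, OH, OW, F).transpose(0, 3, 1, 2)
    return y, (cols, xp.shape)


class Conv2D(Layer):
    """Same-padded 2D convolution over (N, C, H, W)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, name: str = "conv2d"):
        fan_in, fan_out = c_in * k * k, c_out * k * k
        self.W = Param(glorot(rng, (c_in, k, k, c_out), fan_in, fan_out), name=f"{name}.W")
        self.b = Param(np.zeros(c_out), is_weight=False, name=f"{name}.b")
        self.k, self.stride = k, stride

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        y, (cols, xp_shape) = conv2d_forward(x, self.W.value, self.b.value, self.stride)
        self._cols, self._xp_shape = cols, xp_shape
        return y

    def backward(self, dout, need_input_grad=True):
        C, k, _, F = self.W.value.shape
        N, _, OH, OW = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(N * OH * OW, F)
        self.W.grad += (self._cols.reshape(N * OH * OW, C * k * k).T @ dflat).reshape(self.W.value.shape)
        self.b.grad += dflat.sum(axis=0)
        if not need_input_grad:
            return None
        dcols = (dflat @ self.W.value.reshape(C * k * k, F).T).reshape(N, OH, OW, C, k, k)
        dxp = np.zeros(self._xp_shape)
        s = self.stride
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * OH:s, j:j + s * OW:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        p = k // 2
        H, W_ = self._xp_shape[2] - 2 * p, self._xp_shape[3] - 2 * p
        return dxp[:, :, p:p + H, p:p + W_]


class MaxPool2D(Layer):
    """Non-overlapping pooling; trailing remainder rows/cols are dropped."""

    def __init__(self, pool: int = 2):
        self.p = pool

    def forward(self, x, train=False):
        p = self.p
        N, C, H, W = x.shape
        OH, OW = H // p, W // p
        xt = x[:, :, :OH * p, :OW * p].reshape(N, C, OH, p, OW, p)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, OH, OW, p * p)
        self._arg = xt.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout, need_input_grad=True):
        p = self.p
        N, C, OH, OW = dout.shape
        dxt = np.zeros((N, C, OH, OW, p * p))
        np.put_along_axis(dxt, self._arg[..., None], dout[..., None], axis=-1)
        dxt = dxt.reshape(N, C, OH, OW, p, p).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, OH * p, OW * p)
        dx = np.zeros(self._in_shape)
        dx[:, :, :OH * p, :OW * p] = dxt
        return dx


class Conv1D(Layer):
    """Same-padded 1D convolution over (N, C, L)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, name: str = "conv1d"):
        fan_in, fan_out = c_in * k, c_out * k
        self.W = Param(glorot(rng, (c_in, k, c_out), fan_in, fan_out), name=f"{name}.W")
        self.b = Param(np.zeros(c_out), is_weight=False, name=f"{name}.b")
        self.k, self.stride = k, stride

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        k, s = self.k, self.stride
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, k, axis=2)[:, :, ::s]  # (N, C, OL, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3))  # (N, OL, C, k)
        N, OL = cols.shape[:2]
        C, _, F = self.W.value.shape
        y = cols.reshape(N * OL, C * k) @ self.W.value.reshape(C * k, F) + self.b.value
        self._cols, self._xp_len, self._in_len = cols, xp.shape[2], x.shape[2]
        return y.reshape(N, OL, F).transpose(0, 2, 1)

    def backward(self, dout, need_input_grad=True):
        C, k, F = self.W.value.shape
        N, _, OL = dout.shape
        dflat = dout.transpose(0, 2, 1).reshape(N * OL, F)
        self.W.grad += (self._cols.reshape(N * OL, C * k).T @ dflat).reshape(self.W.value.shape)
        self.b.grad += dflat.sum(axis=0)
        if not need_input_grad:
            return None
        dcols = (dflat @ self.W.value.reshape(C * k, F).T).reshape(N, OL, C, k)
        dxp = np.zeros((N, C, self._xp_len))
        s = self.stride
        for i in range(k):
            dxp[:, :, i:i + s * OL:s] += dcols[:, :, :, i].transpose(0, 2, 1)
        p = k // 2
        return dxp[:, :, p:p + self._in_len]


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        self.p = pool

    def forward(self, x, train=False):
        p = self.p
        N, C, L = x.shape
        OL = L // p
        xt = x[:, :, :OL * p].reshape(N, C, OL, p)
        self._arg = xt.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout, need_input_grad=True):
        p = self.p
        N, C, OL = dout.shape
        dxt = np.zeros((N, C, OL, p))
        np.put_along_axis(dxt, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape)
        dx[:, :, :OL * p] = dxt.reshape(N, C, OL * p)
        return dx


# ---------------------------------------------------------------------------
# recurrences (return the final hidden state only)


class LSTMLast(Layer):
    """Single LSTM layer over (N, T, D); output is h_T (N, H).

    Gate order inside the fused weight matrices is (input, forget, cell,
    output). The forget-gate bias starts at 1 — the standard trick that
    keeps gradients alive over the ~200-step slice sequence.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator, name: str = "lstm"):
        H = n_hidden
        self.Wx = Param(glorot(rng, (n_in, 4 * H), n_in + H, 4 * H), name=f"{name}.Wx")
        self.Wh = Param(glorot(rng, (H, 4 * H), n_in + H, 4 * H), name=f"{name}.Wh")
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0
        self.b = Param(b, is_weight=False, name=f"{name}.b")
        self.H = H

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train=False):
        N, T, D = x.shape
        H = self.H
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        self._x = x
        self._cache = []
        for t in range(T):
            a = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
        return h

    def backward(self, dout, need_input_grad=True):
        x = self._x
        N, T, D = x.shape
        H = self.H
        dh, dc = dout, np.zeros_like(dout)
        dx = np.zeros_like(x) if need_input_grad else None
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dct = dh * o * (1.0 - tc * tc) + dc
            di, df, dg = dct * g, dct * c_prev, dct * i
            dc = dct * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1)
            self.Wx.grad += x[:, t].T @ da
            self.Wh.grad += h_prev.T @ da
            self.b.grad += da.sum(axis=0)
            if need_input_grad:
                dx[:, t] = da @ self.Wx.value.T
            dh = da @ self.Wh.value.T
        return dx


class GRULast(Layer):
    """Single GRU layer over (N, T, D); output is h_T (N, H).

    h' = (1 - z) * n + z * h with update z, reset r and candidate
    n = tanh(x Wn + (r * h) Un + bn).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator, name: str = "gru"):
        H = n_hidden
        self.Wx = Param(glorot(rng, (n_in, 3 * H), n_in + H, 3 * H), name=f"{name}.Wx")
        self.Wh = Param(glorot(rng, (H, 3 * H), n_in + H, 3 * H), name=f"{name}.Wh")
        self.b = Param(np.zeros(3 * H), is_weight=False, name=f"{name}.b")
        self.H = H

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train=False):
        N, T, D = x.shape
        H = self.H
        h = np.zeros((N, H))
        self._x = x
        self._cache = []
        Wx, Wh, b = self.Wx.value, self.Wh.value, self.b.value
        for t in range(T):
            ax = x[:, t] @ Wx + b
            ah = h @ Wh
            z = sigmoid(ax[:, :H] + ah[:, :H])
            r = sigmoid(ax[:, H:2 * H] + ah[:, H:2 * H])
            n = np.tanh(ax[:, 2 * H:] + r * ah[:, 2 * H:])
            self._cache.append((h, z, r, n, ah[:, 2 * H:]))
            h = (1 - z) * n + z * h
        return h

    def backward(self, dout, need_input_grad=True):
        x = self._x
        N, T, D = x.shape
        H = self.H
        dh = dout
        dx = np.zeros_like(x) if need_input_grad else None
        for t in range(T - 1, -1, -1):
            h_prev, z, r, n, ahn = self._cache[t]
            dn = dh * (1 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            dan = dn * (1 - n * n)           # grad at candidate pre-activation
            dahn = dan * r                    # through (r * h Un)
            dr = dan * ahn
            daz = dz * z * (1 - z)
            dar = dr * r * (1 - r)
            da_x = np.concatenate([daz, dar, dan], axis=1)
            da_h = np.concatenate([daz, dar, dahn], axis=1)
            self.Wx.grad += x[:, t].T @ da_x
            self.Wh.grad += h_prev.T @ da_h
            self.b.grad += da_x.sum(axis=0)
            if need_input_grad:
                dx[:, t] = da_x @ self.Wx.value.T
            dh = dh_prev + da_h @ self.Wh.value.T
        return dx


class Adam:
    """Adam with the usual bias correction; one state slot per Param."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
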