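"""Minimal numpy neural-network layers with explicit backpropagation.

Everything the localization model needs — LSTM / bidirectional LSTM,
2-D convolution (cross-correlation, valid padding), max-pooling, dense
layers, ReLU — implemented directly on numpy arrays with hand-derived
gradients.  Layers cache what forward() needs for backward(); parameters are
``Param`` objects carrying ``value`` and ``grad`` so an optimizer can walk a
flat parameter list.

Conventions: batches first.  Sequence input is (N, T, D); image-like input
to the convolution stack is (N, C, H, W).  Compute dtype is whatever the
parameters were built with (float32 by default at the model level; float64
for gradient checking).  Large scratch arrays are cached per layer and
reused across mini-batches, which matters on a single CPU: repeatedly
faulting in fresh hundred-megabyte allocations costs more than the matrix
math itself.
"""

from __future__ import annotations

import numpy as np

from sublocnet.errors import ValidationError
from sublocnet.nn_kernels import (
    col2im_accumulate,
    im2col,
    lstm_backward_steps,
    lstm_forward_steps,
    maxpool_backward,
    maxpool_forward,
    relu_backward_inplace,
    relu_forward_inplace,
)

__all__ = [
    "Param",
    "sigmoid",
    "Dense",
    "ReLU",
    "Flatten",
    "Conv2D",
    "MaxPool2D",
    "LSTM",
    "BiLSTM",
    "Adam",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray, dtype=np.float64):
        self.value = np.asarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def sigmoid(x):
    """Numerically stable logistic function, elementwise.

    Computed as 1 / (1 + exp(-x)); the exp overflow for very negative x
    saturates cleanly to 0, so the result is exact at both tails.
    """
    x = np.asarray(x)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-x))
    if out.ndim == 0:
        return float(out)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _BufferCache:
    """Reusable scratch arrays keyed by name (shapes are stable across batches)."""

    __slots__ = ("_store",)

    def __init__(self) -> None:
        self._store: dict[str, np.ndarray] = {}

    def get(self, name: str, shape: tuple[int, ...], dtype) -> np.ndarray:
        buf = self._store.get(name)
        if buf is None or buf.shape != shape or buf.dtype != dtype:
            buf = np.empty(shape, dtype=dtype)
            self._store[name] = buf
        return buf

    def zeros(self, name: str, shape: tuple[int, ...], dtype) -> np.ndarray:
        buf = self.get(name, shape, dtype)
        buf[...] = 0
        return buf


class Dense:
    """Affine map x @ W + b on the trailing axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, dtype=np.float64):
        self.W = Param(_glorot(rng, (in_dim, out_dim), in_dim, out_dim), dtype)
        self.b = Param(np.zeros(out_dim), dtype)
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.reshape(-1, x.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
        self.b.grad += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        return dout @ self.W.value.T


class ReLU:
    """Rectifier applied in place when the input is contiguous (it always is
    between our conv/pool layers, whose outputs are reusable buffers)."""

    params: list[Param] = []

    def __init__(self) -> None:
        self._mask: np.ndarray | None = None
        self._bufs = _BufferCache()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.flags.c_contiguous:
            mask = self._bufs.get("mask", (x.size,), np.int8)
            relu_forward_inplace(x.reshape(-1), mask)
            self._mask = mask
            return x
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is not None and self._mask.dtype == np.int8:
            dout = np.ascontiguousarray(dout)
            relu_backward_inplace(dout.reshape(-1), self._mask)
            return dout
        return np.where(self._mask, dout, 0)


class Flatten:
    params: list[Param] = []

    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Conv2D:
    """Valid 2-D cross-correlation on channel-last input:
    out[n,i,j,f] = sum_c,m,k w[f,c,m,k] x[n,i+m,j+k,c] + b[f].

    Internally im2col: the sliding-window patch matrix is copied once per
    forward pass into a reusable buffer, then both the forward map and the
    kernel gradient are plain matrix products against it.  Layout is NHWC
    throughout, so the (rows, F) product of the forward pass *is* the output
    and no transposition is ever needed.  ``needs_input_grad=False`` (for a
    first layer reading raw data) skips the input-gradient scatter.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: tuple[int, int],
        rng: np.random.Generator,
        dtype=np.float64,
        needs_input_grad: bool = True,
    ):
        kh, kw = kernel_size
        fan_in = in_channels * kh * kw
        # He-uniform: preserves activation variance through the ReLU that
        # follows every convolution layer
        limit = np.sqrt(6.0 / fan_in)
        self.W = Param(rng.uniform(-limit, limit, size=(out_channels, in_channels, kh, kw)), dtype)
        self.b = Param(np.zeros(out_channels), dtype)
        self.kernel_size = (kh, kw)
        self.dtype = dtype
        self.needs_input_grad = needs_input_grad
        self._bufs = _BufferCache()
        self._in_shape: tuple[int, ...] | None = None
        self._out_hw: tuple[int, int] | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.kernel_size
        return h - kh + 1, w - kw + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel_size
        n, h, w, c = x.shape
        if h < kh or w < kw:
            raise ValidationError(
                f"kernel {self.kernel_size} larger than input {(h, w)}"
            )
        ho, wo = h - kh + 1, w - kw + 1
        self._in_shape = x.shape
        self._out_hw = (ho, wo)
        f = self.W.value.shape[0]
        cols = self._bufs.get("cols", (n * ho * wo, c * kh * kw), self.dtype)
        im2col(np.ascontiguousarray(x, dtype=self.dtype), kh, kw, cols)
        out = self._bufs.get("out", (n, ho, wo, f), self.dtype)
        np.matmul(cols, self.W.value.reshape(f, -1).T, out=out.reshape(n * ho * wo, f))
        out += self.b.value
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel_size
        n, h, w, c = self._in_shape
        ho, wo = self._out_hw
        f = dout.shape[-1]
        cols = self._bufs.get("cols", (n * ho * wo, c * kh * kw), self.dtype)
        dout_mat = np.ascontiguousarray(dout, dtype=self.dtype).reshape(n * ho * wo, f)
        self.W.grad += (dout_mat.T @ cols).reshape(self.W.value.shape)
        self.b.grad += dout_mat.sum(axis=0)
        if not self.needs_input_grad:
            return self._bufs.zeros("dx0", self._in_shape, self.dtype)
        dcols = self._bufs.get("dcols", (n * ho * wo, c * kh * kw), self.dtype)
        np.matmul(dout_mat, self.W.value.reshape(f, -1), out=dcols)
        dx = self._bufs.get("dx", (n, h, w, c), self.dtype)
        col2im_accumulate(dcols, kh, kw, dx)
        return dx


class MaxPool2D:
    """Non-overlapping max pooling on channel-last (N,H,W,C) input; trailing
    rows/cols that don't fill a window are dropped.  On ties the first
    maximum in row-major window order receives the gradient.
    """

    params: list[Param] = []

    def __init__(self, pool_size: tuple[int, int]):
        self.pool_size = pool_size
        self._bufs = _BufferCache()
        self._in_shape: tuple[int, ...] | None = None

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        return h // self.pool_size[0], w // self.pool_size[1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        ph, pw = self.pool_size
        n, h, w, c = x.shape
        ho, wo = h // ph, w // pw
        if ho < 1 or wo < 1:
            raise ValidationError(f"pool {self.pool_size} larger than input {(h, w)}")
        self._in_shape = x.shape
        dt = x.dtype
        out = self._bufs.get("out", (n, ho, wo, c), dt)
        arg = self._bufs.get("arg", (n, ho, wo, c), np.int32)
        maxpool_forward(np.ascontiguousarray(x), ph, pw, out, arg)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ph, pw = self.pool_size
        n, h, w, c = self._in_shape
        ho, wo = h // ph, w // pw
        dt = dout.dtype
        arg = self._bufs.get("arg", (n, ho, wo, c), np.int32)
        dx = self._bufs.get("dx", (n, h, w, c), dt)
        maxpool_backward(np.ascontiguousarray(dout, dtype=dt), arg, ph, pw, dx)
        return dx


class LSTM:
    """Single-direction LSTM over (N, T, D) input, returning all hidden states.

    Gate order in the packed weight matrices is [input, forget, output, cell
    candidate] so one sigmoid call covers the first three gates as a
    contiguous slice.  The recurrence follows the standard formulation: the
    input, forget and output coefficients are logistic functions of
    [h_{t-1}, x_t], the candidate cell state is a tanh of the same, the cell
    state mixes the old state (forget gate) with the candidate (input gate),
    and the output is the output gate times tanh of the cell state — so
    every emitted hidden value lies strictly inside (-1, 1).
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, dtype=np.float64):
        self.in_dim = in_dim
        self.hidden = hidden
        self.dtype = dtype
        h4 = 4 * hidden
        self.Wx = Param(_glorot(rng, (in_dim, h4), in_dim + hidden, h4), dtype)
        self.Wh = Param(_glorot(rng, (hidden, h4), in_dim + hidden, h4), dtype)
        self.b = Param(np.zeros(h4), dtype)
        self._bufs = _BufferCache()

    @property
    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, t, d = x.shape
        hdim = self.hidden
        xb = self._bufs.get("x", (n, t, d), self.dtype)
        xb[...] = x
        pre = self._bufs.get("pre", (n, t, 4 * hdim), self.dtype)
        np.matmul(xb.reshape(n * t, d), self.Wx.value, out=pre.reshape(n * t, 4 * hdim))
        pre += self.b.value
        gates = self._bufs.get("gates", (t, n, 4 * hdim), self.dtype)  # [i,f,o,g] activated
        c_s = self._bufs.get("c", (t, n, hdim), self.dtype)
        tc_s = self._bufs.get("tc", (t, n, hdim), self.dtype)
        out = self._bufs.get("h", (n, t, hdim), self.dtype)
        lstm_forward_steps(pre, np.ascontiguousarray(self.Wh.value), gates, c_s, tc_s, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        hdim = self.hidden
        gates = self._bufs._store["gates"]
        c_s = self._bufs._store["c"]
        tc_s = self._bufs._store["tc"]
        out = self._bufs._store["h"]
        x = self._bufs._store["x"]
        n, t, d = x.shape
        dout = np.ascontiguousarray(dout, dtype=self.dtype)
        dA = self._bufs.get("dA", (n, t, 4 * hdim), self.dtype)
        lstm_backward_steps(
            dout, np.ascontiguousarray(self.Wh.value.T), gates, c_s, tc_s, dA
        )
        dA_mat = dA.reshape(n * t, 4 * hdim)
        # weight gradients as single contractions over all timesteps
        h_prev = self._bufs.get("hprev", (n, t, hdim), self.dtype)
        h_prev[:, 0] = 0
        h_prev[:, 1:] = out[:, :-1]
        self.Wx.grad += x.reshape(n * t, d).T @ dA_mat
        self.Wh.grad += h_prev.reshape(n * t, hdim).T @ dA_mat
        self.b.grad += dA_mat.sum(axis=0)
        dx = self._bufs.get("dx", (n, t, d), self.dtype)
        np.matmul(dA_mat, self.Wx.value.T, out=dx.reshape(n * t, d))
        return dx


class BiLSTM:
    """Bidirectional LSTM: per-position concatenation of both directions' states."""

    def __init__(self, in_dim: int, hidden_per_direction: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.fwd = LSTM(in_dim, hidden_per_direction, rng, dtype)
        self.bwd = LSTM(in_dim, hidden_per_direction, rng, dtype)
        self.hidden_per_direction = hidden_per_direction
        self.dtype = dtype
        self._bufs = _BufferCache()

    @property
    def params(self) -> list[Param]:
        return self.fwd.params + self.bwd.params

    def forward(self, x: np.ndarray) -> np.ndarray:
        hdim = self.hidden_per_direction
        n, t, _ = x.shape
        out_f = self.fwd.forward(x)
        out_b = self.bwd.forward(x[:, ::-1])
        cat = self._bufs.get("cat", (n, t, 2 * hdim), out_f.dtype)
        cat[:, :, :hdim] = out_f
        cat[:, :, hdim:] = out_b[:, ::-1]
        return cat

    def backward(self, dout: np.ndarray) -> np.ndarray:
        hdim = self.hidden_per_direction
        dx = self.fwd.backward(np.ascontiguousarray(dout[:, :, :hdim], dtype=self.dtype))
        dx_b = self.bwd.backward(np.ascontiguousarray(dout[:, ::-1, hdim:], dtype=self.dtype))
        dx += dx_b[:, ::-1]
        return dx


class Adam:
    """Adam optimizer over a flat list of Params."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
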