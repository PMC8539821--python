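"""Compiled inner loops for the LSTM recurrence.

The LSTM's per-timestep work is tiny (a 4H-wide gate block per batch row),
so in pure numpy the 400-step Python loop is dominated by interpreter and
allocation overhead rather than arithmetic.  These numba kernels run the
strictly sequential part of the recurrence — gate activation and state
propagation — inside compiled loops; everything that can be batched over
time (input projections, weight-gradient contractions) stays outside as one
large BLAS call per sequence.

Gate layout in the packed 4H axis: [input, forget, output, cell candidate].
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "lstm_forward_steps",
    "lstm_backward_steps",
    "im2col",
    "col2im_accumulate",
    "maxpool_forward",
    "maxpool_backward",
    "relu_forward_inplace",
    "relu_backward_inplace",
]


@njit(cache=True)
def lstm_forward_steps(pre, Wh, gates, c_s, tc_s, out):
    """Run the recurrence; mutates gates (T,N,4H), c_s/tc_s (T,N,H), out (N,T,H).

    ``pre`` is the precomputed input projection x @ Wx + b, shape (N, T, 4H).
    """
    n, t_len, h4 = pre.shape
    hdim = h4 // 4
    h3 = 3 * hdim
    h = np.zeros((n, hdim), dtype=pre.dtype)
    c = np.zeros((n, hdim), dtype=pre.dtype)
    for t in range(t_len):
        a = np.dot(h, Wh)
        for i in range(n):
            for j in range(h4):
                v = a[i, j] + pre[i, t, j]
                if j < h3:
                    gates[t, i, j] = 1.0 / (1.0 + math.exp(-v))
                else:
                    gates[t, i, j] = math.tanh(v)
        for i in range(n):
            for j in range(hdim):
                cv = gates[t, i, hdim + j] * c[i, j] + gates[t, i, j] * gates[t, i, h3 + j]
                tc = math.tanh(cv)
                c[i, j] = cv
                c_s[t, i, j] = cv
                tc_s[t, i, j] = tc
                h[i, j] = gates[t, i, 2 * hdim + j] * tc
                out[i, t, j] = h[i, j]


@njit(cache=True)
def relu_forward_inplace(x_flat, mask_flat):
    """Clamp negatives to zero in place, recording the pass-through mask."""
    for i in range(x_flat.size):
        if x_flat[i] > 0:
            mask_flat[i] = 1
        else:
            mask_flat[i] = 0
            x_flat[i] = 0.0


@njit(cache=True)
def relu_backward_inplace(d_flat, mask_flat):
    for i in range(d_flat.size):
        if mask_flat[i] == 0:
            d_flat[i] = 0.0


@njit(cache=True)
def im2col(x, kh, kw, cols):
    """Gather sliding-window patches: x (N,H,W,C) -> cols (N*H'*W', C*kh*kw).

    Column order is (channel, kernel row, kernel col), matching a reshape of
    weights stored as (F, C, kh, kw).
    """
    n, h, w, c = x.shape
    ho = h - kh + 1
    wo = w - kw + 1
    for b in range(n):
        for i in range(ho):
            for j in range(wo):
                row = (b * ho + i) * wo + j
                for ch in range(c):
                    for m in range(kh):
                        for k in range(kw):
                            cols[row, (ch * kh + m) * kw + k] = x[b, i + m, j + k, ch]


@njit(cache=True)
def col2im_accumulate(dcols, kh, kw, dx):
    """Scatter-add patch gradients back: dcols (N*H'*W', C*kh*kw) -> dx (N,H,W,C)."""
    n, h, w, c = dx.shape
    ho = h - kh + 1
    wo = w - kw + 1
    for b in range(n):
        for i in range(h):
            for j in range(w):
                for ch in range(c):
                    dx[b, i, j, ch] = 0.0
    for b in range(n):
        for i in range(ho):
            for j in range(wo):
                row = (b * ho + i) * wo + j
                for ch in range(c):
                    for m in range(kh):
                        for k in range(kw):
                            dx[b, i + m, j + k, ch] += dcols[row, (ch * kh + m) * kw + k]


@njit(cache=True)
def maxpool_forward(x, ph, pw, out, arg):
    """Windowed max with flat argmax (first maximum in row-major window order
    wins); x (N,H,W,C), out/arg (N,H//ph,W//pw,C)."""
    n, h, w, c = x.shape
    ho = h // ph
    wo = w // pw
    for b in range(n):
        for i in range(ho):
            for j in range(wo):
                for ch in range(c):
                    best = x[b, i * ph, j * pw, ch]
                    best_at = 0
                    for m in range(ph):
                        for k in range(pw):
                            v = x[b, i * ph + m, j * pw + k, ch]
                            if v > best:
                                best = v
                                best_at = m * pw + k
                    out[b, i, j, ch] = best
                    arg[b, i, j, ch] = best_at


@njit(cache=True)
def maxpool_backward(dout, arg, ph, pw, dx):
    """Route gradients to each window's argmax position; dx is zeroed first."""
    n, ho, wo, c = dout.shape
    for b in range(n):
        for i in range(dx.shape[1]):
            for j in range(dx.shape[2]):
                for ch in range(c):
                    dx[b, i, j, ch] = 0.0
    for b in range(n):
        for i in range(ho):
            for j in range(wo):
                for ch in range(c):
                    at = arg[b, i, j, ch]
                    dx[b, i * ph + at // pw, j * pw + at % pw, ch] = dout[b, i, j, ch]


@njit(cache=True)
def lstm_backward_steps(dout, WhT, gates, c_s, tc_s, dA):
    """Backpropagate through time; mutates dA (N,T,4H).

    ``dout`` is the incoming gradient on the hidden states (N,T,H); ``WhT``
    the transposed recurrent weights (4H,H), contiguous.  Weight gradients
    are left to the caller (single matmuls over the stored activations).
    """
    n, t_len, hdim = dout.shape
    h3 = 3 * hdim
    h4 = 4 * hdim
    dh = np.zeros((n, hdim), dtype=dout.dtype)
    dc = np.zeros((n, hdim), dtype=dout.dtype)
    da = np.empty((n, h4), dtype=dout.dtype)
    for t in range(t_len - 1, -1, -1):
        for i in range(n):
            for j in range(hdim):
                ig = gates[t, i, j]
                fg = gates[t, i, hdim + j]
                og = gates[t, i, 2 * hdim + j]
                gg = gates[t, i, h3 + j]
                tc = tc_s[t, i, j]
                c_prev = c_s[t - 1, i, j] if t > 0 else 0.0
                dh_t = dout[i, t, j] + dh[i, j]
                do = dh_t * tc
                dc_t = dc[i, j] + dh_t * og * (1.0 - tc * tc)
                da[i, j] = dc_t * gg * ig * (1.0 - ig)
                da[i, hdim + j] = dc_t * c_prev * fg * (1.0 - fg)
                da[i, 2 * hdim + j] = do * og * (1.0 - og)
                da[i, h3 + j] = dc_t * ig * (1.0 - gg * gg)
                dc[i, j] = dc_t * fg
        dh_new = np.dot(da, WhT)
        for i in range(n):
            for j in range(hdim):
                dh[i, j] = dh_new[i, j]
            for j in range(h4):
                dA[i, t, j] = da[i, j]
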