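"""Minimal batched layers with hand-derived backprop for the HAR models.

Everything operates on float arrays whose leading axis is the batch.  The
convolutional stack uses the layout ``(N, C, H, W)`` — batch, filter
channels, time steps, sensor signals.  Layers cache what their backward
pass needs; ``backward`` must be called with the same training flag state
as the preceding ``forward``.

The attention layers vectorise the reference semantics of
:mod:`cbamhar.attention` over the batch; equality of the two routes is
asserted in the test suite, as is agreement of every backward pass with
finite differences.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base class: parameters, gradients, forward/backward."""

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())


class TemporalConv(Layer):
    """2-D convolution with kernel ``(kt, 1)``: valid along time, per-signal.

    Weight shape ``(out_ch, in_ch, kt)``; output time length shrinks by
    ``kt - 1``.  Implemented as an im2col matmul so BLAS does the work.
    """

    def __init__(self, in_ch: int, out_ch: int, kt: int, rng: np.random.Generator,
                 dtype=np.float64):
        fan_in, fan_out = in_ch * kt, out_ch * kt
        s = np.sqrt(6.0 / (fan_in + fan_out))
        self.w = rng.uniform(-s, s, size=(out_ch, in_ch, kt)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.kt = kt
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=False):
        n, cin, h, w = x.shape
        kt = self.kt
        # (N, Cin, Ht, W, kt) view over time
        xw = sliding_window_view(x, kt, axis=2)
        ht = h - kt + 1
        cols = xw.transpose(0, 2, 3, 1, 4).reshape(n * ht * w, cin * kt)
        wmat = self.w.reshape(self.w.shape[0], cin * kt)
        out = cols @ wmat.T + self.b
        self._cache = (x.shape, cols)
        return np.ascontiguousarray(
            out.reshape(n, ht, w, -1).transpose(0, 3, 1, 2)
        )

    def backward(self, dout):
        (n, cin, h, w), cols = self._cache
        kt = self.kt
        ht = h - kt + 1
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ht * w, -1)
        self.dw[...] = (dmat.T @ cols).reshape(self.w.shape)
        self.db[...] = dmat.sum(axis=0)
        wmat = self.w.reshape(self.w.shape[0], cin * kt)
        dcols = (dmat @ wmat).reshape(n, ht, w, cin, kt)
        dx = np.zeros((n, cin, h, w), dtype=dout.dtype)
        for t in range(kt):
            dx[:, :, t:t + ht, :] += dcols[:, :, :, :, t].transpose(0, 3, 1, 2)
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


def _max_pool_mask(x: np.ndarray, axis) -> tuple[np.ndarray, np.ndarray]:
    """Max over *axis* plus a tie-splitting routing mask for the gradient."""
    m = x.max(axis=axis, keepdims=True)
    mask = (x == m).astype(x.dtype)
    mask /= mask.sum(axis=axis, keepdims=True)
    return np.squeeze(m, axis=axis), mask


class ChannelAttention(Layer):
    """Batched shared-MLP channel attention (sigmoid gate per channel)."""

    def __init__(self, n_channels: int, r: int, rng: np.random.Generator,
                 hidden_activation: str = "relu", dtype=np.float64):
        if n_channels % r != 0:
            raise ValueError(f"C={n_channels} not divisible by r={r}")
        hidden = n_channels // r
        s1 = np.sqrt(6.0 / (n_channels + hidden))
        s2 = np.sqrt(6.0 / (hidden + n_channels))
        self.w1 = rng.uniform(-s1, s1, size=(n_channels, hidden)).astype(dtype)
        self.b1 = np.zeros(hidden, dtype=dtype)
        self.w2 = rng.uniform(-s2, s2, size=(hidden, n_channels)).astype(dtype)
        self.b2 = np.zeros(n_channels, dtype=dtype)
        self.hidden_activation = hidden_activation
        self.dw1 = np.zeros_like(self.w1)
        self.db1 = np.zeros_like(self.b1)
        self.dw2 = np.zeros_like(self.w2)
        self.db2 = np.zeros_like(self.b2)

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def grads(self):
        return [self.dw1, self.db1, self.dw2, self.db2]

    def _mlp(self, v):
        pre = v @ self.w1 + self.b1
        h = np.maximum(pre, 0.0) if self.hidden_activation == "relu" else pre
        return pre, h, h @ self.w2 + self.b2

    def forward(self, x, train=False):
        n, c, hh, ww = x.shape
        favg = x.mean(axis=(2, 3))
        fmax, maxmask = _max_pool_mask(x, axis=(2, 3))
        pre_a, h_a, o_a = self._mlp(favg)
        pre_m, h_m, o_m = self._mlp(fmax)
        mask = sigmoid(o_a + o_m)
        self._cache = (x, favg, fmax, maxmask, pre_a, h_a, pre_m, h_m, mask)
        return x * mask[:, :, None, None]

    def backward(self, dout):
        x, favg, fmax, maxmask, pre_a, h_a, pre_m, h_m, mask = self._cache
        n, c, hh, ww = x.shape
        dmask = (dout * x).sum(axis=(2, 3))
        dx = dout * mask[:, :, None, None]
        ds = dmask * mask * (1.0 - mask)

        self.dw1[...] = 0.0
        self.db1[...] = 0.0
        self.dw2[...] = 0.0
        self.db2[...] = 0.0
        dpool = []
        for v, pre, h in ((favg, pre_a, h_a), (fmax, pre_m, h_m)):
            self.dw2 += h.T @ ds
            self.db2 += ds.sum(axis=0)
            dh = ds @ self.w2.T
            if self.hidden_activation == "relu":
                dh = dh * (pre > 0)
            self.dw1 += v.T @ dh
            self.db1 += dh.sum(axis=0)
            dpool.append(dh @ self.w1.T)
        dfavg, dfmax = dpool
        dx += dfavg[:, :, None, None] / (hh * ww)
        dx += maxmask * dfmax[:, :, None, None]
        return dx


class SpatialAttention(Layer):
    """Batched two-plane k x k spatial attention (sigmoid gate per position)."""

    def __init__(self, k: int, rng: np.random.Generator, dtype=np.float64):
        if k % 2 == 0 or k <= 0:
            raise ValueError("kernel size must be odd and positive")
        s = np.sqrt(6.0 / (2 * k * k + 1))
        self.kernel = rng.uniform(-s, s, size=(2, k, k)).astype(dtype)
        self.k = k
        self.dkernel = np.zeros_like(self.kernel)

    def params(self):
        return [self.kernel]

    def grads(self):
        return [self.dkernel]

    def forward(self, x, train=False):
        n, c, hh, ww = x.shape
        k, pad = self.k, self.k // 2
        favg = x.mean(axis=1)
        fmax, maxmask = _max_pool_mask(x, axis=(1,))
        planes = np.stack([favg, fmax], axis=1)  # (N, 2, H, W)
        pp = np.pad(planes, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        pw = sliding_window_view(pp, (k, k), axis=(2, 3))  # (N,2,H,W,k,k)
        pre = np.einsum("nchwij,cij->nhw", pw, self.kernel, optimize=True)
        mask = sigmoid(pre)
        self._cache = (x, maxmask, pw, mask)
        return x * mask[:, None, :, :]

    def backward(self, dout):
        x, maxmask, pw, mask = self._cache
        n, c, hh, ww = x.shape
        k, pad = self.k, self.k // 2
        dmask = (dout * x).sum(axis=1)
        dx = dout * mask[:, None, :, :]
        ds = dmask * mask * (1.0 - mask)
        self.dkernel[...] = np.einsum("nhw,nchwij->cij", ds, pw, optimize=True)
        # gradient w.r.t. the pooled planes: correlate ds with the flipped kernel
        dsp = np.pad(ds, ((0, 0), (pad, pad), (pad, pad)))
        dsw = sliding_window_view(dsp, (k, k), axis=(1, 2))  # (N,H,W,k,k)
        kf = self.kernel[:, ::-1, ::-1]
        dplanes = np.einsum("nhwij,cij->nchw", dsw, kf, optimize=True)
        dx += dplanes[:, 0][:, None, :, :] / c
        dx += maxmask * dplanes[:, 1][:, None, :, :]
        return dx


class LSTM(Layer):
    """Single LSTM layer over ``(N, T, F)`` returning the full sequence.

    Gate order i, f, g, o; forget-gate bias initialised to 1.
    """

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator,
                 dtype=np.float64):
        s = np.sqrt(6.0 / (n_in + n_units))
        self.wx = rng.uniform(-s, s, size=(n_in, 4 * n_units)).astype(dtype)
        so = np.sqrt(6.0 / (2 * n_units))
        self.wh = rng.uniform(-so, so, size=(n_units, 4 * n_units)).astype(dtype)
        self.b = np.zeros(4 * n_units, dtype=dtype)
        self.b[n_units:2 * n_units] = 1.0
        self.n_units = n_units
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.wx, self.wh, self.b]

    def grads(self):
        return [self.dwx, self.dwh, self.db]

    def forward(self, x, train=False):
        n, t, f = x.shape
        u = self.n_units
        h = np.zeros((n, u), dtype=x.dtype)
        c = np.zeros((n, u), dtype=x.dtype)
        hs = np.empty((n, t, u), dtype=x.dtype)
        cache = []
        for step in range(t):
            z = x[:, step] @ self.wx + h @ self.wh + self.b
            i = sigmoid(z[:, :u])
            fg = sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = sigmoid(z[:, 3 * u:])
            c_new = fg * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, fg, g, o, tc))
            h, c = h_new, c_new
            hs[:, step] = h
        self._cache = (x, cache)
        return hs

    def backward(self, dout):
        x, cache = self._cache
        n, t, f = x.shape
        u = self.n_units
        self.dwx[...] = 0.0
        self.dwh[...] = 0.0
        self.db[...] = 0.0
        dx = np.empty_like(x)
        dh_next = np.zeros((n, u), dtype=x.dtype)
        dc_next = np.zeros((n, u), dtype=x.dtype)
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, fg, g, o, tc = cache[step]
            dh = dout[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            dg = dc * i
            dfg = dc * c_prev
            dc_next = dc * fg
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    dfg * fg * (1.0 - fg),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dwx += x[:, step].T @ dz
            self.dwh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, step] = dz @ self.wx.T
            dh_next = dz @ self.wh.T
        return dx


class Dropout(Layer):
    """Inverted dropout; identity when not training or rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        s = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-s, s, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adam with the usual defaults (lr 1e-3, betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
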