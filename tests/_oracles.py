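"""Explicit-loop reference implementations of the attention arithmetic.

These are deliberately naive (nested Python loops, no vectorisation, no
shared code with the package) so they can serve as independent oracles
for the vectorised implementations.
"""

import math

import numpy as np


def sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def spatial_pool_loop(x):
    c, h, w = x.shape
    favg = np.zeros(c)
    fmax = np.full(c, -np.inf)
    for ci in range(c):
        for hi in range(h):
            for wi in range(w):
                favg[ci] += x[ci, hi, wi]
                fmax[ci] = max(fmax[ci], x[ci, hi, wi])
        favg[ci] /= h * w
    return favg, fmax


def channel_pool_loop(x):
    c, h, w = x.shape
    favg = np.zeros((h, w))
    fmax = np.full((h, w), -np.inf)
    for hi in range(h):
        for wi in range(w):
            for ci in range(c):
                favg[hi, wi] += x[ci, hi, wi]
                fmax[hi, wi] = max(fmax[hi, wi], x[ci, hi, wi])
            favg[hi, wi] /= c
    return favg, fmax


def mlp_loop(v, w1, b1, w2, b2, relu=True):
    hidden = []
    for j in range(w1.shape[1]):
        s = b1[j]
        for i in range(len(v)):
            s += v[i] * w1[i, j]
        hidden.append(max(s, 0.0) if relu else s)
    out = []
    for j in range(w2.shape[1]):
        s = b2[j]
        for i in range(len(hidden)):
            s += hidden[i] * w2[i, j]
        out.append(s)
    return np.array(out)


def channel_mask_loop(x, w1, b1, w2, b2, relu=True):
    favg, fmax = spatial_pool_loop(x)
    pre = mlp_loop(favg, w1, b1, w2, b2, relu) + mlp_loop(fmax, w1, b1, w2, b2, relu)
    return np.array([sigmoid(v) for v in pre])


def spatial_mask_loop(x, kernel):
    """kernel: (2, k, k); zero-padded size-preserving correlation."""
    favg, fmax = channel_pool_loop(x)
    planes = [favg, fmax]
    _, h, w = x.shape
    k = kernel.shape[1]
    pad = k // 2
    mask = np.zeros((h, w))
    for hi in range(h):
        for wi in range(w):
            s = 0.0
            for p in range(2):
                for i in range(k):
                    for j in range(k):
                        a, b = hi + i - pad, wi + j - pad
                        if 0 <= a < h and 0 <= b < w:
                            s += kernel[p, i, j] * planes[p][a, b]
            mask[hi, wi] = sigmoid(s)
    return mask


def apply_channel_loop(x, mask):
    out = np.zeros_like(x)
    c, h, w = x.shape
    for ci in range(c):
        for hi in range(h):
            for wi in range(w):
                out[ci, hi, wi] = mask[ci] * x[ci, hi, wi]
    return out


def apply_spatial_loop(x, mask):
    out = np.zeros_like(x)
    c, h, w = x.shape
    for ci in range(c):
        for hi in range(h):
            for wi in range(w):
                out[ci, hi, wi] = mask[hi, wi] * x[ci, hi, wi]
    return out


def cbam_loop(x, w1, b1, w2, b2, kernel, relu=True):
    """Channel step first, spatial mask computed from the refined map."""
    xp = apply_channel_loop(x, channel_mask_loop(x, w1, b1, w2, b2, relu))
    return apply_spatial_loop(xp, spatial_mask_loop(xp, kernel))
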