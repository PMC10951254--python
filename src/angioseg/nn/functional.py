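"""Structured ops (convolution, resampling, pooling) with autograd support.

Convolution is im2col + batched matmul (BLAS); the backward pass folds the
column gradient back with a KxK loop of strided adds, so no scatter ops are
needed. Every op also accepts a :class:`Probe` instead of a Tensor, in which
case it propagates shapes only and accrues parameter/MAC counts — this is
the static complexity profiler's code path, guaranteed to agree with the
real forward pass because it *is* the forward pass.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _as_tensor, _make


class Probe:
    """Shape-only stand-in for a Tensor used to count parameters and MACs."""

    def __init__(self, shape, counter=None):
        self.shape = tuple(shape)
        self.counter = counter if counter is not None else {"macs": 0, "params": 0}

    def spawn(self, shape, macs=0):
        self.counter["macs"] += int(macs)
        return Probe(shape, self.counter)


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, groups: int = 1):
    """2-D cross-correlation. x: (N,C,H,W); w: (Cout, C//groups, KH, KW)."""
    cout, cg, kh, kw = w.shape
    if isinstance(x, Probe):
        n, c, h, wd = x.shape
        oh = (h + 2 * padding - kh) // stride + 1
        ow = (wd + 2 * padding - kw) // stride + 1
        macs = n * oh * ow * cout * cg * kh * kw
        return x.spawn((n, cout, oh, ow), macs=macs)

    x, w = _as_tensor(x), _as_tensor(w)
    n, c, h, wd = x.shape
    if c != cg * groups:
        raise ValueError(f"conv2d: {c} input channels, weight expects {cg * groups}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    oh = (h + 2 * p - kh) // s + 1
    ow = (wd + 2 * p - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]  # N,C,OH,OW,KH,KW
    g = groups
    coutg = cout // g
    # cols: (G, N*OH*OW, Cg*KH*KW)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * oh * ow, g, cg * kh * kw).transpose(1, 0, 2)
    wg = w.data.reshape(g, coutg, cg * kh * kw)
    out = np.matmul(cols, wg.transpose(0, 2, 1))           # (G, N*OH*OW, CoutG)
    out = out.transpose(1, 0, 2).reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)
    out = np.ascontiguousarray(out)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(gy):
        dyg = gy.transpose(0, 2, 3, 1).reshape(n * oh * ow, g, coutg).transpose(1, 0, 2)
        if w.requires_grad:
            gw = np.matmul(dyg.transpose(0, 2, 1), cols)   # (G, CoutG, K)
            w._accumulate(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(dyg, wg)                     # (G, N*OH*OW, K)
            dcols = dcols.transpose(1, 0, 2).reshape(n, oh, ow, c, kh, kw)
            dcols = dcols.transpose(0, 3, 1, 2, 4, 5)      # N,C,OH,OW,KH,KW
            dxp = np.zeros((n, c, h + 2 * p, wd + 2 * p), dtype=gy.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[:, :, :, :, i, j]
            x._accumulate(dxp[:, :, p:p + h, p:p + wd] if p else dxp)

    return _make(out, parents, bwd)


def linear(x, w, b=None):
    """x: (..., Cin); w: (Cout, Cin)."""
    if isinstance(x, Probe):
        cout, cin = w.shape
        batch = int(np.prod(x.shape[:-1]))
        return x.spawn(x.shape[:-1] + (cout,), macs=batch * cout * cin)
    x, w = _as_tensor(x), _as_tensor(w)
    out = x @ w.transpose(1, 0)
    if b is not None:
        out = out + b
    return out


def global_avg_pool(x):
    """(N,C,H,W) -> (N,C)."""
    if isinstance(x, Probe):
        return x.spawn(x.shape[:2])
    return x.mean(axis=(2, 3))


def _up2x_axis(d: np.ndarray, axis: int) -> np.ndarray:
    """Factor-2 bilinear upsampling along one axis (half-pixel-center grid)."""
    x = np.moveaxis(d, axis, 0)
    xm1 = np.concatenate([x[:1], x[:-1]], axis=0)
    xp1 = np.concatenate([x[1:], x[-1:]], axis=0)
    ye = 0.25 * xm1 + 0.75 * x
    yo = 0.75 * x + 0.25 * xp1
    out = np.empty((2 * x.shape[0],) + x.shape[1:], dtype=d.dtype)
    out[0::2] = ye
    out[1::2] = yo
    return np.moveaxis(out, 0, axis)


def _up2x_axis_adj(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_up2x_axis`."""
    gm = np.moveaxis(g, axis, 0)
    ge, go = gm[0::2], gm[1::2]
    dx = 0.75 * ge + 0.75 * go
    dx[:-1] += 0.25 * ge[1:]
    dx[0] += 0.25 * ge[0]
    dx[1:] += 0.25 * go[:-1]
    dx[-1] += 0.25 * go[-1]
    return np.moveaxis(dx, 0, axis)


def upsample_bilinear2x(x):
    """Double both spatial dims of (N,C,H,W) by bilinear interpolation."""
    if isinstance(x, Probe):
        n, c, h, w = x.shape
        return x.spawn((n, c, 2 * h, 2 * w))
    x = _as_tensor(x)
    out = _up2x_axis(_up2x_axis(x.data, 2), 3)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(_up2x_axis_adj(_up2x_axis_adj(g, 3), 2))

    return _make(out, (x,), bwd)
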