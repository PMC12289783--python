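"""Convolution, pooling and resampling primitives with hand-derived adjoints.

Convolutions use ``sliding_window_view`` + ``einsum`` (im2col without the
copy); their input gradients are accumulated with one strided add per kernel
tap, which is exact and cheap at the kernel sizes used here (1x1 .. 4x4).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor


def _patches(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """[N,C,Hp,Wp] -> [N,C,Ho,Wo,kh,kw] view of stride-strided patches."""
    p = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return p[:, :, ::stride, ::stride]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, depthwise: bool = False) -> Tensor:
    """2-D cross-correlation in NCHW layout.

    ``w`` is [Cout, Cin, kh, kw]; for ``depthwise`` it is [C, 1, kh, kw] and
    each channel is filtered independently (the depthwise half of a
    depthwise-separable convolution).
    """
    N, C, H, W = x.data.shape
    kh, kw = w.data.shape[-2:]
    if kh == 1 and kw == 1 and stride == 1 and padding == 0 and not depthwise:
        return _conv1x1(x, w, b)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    patches = _patches(xp, kh, kw, stride)
    if depthwise:
        if w.data.shape[0] != C:
            raise ValueError("depthwise conv needs one filter per channel")
        out_data = np.einsum("nchwij,cij->nchw", patches, w.data[:, 0], optimize=True)
    else:
        if w.data.shape[1] != C:
            raise ValueError(
                f"conv2d channel mismatch: input {C}, weight expects {w.data.shape[1]}")
        out_data = np.einsum("nchwij,ocij->nohw", patches, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    Ho, Wo = out_data.shape[-2:]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if w.requires_grad:
            if depthwise:
                gw = np.einsum("nchwij,nchw->cij", patches, g, optimize=True)[:, None]
            else:
                gw = np.einsum("nchwij,nohw->ocij", patches, g, optimize=True)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    sl = np.s_[:, :, i : i + stride * Ho : stride,
                               j : j + stride * Wo : stride]
                    if depthwise:
                        gxp[sl] += g * w.data[None, :, 0, i, j, None, None]
                    else:
                        gxp[sl] += np.einsum(
                            "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._make(out_data, parents, backward)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution as one batched GEMM (no patch copies)."""
    N, C, H, W = x.data.shape
    O = w.data.shape[0]
    w2 = w.data[:, :, 0, 0]                      # [O, C]
    xm = x.data.reshape(N, C, H * W)
    out_data = (w2 @ xm).reshape(N, O, H, W)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.reshape(N, O, H * W)
        if w.requires_grad:
            gw = np.einsum("nop,ncp->oc", gm, xm, optimize=True)
            w._accumulate(gw[:, :, None, None])
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate((w2.T @ gm).reshape(N, C, H, W))

    return Tensor._make(out_data, parents, backward)


def dilate2d(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride-1`` zeros between pixels (the expansion half of a
    transposed convolution)."""
    N, C, H, W = x.data.shape
    out_data = np.zeros((N, C, (H - 1) * stride + 1, (W - 1) * stride + 1))
    out_data[:, :, ::stride, ::stride] = x.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g[:, :, ::stride, ::stride])

    return Tensor._make(out_data, (x,), backward)


def maxpool2x(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x needs even spatial dims, got {H}x{W}")
    win = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = win.reshape(N, C, H // 2, W // 2, 4)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gx = (gflat.reshape(N, C, H // 2, W // 2, 2, 2)
              .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W))
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)


def avgpool2d(x: Tensor, k: int = 3, stride: int = 1, padding: int = 1) -> Tensor:
    """k x k mean filter; defaults give the stride-1 padded 3x3 smoothing
    used ahead of feature integration."""
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    patches = _patches(xp, k, k, stride)
    out_data = patches.mean(axis=(-1, -2))
    Ho, Wo = out_data.shape[-2:]

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp)
        share = g / (k * k)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + stride * Ho : stride,
                    j : j + stride * Wo : stride] += share
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    N, C, H, W = x.data.shape

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), backward)
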