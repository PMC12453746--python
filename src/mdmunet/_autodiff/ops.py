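"""Differentiable 3D convolution primitives.

All tensors follow the (batch, channel, depth, height, width) layout. The
forward passes are written as a shift-and-add over kernel taps: for every
kernel offset the padded input is sliced (a view, optionally strided) and
contracted against the corresponding weight slice. Memory therefore stays
O(volume) — no im2col buffer — and each dense-conv tap is a single BLAS
contraction. Gradients are registered with ``autograd`` via hand-written
vector-Jacobian products, so the whole network can be differentiated with
``autograd.grad`` while the heavy lifting stays in vectorized numpy.

Only the cases the network needs are supported: arbitrary odd/even kernels
with symmetric zero padding and uniform stride for ``conv3d``; stride-1
``depthwise_conv3d``; and ``conv_transpose3d`` restricted to kernel == stride
(the non-overlapping 2x2x2 upsampling case).
"""

from __future__ import annotations

from itertools import product

import numpy as np
from autograd.extend import defvjp, primitive


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError(f"expected 3 values, got {v!r}")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


def same_padding(kernel) -> tuple[int, int, int]:
    """Symmetric zero padding that preserves spatial shape for odd kernels."""
    kernel = _triple(kernel)
    for k in kernel:
        if k % 2 == 0:
            raise ValueError(f"'same' padding requires odd kernels, got {kernel}")
    return tuple(k // 2 for k in kernel)


def conv_output_shape(spatial, kernel, stride, padding) -> tuple[int, int, int]:
    kernel, stride, padding = _triple(kernel), _triple(stride), _triple(padding)
    out = tuple((s + 2 * p - k) // t + 1 for s, k, t, p in zip(spatial, kernel, stride, padding))
    if any(o < 1 for o in out):
        raise ValueError(f"kernel {kernel} does not fit input {tuple(spatial)} with padding {padding}")
    return out


def _pad(x, padding):
    pd, ph, pw = padding
    if pd == ph == pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))


def _tap_slices(i, j, k, stride, out_spatial):
    sd, sh, sw = stride
    do, ho, wo = out_spatial
    return (
        slice(i, i + sd * (do - 1) + 1, sd),
        slice(j, j + sh * (ho - 1) + 1, sh),
        slice(k, k + sw * (wo - 1) + 1, sw),
    )


# ---------------------------------------------------------------------------
# dense convolution
# ---------------------------------------------------------------------------

@primitive
def conv3d(x, w, b, stride=(1, 1, 1), padding=(0, 0, 0)):
    """Cross-correlation of x:(B,C,D,H,W) with w:(O,C,kd,kh,kw), bias b:(O,) or None."""
    stride, padding = _triple(stride), _triple(padding)
    o, c, kd, kh, kw = w.shape
    if x.shape[1] != c:
        raise ValueError(f"conv3d: input has {x.shape[1]} channels, weight expects {c}")
    out_sp = conv_output_shape(x.shape[2:], (kd, kh, kw), stride, padding)
    xp = _pad(x, padding)
    acc = np.zeros((o, x.shape[0]) + out_sp, dtype=x.dtype)
    for i, j, k in product(range(kd), range(kh), range(kw)):
        sl = _tap_slices(i, j, k, stride, out_sp)
        xs = xp[:, :, sl[0], sl[1], sl[2]]
        acc += np.tensordot(w[:, :, i, j, k], xs, axes=(1, 1))
    out = np.ascontiguousarray(np.moveaxis(acc, 0, 1))
    if b is not None:
        out += b.reshape(1, -1, 1, 1, 1)
    return out


def _conv3d_vjp_x(ans, x, w, b, stride=(1, 1, 1), padding=(0, 0, 0)):
    stride, padding = _triple(stride), _triple(padding)
    o, c, kd, kh, kw = w.shape
    out_sp = ans.shape[2:]
    pd, ph, pw = padding

    def vjp(g):
        gxp = np.zeros(
            (c, x.shape[0], x.shape[2] + 2 * pd, x.shape[3] + 2 * ph, x.shape[4] + 2 * pw),
            dtype=g.dtype,
        )
        for i, j, k in product(range(kd), range(kh), range(kw)):
            sl = _tap_slices(i, j, k, stride, out_sp)
            # (C,O) @ (B,O,...): contract over O -> (C,B,...)
            gxp[:, :, sl[0], sl[1], sl[2]] += np.tensordot(w[:, :, i, j, k], g, axes=(0, 1))
        gx = np.moveaxis(gxp, 0, 1)
        return np.ascontiguousarray(
            gx[:, :, pd:pd + x.shape[2], ph:ph + x.shape[3], pw:pw + x.shape[4]]
        )

    return vjp


def _conv3d_vjp_w(ans, x, w, b, stride=(1, 1, 1), padding=(0, 0, 0)):
    stride, padding = _triple(stride), _triple(padding)
    o, c, kd, kh, kw = w.shape
    out_sp = ans.shape[2:]
    xp = _pad(x, padding)

    def vjp(g):
        gw = np.zeros_like(w)
        for i, j, k in product(range(kd), range(kh), range(kw)):
            sl = _tap_slices(i, j, k, stride, out_sp)
            xs = xp[:, :, sl[0], sl[1], sl[2]]
            gw[:, :, i, j, k] = np.tensordot(g, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        return gw

    return vjp


def _conv3d_vjp_b(ans, x, w, b, stride=(1, 1, 1), padding=(0, 0, 0)):
    return lambda g: g.sum(axis=(0, 2, 3, 4))


defvjp(conv3d, _conv3d_vjp_x, _conv3d_vjp_w, _conv3d_vjp_b)


# ---------------------------------------------------------------------------
# depthwise convolution (stride 1)
# ---------------------------------------------------------------------------

@primitive
def depthwise_conv3d(x, w, b, padding=(0, 0, 0)):
    """Per-channel cross-correlation: x:(B,C,D,H,W), w:(C,kd,kh,kw), b:(C,) or None.

    Output channel j depends only on input channel j — no channel mixing.
    """
    padding = _triple(padding)
    c, kd, kh, kw = w.shape
    if x.shape[1] != c:
        raise ValueError(f"depthwise_conv3d: input has {x.shape[1]} channels, weight expects {c}")
    out_sp = conv_output_shape(x.shape[2:], (kd, kh, kw), (1, 1, 1), padding)
    xp = _pad(x, padding)
    out = np.zeros((x.shape[0], c) + out_sp, dtype=x.dtype)
    for i, j, k in product(range(kd), range(kh), range(kw)):
        sl = _tap_slices(i, j, k, (1, 1, 1), out_sp)
        out += xp[:, :, sl[0], sl[1], sl[2]] * w[:, i, j, k].reshape(1, -1, 1, 1, 1)
    if b is not None:
        out += b.reshape(1, -1, 1, 1, 1)
    return out


def _dw_vjp_x(ans, x, w, b, padding=(0, 0, 0)):
    padding = _triple(padding)
    c, kd, kh, kw = w.shape
    out_sp = ans.shape[2:]
    pd, ph, pw = padding

    def vjp(g):
        gxp = np.zeros(
            (x.shape[0], c, x.shape[2] + 2 * pd, x.shape[3] + 2 * ph, x.shape[4] + 2 * pw),
            dtype=g.dtype,
        )
        for i, j, k in product(range(kd), range(kh), range(kw)):
            sl = _tap_slices(i, j, k, (1, 1, 1), out_sp)
            gxp[:, :, sl[0], sl[1], sl[2]] += g * w[:, i, j, k].reshape(1, -1, 1, 1, 1)
        return np.ascontiguousarray(
            gxp[:, :, pd:pd + x.shape[2], ph:ph + x.shape[3], pw:pw + x.shape[4]]
        )

    return vjp


def _dw_vjp_w(ans, x, w, b, padding=(0, 0, 0)):
    padding = _triple(padding)
    c, kd, kh, kw = w.shape
    out_sp = ans.shape[2:]
    xp = _pad(x, padding)

    def vjp(g):
        gw = np.zeros_like(w)
        for i, j, k in product(range(kd), range(kh), range(kw)):
            sl = _tap_slices(i, j, k, (1, 1, 1), out_sp)
            gw[:, i, j, k] = np.einsum(
                "bcdhw,bcdhw->c", xp[:, :, sl[0], sl[1], sl[2]], g
            )
        return gw

    return vjp


def _dw_vjp_b(ans, x, w, b, padding=(0, 0, 0)):
    return lambda g: g.sum(axis=(0, 2, 3, 4))


defvjp(depthwise_conv3d, _dw_vjp_x, _dw_vjp_w, _dw_vjp_b)


# ---------------------------------------------------------------------------
# transposed convolution with kernel == stride (non-overlapping upsampling)
# ---------------------------------------------------------------------------

@primitive
def conv_transpose3d(x, w, b, kernel=(2, 2, 2)):
    """Transposed conv with stride == kernel: x:(B,C,...), w:(C,O,kd,kh,kw) -> (B,O,kd*D,...)."""
    kd, kh, kw = _triple(kernel)
    c, o = w.shape[:2]
    if x.shape[1] != c:
        raise ValueError(f"conv_transpose3d: input has {x.shape[1]} channels, weight expects {c}")
    bsz, _, d, h, wd = x.shape
    out = np.empty((bsz, o, d * kd, h * kh, wd * kw), dtype=x.dtype)
    for i, j, k in product(range(kd), range(kh), range(kw)):
        # (B,C,...) x (C,O) -> (B,...,O) -> (B,O,...)
        tap = np.tensordot(x, w[:, :, i, j, k], axes=(1, 0))
        out[:, :, i::kd, j::kh, k::kw] = np.moveaxis(tap, -1, 1)
    if b is not None:
        out += b.reshape(1, -1, 1, 1, 1)
    return out


def _ct_vjp_x(ans, x, w, b, kernel=(2, 2, 2)):
    kd, kh, kw = _triple(kernel)

    def vjp(g):
        gx = np.zeros_like(x)
        for i, j, k in product(range(kd), range(kh), range(kw)):
            tap = np.tensordot(g[:, :, i::kd, j::kh, k::kw], w[:, :, i, j, k], axes=(1, 1))
            gx += np.moveaxis(tap, -1, 1)
        return gx

    return vjp


def _ct_vjp_w(ans, x, w, b, kernel=(2, 2, 2)):
    kd, kh, kw = _triple(kernel)

    def vjp(g):
        gw = np.zeros_like(w)
        for i, j, k in product(range(kd), range(kh), range(kw)):
            gw[:, :, i, j, k] = np.tensordot(
                x, g[:, :, i::kd, j::kh, k::kw], axes=([0, 2, 3, 4], [0, 2, 3, 4])
            )
        return gw

    return vjp


def _ct_vjp_b(ans, x, w, b, kernel=(2, 2, 2)):
    return lambda g: g.sum(axis=(0, 2, 3, 4))


defvjp(conv_transpose3d, _ct_vjp_x, _ct_vjp_w, _ct_vjp_b)


# ---------------------------------------------------------------------------
# fused elementwise / normalization primitives
# ---------------------------------------------------------------------------
# These could be expressed with autograd.numpy directly; fusing them into
# single primitives keeps the tape small and avoids materializing the
# intermediate volumes of the naive compositions.

@primitive
def leaky_relu_(x, negative_slope=0.01):
    return np.where(x >= 0, x, negative_slope * x)


defvjp(
    leaky_relu_,
    lambda ans, x, negative_slope=0.01: lambda g: np.where(x >= 0, g, negative_slope * g),
)


@primitive
def sigmoid_(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


defvjp(sigmoid_, lambda ans, x: lambda g: g * ans * (1.0 - ans))


@primitive
def instance_norm_(x, gamma, beta, eps=1e-5):
    """Normalize (B,C,D,H,W) over the spatial axes per sample and channel."""
    mu = x.mean(axis=(2, 3, 4), keepdims=True)
    xc = x - mu
    var = np.mean(xc * xc, axis=(2, 3, 4), keepdims=True)
    xhat = xc / np.sqrt(var + eps)
    return xhat * gamma.reshape(1, -1, 1, 1, 1) + beta.reshape(1, -1, 1, 1, 1)


def _in_stats(x, eps):
    mu = x.mean(axis=(2, 3, 4), keepdims=True)
    xc = x - mu
    var = np.mean(xc * xc, axis=(2, 3, 4), keepdims=True)
    return xc / np.sqrt(var + eps), np.sqrt(var + eps)


def _in_vjp_x(ans, x, gamma, beta, eps=1e-5):
    def vjp(g):
        xhat, std = _in_stats(x, eps)
        gx = g * gamma.reshape(1, -1, 1, 1, 1)
        m1 = gx.mean(axis=(2, 3, 4), keepdims=True)
        m2 = (gx * xhat).mean(axis=(2, 3, 4), keepdims=True)
        return (gx - m1 - xhat * m2) / std

    return vjp


def _in_vjp_gamma(ans, x, gamma, beta, eps=1e-5):
    def vjp(g):
        xhat, _ = _in_stats(x, eps)
        return (g * xhat).sum(axis=(0, 2, 3, 4))

    return vjp


def _in_vjp_beta(ans, x, gamma, beta, eps=1e-5):
    return lambda g: g.sum(axis=(0, 2, 3, 4))


defvjp(instance_norm_, _in_vjp_x, _in_vjp_gamma, _in_vjp_beta)
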