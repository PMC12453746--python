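"""Building blocks of the multi-dimensional decoupled multi-scale network.

Three bespoke units make up the architecture:

* :class:`MDDMSBlock` — the encoder feature extractor. Features are decoupled
  along the depth/height/width axes; each axis runs three depthwise branches
  with axial kernels of size 5, 7 and 9 (kernel 3 along the two cross axes),
  each followed by a pointwise scaling convolution (PSC: pointwise expand ->
  nonlinearity -> pointwise compress) and a depthwise gate (DG: sigmoid of a
  depthwise 3x3x3 conv, multiplied onto the signal). The three scales are
  fused by elementwise product, added back to the input, and mapped by a
  per-axis pointwise conv. A shared-weight pointwise conv aligns the three
  axis branches, which are concatenated, fused, concatenated again with a
  3x3x3 residual branch, fused once more, and added to the input.
* :class:`MDCA` — channel attention. Three axial convolutions (5,1,1)/(1,5,1)/
  (1,1,5) produce per-axis maps; global average and global max pooling of each
  pass through a single shared PCEC bottleneck (C -> C/r -> C) and are summed;
  the three pooled vectors are concatenated, mapped by a fully connected layer
  to one weight per channel, squashed by a sigmoid, and applied channelwise
  with a residual connection: ``y = x * w + x``.
* :class:`MDSPA` / :class:`RSABlock` — spatial attention for the decoder.
  Three channel-compressing axial convolutions are summed, a 3x3x3 conv
  restores the channel count, and a sigmoid yields a voxelwise attention map:
  ``y = x * A``. The RSA block wraps it: concatenate skip and upsampled
  features, fuse (conv + instance norm + leaky ReLU), attend, close with a
  3x3x3 conv, and add the fused features back as the residual path.

All blocks preserve spatial extents and, except where stated, channel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Module


@dataclass(frozen=True)
class BlockConfig:
    """Hyperparameters shared by the bespoke blocks at one channel width."""

    channels: int
    kernel_scales: tuple[int, ...] = (5, 7, 9)
    cross_kernel: int = 3
    psc_ratio: int = 4
    pcec_ratio: int = 4
    spa_compress_ratio: int = 4
    axial_attention_kernel: int = 5
    negative_slope: float = 0.01

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be positive")
        for k in (*self.kernel_scales, self.cross_kernel, self.axial_attention_kernel):
            if k % 2 == 0:
                raise ValueError(f"kernels must be odd for symmetric padding, got {k}")
        for name in ("psc_ratio", "pcec_ratio", "spa_compress_ratio"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.channels % self.pcec_ratio:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by pcec_ratio ({self.pcec_ratio})"
            )
        if self.channels % self.spa_compress_ratio:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by "
                f"spa_compress_ratio ({self.spa_compress_ratio})"
            )
        if not 0.0 < self.negative_slope < 1.0:
            raise ValueError("negative_slope must lie in (0, 1)")


_AXES = ("depth", "height", "width")


def _axial_kernel(axis: str, k: int, cross: int) -> tuple[int, int, int]:
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")
    kernel = [cross, cross, cross]
    kernel[_AXES.index(axis)] = k
    return tuple(kernel)


class AxialDepthwiseConv(Module):
    """Depthwise conv with kernel ``k`` along one axis and ``cross`` along the others."""

    def __init__(self, channels: int, axis: str, k: int, cross: int = 3):
        self.inner = nn.DepthwiseConv3d(channels, _axial_kernel(axis, k, cross))

    def init(self, rng):
        return self.inner.init(rng)

    def __call__(self, params, x):
        return self.inner(params, x)


class PSC(Module):
    """Pointwise scaling convolution: expand C -> ratio*C, LeakyReLU, compress back."""

    def __init__(self, channels: int, ratio: int = 4, negative_slope: float = 0.01):
        if ratio < 1:
            raise ValueError("psc ratio must be >= 1")
        self.expand = nn.Conv3d(channels, ratio * channels, 1)
        self.compress = nn.Conv3d(ratio * channels, channels, 1)
        self.negative_slope = negative_slope

    def init(self, rng):
        return {"expand": self.expand.init(rng), "compress": self.compress.init(rng)}

    def __call__(self, params, x):
        h = nn.leaky_relu(self.expand(params["expand"], x), self.negative_slope)
        return self.compress(params["compress"], h)


class DepthwiseGate(Module):
    """Multiplicative gate: ``x * sigmoid(depthwise 3x3x3 conv(x))``."""

    def __init__(self, channels: int):
        self.conv = nn.DepthwiseConv3d(channels, 3)

    def init(self, rng):
        return {"conv": self.conv.init(rng)}

    def __call__(self, params, x):
        return nn.mul(x, nn.sigmoid(self.conv(params["conv"], x)))


class ResidualBlock(Module):
    """Two 3x3x3 conv + instance-norm stages with a (projected) identity skip.

    The first stage applies a leaky rectification; the skip is added to the
    un-activated second stage so that zero weights give an exact identity when
    the channel counts match.
    """

    def __init__(self, in_channels: int, out_channels: int, negative_slope: float = 0.01):
        self.conv1 = nn.Conv3d(in_channels, out_channels, 3, bias=False)
        self.norm1 = nn.InstanceNorm3d(out_channels)
        self.conv2 = nn.Conv3d(out_channels, out_channels, 3, bias=False)
        self.norm2 = nn.InstanceNorm3d(out_channels)
        self.project = (
            nn.Conv3d(in_channels, out_channels, 1) if in_channels != out_channels else None
        )
        self.negative_slope = negative_slope

    def init(self, rng):
        p = {
            "conv1": self.conv1.init(rng),
            "norm1": self.norm1.init(rng),
            "conv2": self.conv2.init(rng),
            "norm2": self.norm2.init(rng),
        }
        if self.project is not None:
            p["project"] = self.project.init(rng)
        return p

    def __call__(self, params, x):
        h = nn.leaky_relu(self.norm1(params["norm1"], self.conv1(params["conv1"], x)),
                          self.negative_slope)
        h = self.norm2(params["norm2"], self.conv2(params["conv2"], h))
        skip = x if self.project is None else self.project(params["project"], x)
        return nn.add(h, skip) if nn.is_probe(x) else h + skip


class MDDMSBlock(Module):
    """Multi-dimensional decoupled multi-scale feature extraction block."""

    def __init__(self, cfg: BlockConfig):
        self.cfg = cfg
        c = cfg.channels
        self.branches = {}
        for axis in _AXES:
            scales = {}
            for k in cfg.kernel_scales:
                scales[str(k)] = {
                    "dwc": AxialDepthwiseConv(c, axis, k, cfg.cross_kernel),
                    # normalizing each axial response keeps the three-scale
                    # product fusion from cubing the activation scale
                    "norm": nn.InstanceNorm3d(c),
                    "psc": PSC(c, cfg.psc_ratio, cfg.negative_slope),
                    "gate": DepthwiseGate(c),
                }
            self.branches[axis] = {"scales": scales, "proj": nn.Conv3d(c, c, 1)}
        self.shared_proj = nn.Conv3d(c, c, 1)
        self.res = ResidualBlock(c, c, cfg.negative_slope)
        self.fuse_axes = nn.Conv3d(3 * c, c, 1, bias=False)
        self.norm_axes = nn.InstanceNorm3d(c)
        self.fuse_out = nn.Conv3d(2 * c, c, 1, bias=False)
        self.norm_out = nn.InstanceNorm3d(c)

    def init(self, rng):
        p: dict = {}
        for axis in _AXES:
            bp: dict = {"proj": self.branches[axis]["proj"].init(rng)}
            for k, mods in self.branches[axis]["scales"].items():
                bp[k] = {name: m.init(rng) for name, m in mods.items()}
            p[axis] = bp
        p["shared_proj"] = self.shared_proj.init(rng)
        p["res"] = self.res.init(rng)
        p["fuse_axes"] = self.fuse_axes.init(rng)
        p["norm_axes"] = self.norm_axes.init(rng)
        p["fuse_out"] = self.fuse_out.init(rng)
        p["norm_out"] = self.norm_out.init(rng)
        return p

    def _axis_branch(self, params, axis, x):
        prod = None
        for k, mods in self.branches[axis]["scales"].items():
            t = mods["dwc"](params[axis][k]["dwc"], x)
            t = mods["norm"](params[axis][k]["norm"], t)
            t = mods["psc"](params[axis][k]["psc"], t)
            t = mods["gate"](params[axis][k]["gate"], t)
            prod = t if prod is None else nn.mul(prod, t)
        return self.branches[axis]["proj"](params[axis]["proj"], nn.add(x, prod))

    def __call__(self, params, x):
        cfg = self.cfg
        if not nn.is_probe(x) and x.shape[1] != cfg.channels:
            raise ValueError(f"expected {cfg.channels} channels, got {x.shape[1]}")
        axes_out = [
            self.shared_proj(params["shared_proj"], self._axis_branch(params, axis, x))
            for axis in _AXES
        ]
        x_res = self.res(params["res"], x)
        x_out = nn.leaky_relu(
            self.norm_axes(params["norm_axes"], self.fuse_axes(params["fuse_axes"], nn.cat(axes_out))),
            cfg.negative_slope,
        )
        y = nn.leaky_relu(
            self.norm_out(params["norm_out"], self.fuse_out(params["fuse_out"], nn.cat([x_res, x_out]))),
            cfg.negative_slope,
        )
        return nn.add(y, x) if nn.is_probe(x) else y + x


class PCEC(Module):
    """Shared pointwise bottleneck on pooled channel vectors: C -> C/ratio -> C."""

    def __init__(self, channels: int, ratio: int = 4, negative_slope: float = 0.01):
        if channels % ratio:
            raise ValueError(f"channels ({channels}) not divisible by pcec ratio ({ratio})")
        hidden = channels // ratio
        self.compress = nn.Linear(channels, hidden)
        self.expand = nn.Linear(hidden, channels)
        self.negative_slope = negative_slope

    def init(self, rng):
        return {"compress": self.compress.init(rng), "expand": self.expand.init(rng)}

    def __call__(self, params, v):
        h = nn.leaky_relu(self.compress(params["compress"], v), self.negative_slope)
        return self.expand(params["expand"], h)


class MDCA(Module):
    """Multi-dimensional decoupled channel attention with residual connection."""

    def __init__(self, cfg: BlockConfig):
        self.cfg = cfg
        c, k = cfg.channels, cfg.axial_attention_kernel
        self.convs = {
            "depth": nn.Conv3d(c, c, (k, 1, 1)),
            "height": nn.Conv3d(c, c, (1, k, 1)),
            "width": nn.Conv3d(c, c, (1, 1, k)),
        }
        self.pcec = PCEC(c, cfg.pcec_ratio, cfg.negative_slope)
        self.fc = nn.Linear(3 * c, c)

    def init(self, rng):
        p = {axis: m.init(rng) for axis, m in self.convs.items()}
        p["pcec"] = self.pcec.init(rng)
        p["fc"] = self.fc.init(rng)
        return p

    def channel_weights(self, params, x):
        """The sigmoid channel-weight vector w in (0,1)^C, shape (B, C)."""
        pooled = []
        for axis in _AXES:
            xa = self.convs[axis](params[axis], x)
            pooled.append(
                nn.add(
                    self.pcec(params["pcec"], nn.global_max_pool(xa)),
                    self.pcec(params["pcec"], nn.global_avg_pool(xa)),
                )
            )
        v = self.fc(params["fc"], nn.cat(pooled, axis=1))
        return nn.sigmoid(v)

    def __call__(self, params, x):
        if not nn.is_probe(x) and x.shape[1] != self.cfg.channels:
            raise ValueError(f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        w = self.channel_weights(params, x)
        if nn.is_probe(x):
            return x
        return x * w[:, :, None, None, None] + x


class MDSPA(Module):
    """Multi-dimensional decoupled spatial attention: ``y = x * A``, A in (0,1)."""

    def __init__(self, cfg: BlockConfig):
        self.cfg = cfg
        c, k, r = cfg.channels, cfg.axial_attention_kernel, cfg.spa_compress_ratio
        self.convs = {
            "depth": nn.Conv3d(c, c // r, (k, 1, 1)),
            "height": nn.Conv3d(c, c // r, (1, k, 1)),
            "width": nn.Conv3d(c, c // r, (1, 1, k)),
        }
        self.restore = nn.Conv3d(c // r, c, 3)

    def init(self, rng):
        p = {axis: m.init(rng) for axis, m in self.convs.items()}
        p["restore"] = self.restore.init(rng)
        return p

    def attention_map(self, params, x):
        parts = [self.convs[axis](params[axis], x) for axis in _AXES]
        if nn.is_probe(x):
            return self.restore(params["restore"], parts[0])
        s = parts[0] + parts[1] + parts[2]
        return nn.sigmoid(self.restore(params["restore"], s))

    def __call__(self, params, x):
        if not nn.is_probe(x) and x.shape[1] != self.cfg.channels:
            raise ValueError(f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        a = self.attention_map(params, x)
        return x if nn.is_probe(x) else x * a


class RSABlock(Module):
    """Residual spatial-attention decoder block fusing skip and upsampled features."""

    def __init__(self, cfg: BlockConfig, use_mdspa: bool = True):
        self.cfg = cfg
        c = cfg.channels
        self.fuse = nn.Conv3d(2 * c, c, 3, bias=False)
        self.norm = nn.InstanceNorm3d(c)
        self.mdspa = MDSPA(cfg) if use_mdspa else None
        self.close = nn.Conv3d(c, c, 3)

    def init(self, rng):
        p = {"fuse": self.fuse.init(rng), "norm": self.norm.init(rng)}
        if self.mdspa is not None:
            p["mdspa"] = self.mdspa.init(rng)
        p["close"] = self.close.init(rng)
        return p

    def __call__(self, params, skip, up):
        if not nn.is_probe(skip) and skip.shape[2:] != up.shape[2:]:
            raise ValueError(
                f"skip {skip.shape[2:]} and upsampled {up.shape[2:]} spatial extents differ"
            )
        h = nn.leaky_relu(
            self.norm(params["norm"], self.fuse(params["fuse"], nn.cat([skip, up]))),
            self.cfg.negative_slope,
        )
        a = h if self.mdspa is None else self.mdspa(params["mdspa"], h)
        closed = self.close(params["close"], a)
        return nn.add(h, closed) if nn.is_probe(skip) else h + closed
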