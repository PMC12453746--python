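"""Minimal functional neural-network layer system on numpy + autograd.

Modules are stateless descriptions: ``init(rng)`` returns the parameters as a
nested dict of numpy arrays, and ``module(params, x)`` runs the forward pass.
Because parameters live in plain dicts, ``autograd.grad`` differentiates any
scalar function of them directly, tests can zero individual layers by
assignment, and checkpoints are a flat name->array mapping.

Profiling uses the same forward code: passing a :class:`ShapeProbe` instead of
an array performs a shape-only traversal while accumulating multiply-accumulate
counts (one MAC counted once; only convolutional, transposed-convolutional and
fully connected layers contribute, matching the usual Table-style FLOP
convention — normalization and activation costs are excluded).
"""

from __future__ import annotations

import math
from typing import Sequence

import autograd.numpy as anp
import numpy as np

from ._autodiff import conv3d, conv_transpose3d, depthwise_conv3d
from ._autodiff.ops import (
    _triple,
    conv_output_shape,
    instance_norm_,
    leaky_relu_,
    same_padding,
    sigmoid_,
)


class ShapeProbe:
    """Stand-in tensor carrying only a shape; MACs accumulate in a shared counter."""

    def __init__(self, shape, counter=None):
        self.shape = tuple(int(s) for s in shape)
        self.counter = counter if counter is not None else {"macs": 0}

    def add_macs(self, n):
        self.counter["macs"] += int(n)

    def with_shape(self, shape):
        return ShapeProbe(shape, self.counter)

    @property
    def macs(self):
        return self.counter["macs"]


def is_probe(x) -> bool:
    return isinstance(x, ShapeProbe)


# ---------------------------------------------------------------------------
# functional helpers usable on arrays and probes
# ---------------------------------------------------------------------------

def cat(xs, axis=1):
    if is_probe(xs[0]):
        shape = list(xs[0].shape)
        shape[axis] = sum(x.shape[axis] for x in xs)
        return xs[0].with_shape(shape)
    return anp.concatenate(xs, axis=axis)


def add(x, y):
    return x if is_probe(x) else x + y


def mul(x, y):
    return x if is_probe(x) else x * y


def leaky_relu(x, negative_slope=0.01):
    if is_probe(x):
        return x
    return leaky_relu_(x, negative_slope=negative_slope)


def sigmoid(x):
    if is_probe(x):
        return x
    return sigmoid_(x)


def softmax(x, axis=1):
    if is_probe(x):
        return x
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def global_avg_pool(x):
    """(B,C,D,H,W) -> (B,C)"""
    if is_probe(x):
        return x.with_shape(x.shape[:2])
    return anp.mean(x, axis=(2, 3, 4))


def global_max_pool(x):
    if is_probe(x):
        return x.with_shape(x.shape[:2])
    return anp.max(x, axis=(2, 3, 4))


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class; subclasses define ``init`` and ``__call__``."""

    def init(self, rng: np.random.Generator) -> dict:
        raise NotImplementedError

    def __call__(self, params, x):
        raise NotImplementedError


def _he_std(fan_in, negative_slope=0.01):
    return math.sqrt(2.0 / ((1.0 + negative_slope**2) * fan_in))


class Conv3d(Module):
    """Dense 3D convolution; ``padding='same'`` preserves spatial shape (odd kernels)."""

    def __init__(self, in_channels, out_channels, kernel, stride=1, padding="same", bias=True):
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = same_padding(self.kernel) if padding == "same" else _triple(padding)
        self.bias = bias

    def init(self, rng):
        fan_in = self.in_channels * int(np.prod(self.kernel))
        w = rng.normal(0.0, _he_std(fan_in), size=(self.out_channels, self.in_channels) + self.kernel)
        p = {"w": w.astype(np.float32)}
        if self.bias:
            p["b"] = np.zeros(self.out_channels, dtype=np.float32)
        return p

    def out_shape(self, shape):
        sp = conv_output_shape(shape[2:], self.kernel, self.stride, self.padding)
        return (shape[0], self.out_channels) + sp

    def __call__(self, params, x):
        if is_probe(x):
            out = self.out_shape(x.shape)
            x.add_macs(
                x.shape[0] * self.in_channels * self.out_channels
                * int(np.prod(self.kernel)) * int(np.prod(out[2:]))
            )
            return x.with_shape(out)
        return conv3d(x, params["w"], params.get("b"), stride=self.stride, padding=self.padding)


class DepthwiseConv3d(Module):
    """Per-channel convolution; never mixes channels."""

    def __init__(self, channels, kernel, bias=True):
        self.channels = int(channels)
        self.kernel = _triple(kernel)
        for k in self.kernel:
            if k % 2 == 0:
                raise ValueError(f"depthwise kernels must be odd, got {self.kernel}")
        self.padding = same_padding(self.kernel)
        self.bias = bias

    def init(self, rng):
        fan_in = int(np.prod(self.kernel))
        w = rng.normal(0.0, _he_std(fan_in), size=(self.channels,) + self.kernel)
        p = {"w": w.astype(np.float32)}
        if self.bias:
            p["b"] = np.zeros(self.channels, dtype=np.float32)
        return p

    def __call__(self, params, x):
        if is_probe(x):
            x.add_macs(
                x.shape[0] * self.channels * int(np.prod(self.kernel)) * int(np.prod(x.shape[2:]))
            )
            return x
        return depthwise_conv3d(x, params["w"], params.get("b"), padding=self.padding)


class ConvTranspose3d(Module):
    """Transposed convolution with kernel == stride (e.g. 2x2x2, stride 2)."""

    def __init__(self, in_channels, out_channels, kernel=2, bias=True):
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel = _triple(kernel)
        self.bias = bias

    def init(self, rng):
        fan_in = self.in_channels
        w = rng.normal(
            0.0, _he_std(fan_in), size=(self.in_channels, self.out_channels) + self.kernel
        )
        p = {"w": w.astype(np.float32)}
        if self.bias:
            p["b"] = np.zeros(self.out_channels, dtype=np.float32)
        return p

    def __call__(self, params, x):
        if is_probe(x):
            sp = tuple(s * k for s, k in zip(x.shape[2:], self.kernel))
            x.add_macs(
                x.shape[0] * self.in_channels * self.out_channels
                * int(np.prod(self.kernel)) * int(np.prod(x.shape[2:]))
            )
            return x.with_shape((x.shape[0], self.out_channels) + sp)
        return conv_transpose3d(x, params["w"], params.get("b"), kernel=self.kernel)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        self.in_features = int(in_features)
        self.out_features = int(out_features)
        self.bias = bias

    def init(self, rng):
        w = rng.normal(0.0, _he_std(self.in_features), size=(self.in_features, self.out_features))
        p = {"w": w.astype(np.float32)}
        if self.bias:
            p["b"] = np.zeros(self.out_features, dtype=np.float32)
        return p

    def __call__(self, params, x):
        if is_probe(x):
            x.add_macs(x.shape[0] * self.in_features * self.out_features)
            return x.with_shape((x.shape[0], self.out_features))
        y = anp.dot(x, params["w"])
        if self.bias:
            y = y + params["b"]
        return y


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes, with affine."""

    eps = 1e-5

    def __init__(self, channels):
        self.channels = int(channels)

    def init(self, rng):
        return {
            "gamma": np.ones(self.channels, dtype=np.float32),
            "beta": np.zeros(self.channels, dtype=np.float32),
        }

    def __call__(self, params, x):
        if is_probe(x):
            return x
        return instance_norm_(x, params["gamma"], params["beta"], eps=self.eps)


class Sequential(Module):
    def __init__(self, modules: Sequence[Module]):
        self.modules = list(modules)

    def init(self, rng):
        return {str(i): m.init(rng) for i, m in enumerate(self.modules)}

    def __call__(self, params, x):
        for i, m in enumerate(self.modules):
            x = m(params[str(i)], x)
        return x


class Lambda(Module):
    """Parameter-free elementwise module (must be probe-transparent)."""

    def __init__(self, fn):
        self.fn = fn

    def init(self, rng):
        return {}

    def __call__(self, params, x):
        return self.fn(x)


# ---------------------------------------------------------------------------
# parameter-tree utilities
# ---------------------------------------------------------------------------

def tree_map(fn, *trees):
    first = trees[0]
    if isinstance(first, dict):
        return {k: tree_map(fn, *[t[k] for t in trees]) for k in first}
    return fn(*trees)


def tree_leaves(tree, prefix=""):
    """Yield (path, array) pairs in deterministic (sorted) order."""
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from tree_leaves(tree[k], f"{prefix}{k}/" if prefix or True else k)
    else:
        yield prefix.rstrip("/"), tree


def count_parameters(tree) -> int:
    return sum(int(np.asarray(leaf).size) for _, leaf in tree_leaves(tree))


def flatten_tree(tree) -> dict:
    return {path: np.asarray(leaf) for path, leaf in tree_leaves(tree)}


def unflatten_tree(flat: dict) -> dict:
    out: dict = {}
    for path, arr in flat.items():
        keys = path.split("/")
        node = out
        for k in keys[:-1]:
            node = node.setdefault(k, {})
        node[keys[-1]] = arr
    return out
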