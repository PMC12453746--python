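"""Contracts of the bespoke blocks: shapes, residual identities, attention
ranges, channel isolation, and the compositional equivalence of the
multi-scale encoder block with its published sub-operations."""

import numpy as np
import pytest
from autograd import grad

from mdmunet import nn
from mdmunet.blocks import (
    MDCA,
    MDSPA,
    PCEC,
    PSC,
    AxialDepthwiseConv,
    BlockConfig,
    DepthwiseGate,
    MDDMSBlock,
    ResidualBlock,
    RSABlock,
)


def finite(x):
    return np.isfinite(np.asarray(x)).all()


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

def test_block_config_rejects_invalid_settings():
    with pytest.raises(ValueError):
        BlockConfig(channels=8, kernel_scales=(4, 7, 9))  # even kernel
    with pytest.raises(ValueError):
        BlockConfig(channels=6, pcec_ratio=4)  # not divisible
    with pytest.raises(ValueError):
        BlockConfig(channels=8, spa_compress_ratio=3)
    with pytest.raises(ValueError):
        AxialDepthwiseConv(8, "diagonal", 5)


# ---------------------------------------------------------------------------
# axial depthwise convolution
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("axis", ["depth", "height", "width"])
def test_axial_conv_preserves_shape_and_isolates_channels(rng, axis):
    conv = AxialDepthwiseConv(4, axis, 5)
    params = conv.init(rng)
    x = rng.normal(size=(1, 4, 8, 8, 8)).astype(np.float32)
    y = np.asarray(conv(params, x))
    assert y.shape == x.shape and finite(y)

    # perturbing channel j must change only channel j of the output
    x2 = x.copy()
    x2[:, 2] += 1.0
    y2 = np.asarray(conv(params, x2))
    changed = [j for j in range(4) if not np.allclose(y[:, j], y2[:, j])]
    assert changed == [2]


def test_axial_conv_kernel_orientation(rng):
    """The long kernel extent lies along the chosen axis."""
    conv = AxialDepthwiseConv(2, "height", 9, cross=3)
    assert conv.inner.kernel == (3, 9, 3)


# ---------------------------------------------------------------------------
# pointwise scaling convolution
# ---------------------------------------------------------------------------

def test_psc_shape_zero_map_and_parameter_enumeration(rng):
    c, ratio = 8, 4
    psc = PSC(c, ratio)
    params = psc.init(rng)
    x = rng.normal(size=(1, c, 4, 4, 4)).astype(np.float32)
    assert np.asarray(psc(params, x)).shape == x.shape

    zeroed = nn.tree_map(np.zeros_like, params)
    assert np.all(np.asarray(psc(zeroed, x)) == 0.0)

    # closed-form weight enumeration of the two pointwise layers
    expected = (c * ratio * c + ratio * c) + (ratio * c * c + c)
    assert nn.count_parameters(params) == expected


# ---------------------------------------------------------------------------
# depthwise gate
# ---------------------------------------------------------------------------

def test_depthwise_gate_halves_at_zero_weights_and_bounds_magnitude(rng):
    gate = DepthwiseGate(4)
    params = gate.init(rng)
    x = rng.normal(size=(2, 4, 6, 6, 6)).astype(np.float32)

    zeroed = nn.tree_map(np.zeros_like, params)
    assert np.allclose(np.asarray(gate(zeroed, x)), 0.5 * x)

    assert np.all(np.asarray(gate(params, np.zeros_like(x))) == 0.0)

    for _ in range(5):
        xi = rng.normal(size=(1, 4, 5, 5, 5)).astype(np.float32)
        pi = gate.init(rng)
        assert np.all(np.abs(np.asarray(gate(pi, xi))) <= np.abs(xi) + 1e-7)


# ---------------------------------------------------------------------------
# MDDMS block
# ---------------------------------------------------------------------------

def test_mddms_preserves_shape_and_zero_init_is_identity(rng, small_cfg):
    blk = MDDMSBlock(small_cfg)
    params = blk.init(rng)
    x = rng.normal(size=(1, 8, 8, 8, 8)).astype(np.float32)
    y = np.asarray(blk(params, x))
    assert y.shape == x.shape and finite(y)

    params["fuse_out"]["w"][:] = 0.0
    assert np.allclose(np.asarray(blk(params, x)), x)


def test_mddms_rejects_channel_mismatch(rng, small_cfg):
    blk = MDDMSBlock(small_cfg)
    params = blk.init(rng)
    with pytest.raises(ValueError, match="channels"):
        blk(params, np.zeros((1, 5, 8, 8, 8), dtype=np.float32))


def test_mddms_equals_stepwise_composition_of_sub_operations(rng, small_cfg):
    """Reference composition: per axis a, branch = Conv1(x + prod_k
    DG(PSC(IN(DWC_k,a(x))))); shared Conv1 on each branch; residual branch;
    concat+fuse; concat with residual + fuse; +x. Same weights as the block."""
    blk = MDDMSBlock(small_cfg)
    params = blk.init(rng)
    x = rng.normal(size=(1, 8, 7, 7, 7)).astype(np.float32)

    def lrelu(v):
        return np.where(v >= 0, v, small_cfg.negative_slope * v)

    branches = []
    for axis in ("depth", "height", "width"):
        prod = None
        for k in map(str, small_cfg.kernel_scales):
            mods = blk.branches[axis]["scales"][k]
            t = np.asarray(mods["dwc"](params[axis][k]["dwc"], x))
            t = np.asarray(mods["norm"](params[axis][k]["norm"], t))
            t = np.asarray(mods["psc"](params[axis][k]["psc"], t))
            t = np.asarray(mods["gate"](params[axis][k]["gate"], t))
            prod = t if prod is None else prod * t
        branch = np.asarray(blk.branches[axis]["proj"](params[axis]["proj"], x + prod))
        branches.append(np.asarray(blk.shared_proj(params["shared_proj"], branch)))
    x_res = np.asarray(blk.res(params["res"], x))
    fused = np.asarray(
        blk.fuse_axes(params["fuse_axes"], np.concatenate(branches, axis=1))
    )
    x_out = lrelu(np.asarray(blk.norm_axes(params["norm_axes"], fused)))
    closing = np.asarray(
        blk.fuse_out(params["fuse_out"], np.concatenate([x_res, x_out], axis=1))
    )
    want = lrelu(np.asarray(blk.norm_out(params["norm_out"], closing))) + x

    got = np.asarray(blk(params, x))
    assert np.allclose(got, want, atol=1e-5)


# ---------------------------------------------------------------------------
# PCEC and channel attention
# ---------------------------------------------------------------------------

def test_pcec_bottleneck_arithmetic_and_shared_weights(rng):
    pcec = PCEC(16, ratio=4)
    assert pcec.compress.out_features == 4
    params = pcec.init(rng)
    v = rng.normal(size=(2, 16)).astype(np.float32)
    assert np.asarray(pcec(params, v)).shape == (2, 16)

    zeroed = nn.tree_map(np.zeros_like, params)
    assert np.all(np.asarray(pcec(zeroed, v)) == 0.0)

    # two calls within one attention instance share one weight set
    assert np.allclose(np.asarray(pcec(params, v)), np.asarray(pcec(params, v)))

    with pytest.raises(ValueError):
        PCEC(6, ratio=4)


def test_mdca_zero_fc_gives_three_halves_and_weights_in_unit_interval(rng, small_cfg):
    ca = MDCA(small_cfg)
    params = ca.init(rng)
    x = rng.normal(size=(1, 8, 6, 6, 6)).astype(np.float32)
    assert np.asarray(ca(params, x)).shape == x.shape

    w = np.asarray(ca.channel_weights(params, x))
    assert np.all((w > 0.0) & (w < 1.0))

    params["fc"]["w"][:] = 0.0
    params["fc"]["b"][:] = 0.0
    assert np.allclose(np.asarray(ca(params, x)), 1.5 * x)


def test_mdca_constant_input_pooling_identity(rng, small_cfg):
    """For a constant volume GAP == GMP per branch, so each pooled vector is
    2 * PCEC(pool) — checked against direct computation."""
    ca = MDCA(small_cfg)
    params = ca.init(rng)
    x = np.full((1, 8, 5, 5, 5), 0.7, dtype=np.float32)
    for axis in ("depth", "height", "width"):
        # Dirac axial conv keeps a constant volume constant (zero padding
        # would otherwise break constancy at the borders)
        w = params[axis]["w"]
        w[:] = 0.0
        for c in range(8):
            w[c, c][tuple(k // 2 for k in w.shape[2:])] = 1.0
        params[axis]["b"][:] = 0.0
    for axis in ("depth", "height", "width"):
        xa = np.asarray(ca.convs[axis](params[axis], x))
        gap = xa.mean(axis=(2, 3, 4))
        gmp = xa.max(axis=(2, 3, 4))
        assert np.allclose(gap, gmp, atol=1e-5)
        pooled = np.asarray(ca.pcec(params["pcec"], gmp)) + np.asarray(
            ca.pcec(params["pcec"], gap)
        )
        assert np.allclose(pooled, 2.0 * np.asarray(ca.pcec(params["pcec"], gap)), atol=1e-5)


# ---------------------------------------------------------------------------
# spatial attention and the RSA decoder block
# ---------------------------------------------------------------------------

def test_mdspa_channel_arithmetic_zero_init_and_attention_range(rng):
    cfg = BlockConfig(channels=16, spa_compress_ratio=4)
    spa = MDSPA(cfg)
    assert spa.convs["depth"].out_channels == 4
    params = spa.init(rng)
    x = rng.normal(size=(1, 16, 6, 6, 6)).astype(np.float32)
    assert np.asarray(spa(params, x)).shape == x.shape

    a = np.asarray(spa.attention_map(params, x))
    assert np.all((a > 0.0) & (a < 1.0))

    params["restore"]["w"][:] = 0.0
    params["restore"]["b"][:] = 0.0
    assert np.allclose(np.asarray(spa(params, x)), 0.5 * x)


def test_rsa_shape_zero_close_collapse_and_gradient_flow(rng, small_cfg):
    rsa = RSABlock(small_cfg)
    params = rsa.init(rng)
    skip = rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32)
    up = rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32)
    y = np.asarray(rsa(params, skip, up))
    assert y.shape == (1, 8, 4, 4, 4) and finite(y)

    with pytest.raises(ValueError, match="extents"):
        rsa(params, skip, up[:, :, :2])

    # zero closing conv: output equals the fused residual path
    pz = {k: v for k, v in params.items()}
    pz["close"] = nn.tree_map(np.zeros_like, params["close"])
    fused = nn.leaky_relu(
        rsa.norm(params["norm"], rsa.fuse(params["fuse"], np.concatenate([skip, up], axis=1))),
        small_cfg.negative_slope,
    )
    assert np.allclose(np.asarray(rsa(pz, skip, up)), np.asarray(fused), atol=1e-6)

    # gradients reach both inputs
    g_skip = grad(lambda s: np.sum(rsa(params, s, up) ** 2))(skip)
    g_up = grad(lambda u: np.sum(rsa(params, skip, u) ** 2))(up)
    for g in (g_skip, g_up):
        assert finite(g) and np.any(g != 0)


# ---------------------------------------------------------------------------
# residual block
# ---------------------------------------------------------------------------

def test_residual_block_identity_projection_and_parameter_count(rng):
    rb = ResidualBlock(16, 16)
    params = rb.init(rng)
    x = rng.normal(size=(1, 16, 5, 5, 5)).astype(np.float32)
    params["conv1"]["w"][:] = 0.0
    params["conv2"]["w"][:] = 0.0
    assert np.allclose(np.asarray(rb(params, x)), x)

    rb2 = ResidualBlock(16, 32)
    p2 = rb2.init(rng)
    y = np.asarray(rb2(p2, x))
    assert y.shape == (1, 32, 5, 5, 5)

    # enumeration of the declared layers
    expected = (
        27 * 16 * 32  # conv1, no bias
        + 2 * 32  # norm1 affine
        + 27 * 32 * 32  # conv2, no bias
        + 2 * 32  # norm2 affine
        + 16 * 32 + 32  # pointwise projection with bias
    )
    assert nn.count_parameters(p2) == expected
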