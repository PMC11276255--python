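"""The three architectural deltas: deformable convolution, aggregated
residual blocks, and the information-preserving down-sampling shortcut."""

from __future__ import annotations

import numpy as np
import pytest

from dcrnet import autograd as ag
from dcrnet.autograd import Parameter, Tensor
from dcrnet.backbone import (AggregatedResidualBlock, BackboneConfig, ConfigError,
                             DcrDownsample, DCRNet, block_accounting, build_backbone)
from dcrnet.nn import DeformableConv2d

from oracles import deformable_conv_reference


# ---------------------------------------------------------------------------
# deformable convolution
# ---------------------------------------------------------------------------

def test_zero_offsets_reduce_to_standard_convolution(rng):
    x = Tensor(rng.normal(size=(1, 3, 8, 8)))
    w = Tensor(rng.normal(size=(4, 3, 3, 3)))
    off = Tensor(np.zeros((1, 18, 8, 8)))
    y_def = ag.deform_conv2d(x, w, off, padding=1)
    y_std = ag.conv2d(x, w, padding=1)
    np.testing.assert_allclose(y_def.data, y_std.data, atol=1e-12)


def test_integer_column_shift_equals_shifted_convolution(rng):
    """Offsets of exactly (0, 1) sample one column to the right: the result
    is the standard convolution output shifted by one column (identical
    zero-outside-the-map semantics at the borders)."""
    x = Tensor(rng.normal(size=(1, 2, 6, 7)))
    w = Tensor(rng.normal(size=(3, 2, 3, 3)))
    off = np.zeros((1, 18, 6, 7))
    off[:, 1::2] = 1.0                     # Δx = +1 for every tap
    y_def = ag.deform_conv2d(x, w, Tensor(off), padding=1)
    y_std = ag.conv2d(x, w, padding=1)
    np.testing.assert_allclose(y_def.data[:, :, :, :-1], y_std.data[:, :, :, 1:],
                               atol=1e-10)
    # interior columns also equal convolving an explicitly shifted input
    x_shift = np.zeros_like(x.data)
    x_shift[:, :, :, :-1] = x.data[:, :, :, 1:]
    y_shift = ag.conv2d(Tensor(x_shift), w, padding=1)
    np.testing.assert_allclose(y_def.data[:, :, :, 1:-1], y_shift.data[:, :, :, 1:-1],
                               atol=1e-10)


def test_matches_scalar_loop_reference_on_random_instances(rng):
    """Production vectorised deformable convolution vs the independent
    per-location scalar evaluation, random fractional offsets."""
    for _ in range(5):
        x = rng.normal(size=(1, 8, 8))
        w = rng.normal(size=(2, 1, 3, 3))
        off = rng.uniform(-1.7, 1.7, size=(18, 8, 8))
        ref = deformable_conv_reference(x, w, off, stride=1, padding=1)
        got = ag.deform_conv2d(Tensor(x[None]), Tensor(w), Tensor(off[None]),
                               padding=1).data[0]
        np.testing.assert_allclose(got, ref, rtol=1e-5, atol=1e-8)


def test_offset_gradients_match_finite_differences(rng):
    """The offsets are trainable: dY/dΔPn checked on a 5x5 input."""
    x = Tensor(rng.normal(size=(1, 2, 5, 5)))
    w = Tensor(rng.normal(size=(2, 2, 3, 3)))
    off = Parameter(rng.uniform(0.05, 0.45, size=(1, 18, 5, 5)))  # away from integers

    def loss():
        y = ag.deform_conv2d(x, w, off, padding=1)
        return ag.smooth_l1(ag.reshape(y, (-1, 1)), np.zeros((y.data.size, 1)),
                            np.ones(y.data.size), beta=1e9, normalizer=2e9)

    l = loss()
    l.backward()
    grad = off.grad.copy()
    eps = 1e-6
    for i in [(0, 3, 2, 2), (0, 10, 0, 4), (0, 17, 4, 1), (0, 8, 2, 0)]:
        orig = off.data[i]
        off.data[i] = orig + eps
        lp = float(loss().data)
        off.data[i] = orig - eps
        lm = float(loss().data)
        off.data[i] = orig
        num = (lp - lm) / (2 * eps)
        assert abs(num - grad[i]) <= 1e-3 * max(abs(num), 1.0)


def test_offset_shape_mismatch_rejected(rng):
    x = Tensor(rng.normal(size=(1, 2, 5, 5)))
    w = Tensor(rng.normal(size=(2, 2, 3, 3)))
    with pytest.raises(ValueError, match="offset shape"):
        ag.deform_conv2d(x, w, Tensor(np.zeros((1, 10, 5, 5))), padding=1)


# ---------------------------------------------------------------------------
# aggregated residual block
# ---------------------------------------------------------------------------

def test_zero_weights_pass_shortcut_through(rng):
    blk = AggregatedResidualBlock(16, 16, 8, 4, rng)
    for name, p in blk.named_parameters():
        if "conv" in name and "weight" in name:
            p.data = np.zeros_like(p.data)
    blk.eval()
    x = np.abs(rng.normal(size=(1, 16, 6, 6))).astype(np.float32)
    y = blk(Tensor(x))
    np.testing.assert_allclose(y.data, x, atol=1e-6)


def test_grouped_convolution_equals_explicit_branch_sum(rng):
    """The grouped 3x3 must equal summing (concatenating) the independent
    per-path convolutions computed one branch at a time."""
    card, width = 8, 3
    mid = card * width
    x = Tensor(rng.normal(size=(2, mid, 5, 5)).astype(np.float64))
    w = Tensor(rng.normal(size=(mid, width, 3, 3)))
    grouped = ag.conv2d(x, w, padding=1, groups=card).data
    explicit = np.zeros_like(grouped)
    for k in range(card):
        xs = Tensor(x.data[:, k * width:(k + 1) * width])
        wk = Tensor(w.data[k * width:(k + 1) * width])
        explicit[:, k * width:(k + 1) * width] = ag.conv2d(xs, wk, padding=1).data
    np.testing.assert_allclose(grouped, explicit, rtol=1e-5, atol=1e-10)


def test_aggregated_block_weight_and_mac_accounting():
    """At 256 channels, cardinality 64 x width 2: 67,840 conv weights versus
    69,632 for the plain 64-wide bottleneck, with multiply-adds within 5%."""
    acc = block_accounting(in_ch=256, cardinality=64, path_width=2, plain_mid=64)
    assert acc["aggregated_weights"] == 256 * 128 + 64 * (3 * 3 * 2 * 2) + 128 * 256 == 67840
    assert acc["plain_weights"] == 256 * 64 + 3 * 3 * 64 * 64 + 64 * 256 == 69632
    assert acc["fewer_parameters"]
    assert abs(acc["mac_ratio"] - 1.0) < 0.05


def test_mid_channels_must_divide_cardinality(rng):
    with pytest.raises(ConfigError):
        AggregatedResidualBlock(16, 16, 10, 4, rng)


# ---------------------------------------------------------------------------
# down-sampling shortcut
# ---------------------------------------------------------------------------

def _identity_downsample(mode, rng):
    ds = DcrDownsample(1, 1, rng, mode=mode, bn=False)
    ds.conv.weight.data = np.ones((1, 1, 1, 1), dtype=np.float32)
    ds.eval()
    return ds


def test_constant_field_stays_constant_at_half_size(rng):
    ds = _identity_downsample("dcr", rng)
    y = ds(Tensor(np.full((1, 1, 6, 6), 7.0, dtype=np.float32)))
    assert y.data.shape == (1, 1, 3, 3)
    np.testing.assert_allclose(y.data, 7.0)


def test_output_equals_mean_of_each_2x2_block(rng):
    ds = _identity_downsample("dcr", rng)
    x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
    y = ds(Tensor(x))
    expected = x.reshape(1, 1, 2, 2, 2, 2).mean(axis=(3, 5))
    np.testing.assert_allclose(y.data, expected.reshape(1, 1, 2, 2))


def test_every_pixel_influences_dcr_output_but_strided_ignores_three_quarters(rng):
    """Exhaustive single-pixel perturbation on an 8x8 map."""
    base = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
    influential = {"dcr": 0, "strided": 0}
    for mode in influential:
        ds = _identity_downsample(mode, rng)
        y0 = ds(Tensor(base)).data
        for i in range(8):
            for j in range(8):
                xp = base.copy()
                xp[0, 0, i, j] += 1.0
                if not np.allclose(ds(Tensor(xp)).data, y0):
                    influential[mode] += 1
    assert influential["dcr"] == 64
    assert influential["strided"] == 16      # 1 in 4 grid positions


# ---------------------------------------------------------------------------
# assembled backbone
# ---------------------------------------------------------------------------

def test_pyramid_strides_4_8_16_32():
    net = build_backbone(BackboneConfig.desk_scale(), seed=0)
    x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 224, 224)).astype(np.float32))
    with ag.no_grad():
        levels = net(x)
    assert [p.data.shape[2:] for p in levels] == [(56, 56), (28, 28), (14, 14), (7, 7)]
    assert all(np.isfinite(p.data).all() for p in levels)


def test_plain_residual_degeneracy_builds_and_runs():
    cfg = BackboneConfig.desk_scale(plain=True)
    assert cfg.cardinality == 1 and cfg.downsample_mode == "strided"
    assert not cfg.deformable_stages
    net = build_backbone(cfg, seed=0)
    x = Tensor(np.random.default_rng(1).normal(size=(1, 3, 64, 64)).astype(np.float32))
    with ag.no_grad():
        levels = net(x)
    assert len(levels) == 4


def test_invalid_deformable_stage_rejected():
    with pytest.raises(ConfigError):
        BackboneConfig(deformable_stages=frozenset({7}))


def test_state_dict_round_trip_reproduces_outputs():
    cfg = BackboneConfig.desk_scale()
    net1 = build_backbone(cfg, seed=3)
    net2 = build_backbone(cfg, seed=4)
    x = Tensor(np.random.default_rng(2).normal(size=(1, 3, 64, 64)).astype(np.float32))
    net1.eval(), net2.eval()
    with ag.no_grad():
        before = net2(x)[0].data.copy()
        net2.load_state_dict(net1.state_dict())
        after2 = [p.data for p in net2(x)]
        after1 = [p.data for p in net1(x)]
    assert not np.allclose(before, after2[0])
    for a, b in zip(after1, after2):
        np.testing.assert_allclose(a, b)
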