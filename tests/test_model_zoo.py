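"""Architecture tests: attention arithmetic, side-branch block contracts
(including a loop-based convolution oracle), channel attention gating and
shape walks of the built networks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pneumonet.model_zoo import (
    AttentionQKV,
    ChannelAttention,
    DESK_CONFIG,
    NetworkConfig,
    PAPER_CONFIG,
    SideBranchBlock,
    build_attention_net,
    build_resnet_baseline,
    resnet_shape_walk,
    scaled_dot_product_attention,
)
from pneumonet.model_zoo import ConfigError


# ---------------------------------------------------------------------------
# scaled dot-product attention
# ---------------------------------------------------------------------------

class TestScaledDotProductAttention:
    def test_single_key_returns_v_row(self):
        qkv = AttentionQKV(q=np.random.default_rng(0).normal(size=(4, 3)),
                           k=[[1.0, -2.0, 0.5]], v=[[7.0, -1.0]])
        out = scaled_dot_product_attention(qkv)
        np.testing.assert_allclose(out, np.tile([7.0, -1.0], (4, 1)))

    def test_zero_query_gives_mean_of_v(self):
        rng = np.random.default_rng(1)
        k, v = rng.normal(size=(5, 3)), rng.normal(size=(5, 2))
        out = scaled_dot_product_attention(AttentionQKV(np.zeros((2, 3)), k, v))
        np.testing.assert_allclose(out, np.tile(v.mean(axis=0), (2, 1)), atol=1e-12)

    def test_worked_example(self):
        # independent oracle: direct softmax of (1/sqrt(2), 0) and matmul
        qkv = AttentionQKV(q=[[1.0, 0.0]], k=[[1.0, 0.0], [0.0, 1.0]],
                           v=[[1.0, 0.0], [0.0, 1.0]])
        out, weights = scaled_dot_product_attention(qkv, return_weights=True)
        e = math.exp(1.0 / math.sqrt(2.0))
        w1 = e / (e + 1.0)
        np.testing.assert_allclose(weights, [[w1, 1.0 - w1]], atol=1e-12)
        np.testing.assert_allclose(out, [[w1, 1.0 - w1]], atol=1e-12)
        assert abs(w1 - 0.6698) < 5e-5

    def test_shape_mismatch_raises(self):
        with pytest.raises(ConfigError):
            AttentionQKV(np.zeros((2, 3)), np.zeros((4, 2)), np.zeros((4, 2)))
        with pytest.raises(ConfigError):
            AttentionQKV(np.zeros((2, 3)), np.zeros((4, 3)), np.zeros((5, 2)))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_weights_are_a_distribution_per_query(self, seed):
        rng = np.random.default_rng(seed)
        nq, nk, dk, dv = rng.integers(1, 5, size=4)
        qkv = AttentionQKV(rng.normal(size=(nq, dk)), rng.normal(size=(nk, dk)),
                           rng.normal(size=(nk, dv)))
        _, w = scaled_dot_product_attention(qkv, return_weights=True)
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# side-branch block
# ---------------------------------------------------------------------------

def _zero_weights(block):
    for p in block.params():
        p.data[...] = 0.0


def _identity_main(block):
    # 3x3 kernel with a centre tap per channel
    w = block.main.w.data
    w[...] = 0.0
    for c in range(w.shape[0]):
        w[c, c, 1, 1] = 1.0
    block.main.b.data[...] = 0.0


class TestSideBranchBlock:
    def test_zero_kernels_with_skip_is_identity(self):
        rng = np.random.default_rng(0)
        block = SideBranchBlock(4, reduction=2, stride=2, use_norm=False,
                                use_skip=True, dtype=np.float64, rng=rng)
        _zero_weights(block)
        x = np.random.default_rng(1).normal(size=(2, 4, 8, 8))
        np.testing.assert_array_equal(block.forward(x), x)

    def test_zero_branches_identity_main_is_identity(self):
        block = SideBranchBlock(3, reduction=1, stride=1, use_norm=False,
                                use_skip=False, dtype=np.float64)
        _zero_weights(block)
        _identity_main(block)
        x = np.random.default_rng(2).normal(size=(1, 3, 6, 6))
        np.testing.assert_allclose(block.forward(x), x, atol=1e-12)

    def test_ones_input_unit_kernels_sum_to_three(self):
        # main identity + two unit 1x1 branches on a 4x4 grid of ones
        block = SideBranchBlock(1, reduction=1, stride=1, reduce_ksize=1,
                                up_ksize=1, use_norm=False, use_skip=False,
                                dtype=np.float64)
        _zero_weights(block)
        _identity_main(block)
        for reduce, _, _, up, _ in block.branches:
            reduce.w.data[...] = 1.0
            up.w.data[...] = 1.0
        x = np.ones((1, 1, 4, 4))
        np.testing.assert_allclose(block.forward(x), 3.0 * x, atol=1e-12)

    @given(st.sampled_from([4, 8]), st.sampled_from([2, 4]),
           st.sampled_from([1, 2]), st.integers(0, 10 ** 6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_shape_preserving(self, hw, channels, stride, seed):
        rng = np.random.default_rng(seed)
        block = SideBranchBlock(channels, reduction=2, stride=stride, rng=rng)
        x = rng.normal(size=(1, channels, hw, hw)).astype(np.float32)
        assert block.forward(x).shape == x.shape

    def test_indivisible_spatial_dims_raise(self):
        block = SideBranchBlock(2, reduction=2, stride=2)
        with pytest.raises(ConfigError):
            block.forward(np.zeros((1, 2, 7, 7), dtype=np.float32))

    def test_gated_fusion_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        add_block = SideBranchBlock(2, reduction=2, stride=2, use_norm=False,
                                    use_skip=False, fusion_mode="additive",
                                    dtype=np.float64, rng=np.random.default_rng(9))
        gate_block = SideBranchBlock(2, reduction=2, stride=2, use_norm=False,
                                     use_skip=False, fusion_mode="gated",
                                     dtype=np.float64, rng=np.random.default_rng(9))
        x = rng.normal(size=(1, 2, 4, 4))
        # same seed -> same weights: reconstruct gated output from the
        # additive block's main and branch parts
        main = add_block.main.forward(x)
        branches = add_block.forward(x) - main
        expected = main / (1.0 + np.exp(-branches))
        np.testing.assert_allclose(gate_block.forward(x), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# loop-based convolution oracle (<= 6x6 inputs)
# ---------------------------------------------------------------------------

def loop_conv(x, w, b, stride, pad):
    n, ci, h, wd = x.shape
    co, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd + 2 * pad - kw) // stride + 1
    y = np.zeros((n, co, ho, wo))
    for nn in range(n):
        for oc in range(co):
            for i in range(ho):
                for j in range(wo):
                    patch = xp[nn, :, i * stride:i * stride + kh,
                               j * stride:j * stride + kw]
                    y[nn, oc, i, j] = (patch * w[oc]).sum() + b[oc]
    return y


def loop_conv_transpose(x, w, b, stride, pad):
    n, ci, h, wd = x.shape
    _, co, kh, kw = w.shape
    oh = (h - 1) * stride + kh - 2 * pad
    ow = (wd - 1) * stride + kw - 2 * pad
    y = np.zeros((n, co, oh + 2 * pad, ow + 2 * pad))
    for nn in range(n):
        for ic in range(ci):
            for i in range(h):
                for j in range(wd):
                    y[nn, :, i * stride:i * stride + kh,
                      j * stride:j * stride + kw] += x[nn, ic, i, j] * w[ic]
    y = y[:, :, pad:pad + oh, pad:pad + ow]
    return y + b[None, :, None, None]


def test_block_matches_loop_oracle_on_small_inputs():
    """On <=6x6 inputs the block equals a direct loop-based convolution /
    transposed-convolution evaluation to 1e-10."""
    for hw in (4, 6):
        rng = np.random.default_rng(hw)
        block = SideBranchBlock(2, reduction=2, stride=2, use_norm=False,
                                use_skip=True, dtype=np.float64,
                                rng=np.random.default_rng(42))
        x = rng.normal(size=(2, 2, hw, hw))
        main = loop_conv(x, block.main.w.data, block.main.b.data, 1, 1)
        fused = main.copy()
        for reduce, _, _, up, _ in block.branches:
            r = loop_conv(x, reduce.w.data, reduce.b.data, reduce.stride,
                          reduce.pad)
            r = np.maximum(r, 0.0)
            fused += loop_conv_transpose(r, up.w.data, up.b.data, up.stride,
                                         up.pad)
        np.testing.assert_allclose(block.forward(x), x + fused, atol=1e-10)


# ---------------------------------------------------------------------------
# channel attention
# ---------------------------------------------------------------------------

class TestChannelAttention:
    def test_saturated_gates_pass_input_through(self):
        ca = ChannelAttention(3, reduction=1, dtype=np.float64)
        for p in ca.params():
            p.data[...] = 0.0
        ca.fc2.b.data[...] = 50.0  # sigmoid(50) ~ 1 within 1e-6
        x = np.random.default_rng(0).normal(size=(2, 3, 4, 4))
        np.testing.assert_allclose(ca.forward(x), x, atol=1e-6)

    def test_zero_weights_halve_the_input(self):
        ca = ChannelAttention(3, reduction=1, dtype=np.float64)
        for p in ca.params():
            p.data[...] = 0.0
        x = np.random.default_rng(1).normal(size=(2, 3, 4, 4))
        np.testing.assert_allclose(ca.forward(x), x / 2.0, atol=1e-12)

    def test_gates_in_open_unit_interval_and_pooling_locality(self):
        rng = np.random.default_rng(2)
        ca = ChannelAttention(4, reduction=2, rng=rng, dtype=np.float64)
        x = rng.normal(size=(3, 4, 5, 5))
        x[:, 2] = 0.0
        g = ca.gates(x)
        assert ((g > 0) & (g < 1)).all()
        # a zero channel has a zero descriptor irrespective of other channels
        np.testing.assert_allclose(x[:, 2].mean(axis=(1, 2)), 0.0)
        # output channel norms bounded by input channel norms (gates < 1)
        y = ca.forward(x)
        assert (np.abs(y) <= np.abs(x) + 1e-12).all()

    def test_backward_matches_numerical_gradient(self):
        from test_nn import numerical_grad

        rng = np.random.default_rng(3)
        ca = ChannelAttention(4, reduction=2, rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 4, 3, 3))
        dy = rng.normal(size=x.shape)

        def loss():
            return float((ca.forward(x) * dy).sum())

        ca.forward(x)
        for p in ca.params():
            p.zero_grad()
        dx = ca.backward(dy)
        np.testing.assert_allclose(dx, numerical_grad(loss, x), atol=1e-7)
        np.testing.assert_allclose(ca.fc1.w.grad,
                                   numerical_grad(loss, ca.fc1.w.data), atol=1e-7)


# ---------------------------------------------------------------------------
# built networks
# ---------------------------------------------------------------------------

class TestBuiltNetworks:
    def test_paper_walk_shapes(self):
        net = build_attention_net(PAPER_CONFIG, seed=0)
        walk = {e.name: e.shape for e in net.shape_walk()}
        assert walk["input"] == (512, 512, 3)
        assert walk["stem"] == (512, 512, 64)
        assert walk["block8"] == (512, 512, 64)
        assert walk["pool"] == (64,)
        assert walk["head"] == (2,)

    def test_desk_forward_logits_shape(self):
        cfg = NetworkConfig(input_size=(64, 64, 1), stem_channels=16, n_blocks=4)
        net = build_attention_net(cfg, seed=0)
        x = np.random.default_rng(0).random((3, 1, 64, 64), dtype=np.float32)
        assert net.forward(x).shape == (3, 2)

    def test_same_seed_same_init(self):
        a = build_attention_net(DESK_CONFIG, seed=5)
        b = build_attention_net(DESK_CONFIG, seed=5)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_invalid_config_raises_with_violation(self):
        cfg = NetworkConfig(input_size=(63, 63, 1), stem_channels=8, n_blocks=1)
        with pytest.raises(ConfigError, match="branch_stride"):
            build_attention_net(cfg)

    def test_resnet_walk_224(self):
        walk = resnet_shape_walk(224)
        assert walk[0] == (112, 112, 64)
        assert walk[1] == (56, 56, 64)
        assert walk[-1] == (7, 7, 2048)
        assert walk[0][0] == -(-224 // 2)

    def test_resnet_walk_too_small_raises(self):
        with pytest.raises(ConfigError):
            resnet_shape_walk(16)

    def test_resnet_desk_build_forward(self):
        net = build_resnet_baseline(DESK_CONFIG, seed=0)
        x = np.random.default_rng(0).random((2, 1, 64, 64), dtype=np.float32)
        assert net.forward(x).shape == (2, 2)
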