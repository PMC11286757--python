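"""Block-level contracts: residual identity, six-branch concatenation,
dilated receptive fields, tanh fusion range, attention normalisation and
the elementwise attention gating oracle."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from wbcnet.autograd import Tensor, concat, conv2d
from wbcnet.blocks import (CSAB, DRDB, GLFEB, ChannelAttention, ConvStem,
                           ResidualBranch, SpatialAttention,
                           global_average_pool)
from wbcnet.layers import GroupNorm, MaxPool2d


def _rng():
    return np.random.default_rng(42)


class TestConvStem:
    def test_shape_and_relu_range(self, rng):
        stem = ConvStem(3, 8, 4, _rng())
        out = stem(Tensor(rng.random((2, 3, 16, 16)).astype(np.float32)))
        assert out.shape == (2, 8, 8, 8)       # max-pool halves spatial dims
        assert out.data.min() >= 0.0

    def test_composition_of_primitives(self, rng):
        """Stem forward equals conv -> pool -> GN -> ReLU applied separately."""
        stem = ConvStem(3, 8, 4, _rng())
        x = Tensor(rng.random((1, 3, 8, 8)).astype(np.float32))
        manual = stem.conv(x)
        manual = MaxPool2d(2)(manual)
        manual = stem.norm(manual)
        manual = manual.relu()
        np.testing.assert_array_equal(stem(x).data, manual.data)


class TestResidualBranch:
    def test_identity_when_transform_zeroed(self, rng):
        br = ResidualBranch(4, 2, _rng())
        br.norm2.gamma.data[:] = 0.0            # T(x) == 0
        br.norm2.beta.data[:] = 0.0
        x = rng.normal(size=(2, 4, 5, 5)).astype(np.float32)
        np.testing.assert_array_equal(br(Tensor(x)).data, x)

    def test_same_size_contract(self, rng):
        for d in (1, 2, 4):
            br = ResidualBranch(4, 2, _rng(), dilation=d)
            x = Tensor(rng.normal(size=(1, 4, 9, 9)))
            assert br(x).shape == (1, 4, 9, 9)

    def test_dilation_one_equals_plain_branch(self, rng):
        plain = ResidualBranch(4, 2, np.random.default_rng(5))
        dil = ResidualBranch(4, 2, np.random.default_rng(5), dilation=1)
        x = Tensor(rng.normal(size=(1, 4, 7, 7)))
        np.testing.assert_array_equal(plain(x).data, dil(x).data)

    def test_manual_residual_oracle(self, rng):
        """1-channel toy: output equals hand-computed x + T(x)."""
        br = ResidualBranch(1, 1, _rng())
        x = rng.normal(size=(1, 1, 5, 5))
        h = conv2d(Tensor(x), br.conv1.weight, br.conv1.bias, padding=1)
        h = br.norm1(h).relu()
        h = conv2d(h, br.conv2.weight, br.conv2.bias, padding=1)
        t = br.norm2(h).data
        np.testing.assert_allclose(br(Tensor(x)).data, x + t, atol=1e-5)


@pytest.mark.parametrize("dilation,expected_span", [(1, 3), (2, 5), (4, 9)])
def test_dilated_receptive_field_span(dilation, expected_span):
    """Gradient of one output pixel touches a span of k + (k-1)(d-1)."""
    rng = np.random.default_rng(0)
    x = Tensor(rng.normal(size=(1, 1, 21, 21)), requires_grad=True)
    w = Tensor(np.ones((1, 1, 3, 3)), requires_grad=True)
    pad = dilation
    out = conv2d(x, w, None, dilation=dilation, padding=pad)
    seed = np.zeros_like(out.data)
    seed[0, 0, 10, 10] = 1.0
    out.backward(seed)
    ys, xs = np.where(x.grad[0, 0] != 0)
    assert ys.max() - ys.min() + 1 == expected_span
    assert xs.max() - xs.min() + 1 == expected_span
    assert len(ys) == 9                      # 3x3 lattice of taps


class TestDRDB:
    def test_six_branch_concat_width(self, rng):
        block = DRDB(4, 4, 2, _rng())
        x = Tensor(rng.normal(size=(1, 4, 8, 8)))
        cat = concat(block.branch_outputs(x), axis=1)
        assert cat.shape[1] == 6 * 4
        assert block(x).shape == (1, 4, 8, 8)   # same-size output

    def test_branch_dilations_follow_sequence(self):
        block = DRDB(4, 4, 2, _rng())
        dils = [b.dilation for b in block.branches]
        assert dils == [1, 1, 1, 2, 1, 4]       # plain/dilated interleave

    def test_branch_isolation_oracle(self, rng):
        """Zeroing branches 2-6 reduces the block to final-conv of the
        zero-padded first branch output."""
        block = DRDB(4, 4, 2, _rng())
        x = Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))
        b1 = block.branches[0](x)

        class _Zero:
            def __call__(self, t):
                return Tensor(np.zeros_like(t.data))
        block.branches = [block.branches[0]] + [_Zero()] * 5

        manual = concat([b1] + [Tensor(np.zeros_like(b1.data))] * 5, axis=1)
        manual = block.norm(block.reduce(manual)).relu()
        np.testing.assert_array_equal(block(x).data, manual.data)


class TestGLFEB:
    def _block(self):
        return GLFEB(3, 4, (4, 8, 4), 2, _rng())

    def test_output_channels_double_and_range(self, rng):
        block = self._block()
        g = Tensor(rng.normal(size=(1, 3, 6, 6)))
        l = Tensor(rng.normal(size=(1, 4, 6, 6)))
        out = block(g, l)
        assert out.shape[1] == 2 * 4
        assert np.abs(out.data).max() < 1.0      # tanh codomain

    def test_zero_inputs_zero_biases_give_zero(self):
        block = self._block()
        out = block(Tensor(np.zeros((1, 3, 6, 6))),
                    Tensor(np.zeros((1, 4, 6, 6))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_terminal_tanh_odd_symmetry(self, rng):
        """Negating the pre-activation volume negates the output exactly."""
        block = self._block()
        g = Tensor(rng.normal(size=(1, 3, 6, 6)).astype(np.float32))
        l = Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))
        local = block.local_path(l)
        fused = concat([local, block.global_proj(g)], axis=1)
        np.testing.assert_array_equal(block(g, l).data,
                                      np.tanh(fused.data))
        np.testing.assert_array_equal((-fused).tanh().data,
                                      -fused.tanh().data)

    def test_spatial_mismatch_is_resampled(self, rng):
        block = self._block()
        g = Tensor(rng.normal(size=(1, 3, 12, 12)))
        l = Tensor(rng.normal(size=(1, 4, 6, 6)))
        assert block(g, l).shape == (1, 8, 6, 6)


class TestChannelAttention:
    def test_codomain_open_unit_interval(self, rng):
        att = ChannelAttention(8, 4, _rng())
        q = att(Tensor(rng.normal(size=(3, 8, 5, 5)))).data
        assert ((q > 0) & (q < 1)).all()

    def test_manual_forward_oracle(self):
        """2-channel toy with hand-set weights matches the explicit
        sigmoid(FC(ReLU(W1 . GAP))) chain."""
        att = ChannelAttention(2, 1, _rng())
        w1 = np.array([[0.5, -1.0], [2.0, 0.25]])
        att.lin0.weight.data = w1.astype(np.float32)
        att.lin0.bias.data[:] = 0.1
        f1 = np.array([[1.0, 0.5], [-0.5, 1.5]])
        att.fc1.weight.data = f1.astype(np.float32)
        att.fc1.bias.data[:] = 0.0
        f2 = np.array([[0.3, -0.2], [0.8, 1.1]])
        att.fc2.weight.data = f2.astype(np.float32)
        att.fc2.bias.data[:] = -0.05
        x = np.arange(2 * 2 * 3 * 3, dtype=np.float32).reshape(2, 2, 3, 3) / 10
        gap = x.mean(axis=(2, 3))
        h = np.maximum(gap @ w1 + 0.1, 0)
        h = np.maximum(h @ f1, 0)
        want = 1.0 / (1.0 + np.exp(-(h @ f2 - 0.05)))
        got = att(Tensor(x)).data
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_monotone_in_channel_mean(self, rng):
        """Raising one channel's activations never lowers its weight when
        the gating path is identity-like."""
        att = ChannelAttention(2, 1, _rng())
        att.lin0.weight.data = np.eye(2, dtype=np.float32)
        att.lin0.bias.data[:] = 0.0
        att.fc1.weight.data = np.eye(2, dtype=np.float32)
        att.fc1.bias.data[:] = 0.0
        att.fc2.weight.data = np.eye(2, dtype=np.float32)
        att.fc2.bias.data[:] = 0.0
        x = rng.random((1, 2, 4, 4)).astype(np.float32)
        base = att(Tensor(x)).data[0, 0]
        x2 = x.copy()
        x2[0, 0] += 1.0
        assert att(Tensor(x2)).data[0, 0] >= base


class TestSpatialAttention:
    def test_normalised_to_unit_sum_and_nonnegative(self, rng):
        att = SpatialAttention(4, 5, _rng())
        out = att(Tensor(rng.normal(size=(3, 4, 7, 7)))).data
        assert out.min() >= 0.0
        np.testing.assert_allclose(out.sum(axis=(1, 2, 3)), 1.0, atol=1e-6)

    def test_pre_normalisation_matches_convolution_oracle(self, rng):
        """1-channel toy vs scipy.signal.correlate2d with a 5x5 kernel."""
        att = SpatialAttention(1, 5, _rng())
        x = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        pre = att.conv(Tensor(x)).relu().data[0, 0]
        ref = correlate2d(x[0, 0], att.conv.weight.data[0, 0], mode="same",
                          boundary="fill") + float(att.conv.bias.data[0])
        np.testing.assert_allclose(pre, np.maximum(ref, 0), atol=1e-5)

    def test_all_zero_map_falls_back_to_uniform(self, rng, caplog):
        att = SpatialAttention(2, 5, _rng())
        att.conv.weight.data[:] = 0.0
        att.conv.bias.data[:] = -1.0            # ReLU kills everything
        with caplog.at_level("WARNING"):
            out = att(Tensor(rng.normal(size=(1, 2, 6, 6)))).data
        np.testing.assert_allclose(out, 1.0 / 36, atol=1e-7)
        assert any("uniform" in r.message for r in caplog.records)


class TestCSAB:
    def _gated(self, block, x, qc, qs):
        class _Const:
            def __init__(self, v):
                self.v = v

            def __call__(self, t):
                return Tensor(self.v)
        block.channel_att = _Const(qc)
        block.spatial_att = _Const(qs)
        return block(Tensor(x)).data

    def test_identity_gating(self, rng):
        block = CSAB(3, 1, 5, _rng())
        x = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        out = self._gated(block, x, np.ones((2, 3)), np.ones((2, 1, 4, 4)))
        np.testing.assert_array_equal(out, x)

    def test_zero_spatial_gate_annihilates(self, rng):
        block = CSAB(3, 1, 5, _rng())
        x = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        out = self._gated(block, x, np.ones((2, 3)), np.zeros((2, 1, 4, 4)))
        np.testing.assert_array_equal(out, 0.0)

    def test_broadcast_product_oracle(self, rng):
        block = CSAB(2, 1, 5, _rng())
        x = rng.normal(size=(1, 2, 3, 3)).astype(np.float32)
        qc = rng.random((1, 2)).astype(np.float32)
        qs = rng.random((1, 1, 3, 3)).astype(np.float32)
        got = self._gated(block, x, qc, qs)
        want = x * qc[:, :, None, None] * qs
        np.testing.assert_allclose(got, want, atol=1e-7)

    def test_end_to_end_product_structure(self, rng):
        """Unpatched block equals at * Qc * Qs computed from its own gates."""
        block = CSAB(4, 2, 5, _rng())
        x = Tensor(rng.normal(size=(2, 4, 6, 6)).astype(np.float32))
        qc = block.channel_att(x).data
        qs = block.spatial_att(x).data
        np.testing.assert_allclose(block(x).data,
                                   x.data * qc[:, :, None, None] * qs,
                                   atol=1e-6)


class TestGlobalAveragePool:
    def test_constant_map(self):
        x = np.full((4, 6, 6), 3.7, dtype=np.float32)
        np.testing.assert_allclose(global_average_pool(x), 3.7, atol=1e-6)

    def test_linearity(self, rng):
        a = rng.normal(size=(3, 4, 4))
        b = rng.normal(size=(3, 4, 4))
        np.testing.assert_allclose(global_average_pool(a + b),
                                   global_average_pool(a)
                                   + global_average_pool(b), atol=1e-12)

    def test_empty_spatial_extent_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_average_pool(np.zeros((3, 0, 4)))
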