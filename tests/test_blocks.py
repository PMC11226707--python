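"""Building-block contracts: shapes, parameter counts, slice order, and the
serial/parallel pooling equivalence."""

import numpy as np
import pytest

from polypdet import nn as N
from polypdet.blocks import (C3, PC3, Bottleneck, ConvBNAct, ConvSpec, Focus,
                             PBottleneck, SPPF, conv_bn_act_params, focus_slice)


def _fmap(rng, c, h, w, n=1):
    return N.Tensor(rng.normal(size=(n, c, h, w)).astype(np.float32))


class TestConvBNAct:
    def test_hand_counted_parameters(self):
        # conv weights + norm scale/shift, no conv bias under normalisation
        spec = ConvSpec(3, 16, 3)
        assert conv_bn_act_params(spec) == 3 * 16 * 9 + 2 * 16 == 464
        block = ConvBNAct(spec)
        assert block.count_parameters() == 464

    @pytest.mark.parametrize("cin,cout,k,s,hin,hout", [
        (8, 8, 1, 1, 10, 10),
        (16, 16, 3, 2, 64, 32),
        (4, 6, 5, 1, 9, 9),
    ])
    def test_output_shapes(self, rng, cin, cout, k, s, hin, hout):
        block = ConvBNAct(ConvSpec(cin, cout, k, stride=s), rng=rng)
        y = block(_fmap(rng, cin, hin, hin, n=2))
        assert y.shape == (2, cout, hout, hout)

    def test_channel_mismatch_raises(self, rng):
        block = ConvBNAct(ConvSpec(4, 8, 3), rng=rng)
        with pytest.raises(ValueError, match="channels"):
            block(_fmap(rng, 5, 6, 6))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ConvSpec(3, 8, kernel=2)
        with pytest.raises(ValueError):
            ConvSpec(3, 8, dilation=0)

    def test_batch_independence(self, rng):
        block = ConvBNAct(ConvSpec(3, 6, 3), rng=rng).eval()
        a = _fmap(rng, 3, 8, 8)
        b = _fmap(rng, 3, 8, 8)
        stacked = N.Tensor(np.concatenate([a.data, b.data]))
        y = block(stacked).data
        assert np.allclose(y[0], block(a).data[0], atol=1e-6)
        assert np.allclose(y[1], block(b).data[0], atol=1e-6)


class TestFocus:
    def test_shape_arithmetic(self, rng):
        y = focus_slice(_fmap(rng, 3, 640 // 8, 640 // 8))   # scaled-down 640 case
        assert y.shape == (1, 12, 40, 40)

    def test_slice_order_on_counted_grid(self):
        x = N.Tensor(np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4))
        y = focus_slice(x).data[0]
        assert np.array_equal(y[0], [[0, 2], [8, 10]])       # (even row, even col)
        assert np.array_equal(y[1], [[4, 6], [12, 14]])      # (odd row, even col)
        assert np.array_equal(y[2], [[1, 3], [9, 11]])       # (even row, odd col)
        assert np.array_equal(y[3], [[5, 7], [13, 15]])      # (odd row, odd col)

    def test_slices_are_a_permutation_of_the_input(self, rng):
        x = _fmap(rng, 2, 6, 8)
        y = focus_slice(x)
        assert np.allclose(np.sort(y.data.ravel()), np.sort(x.data.ravel()))

    def test_odd_dims_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            focus_slice(_fmap(rng, 1, 5, 4))

    def test_focus_equals_slice_then_cbl(self, rng):
        focus = Focus(3, 8, rng=rng).eval()
        x = _fmap(rng, 3, 8, 8)
        direct = focus.conv(focus_slice(x))
        assert np.allclose(focus(x).data, direct.data)


class TestSPPF:
    def test_shape_contract(self, rng):
        sppf = SPPF(32, 32, rng=rng).eval()
        y = sppf(_fmap(rng, 32, 10, 10))
        assert y.shape == (1, 32, 10, 10)

    def test_serial_pools_equal_parallel_5_9_13(self, rng):
        """Three serial k=5 stride-1 max-pools equal parallel pools of kernel
        5, 9, 13 — exact value equality over at least 100 random maps."""
        for trial in range(100):
            x = N.Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
            y1 = N.maxpool2d(x, 5, 1, 2)
            y2 = N.maxpool2d(y1, 5, 1, 2)
            y3 = N.maxpool2d(y2, 5, 1, 2)
            p9 = N.maxpool2d(x, 9, 1, 4)
            p13 = N.maxpool2d(x, 13, 1, 6)
            assert np.array_equal(y2.data, p9.data)
            assert np.array_equal(y3.data, p13.data)

    def test_constant_map_preserved_through_pool_stages(self, rng):
        x = N.Tensor(np.full((1, 2, 6, 6), 3.25, dtype=np.float32))
        y = N.maxpool2d(x, 5, 1, 2)
        assert np.allclose(y.data, 3.25)


class TestPBottleneck:
    def test_shape_preserved_with_residual(self, rng):
        blk = PBottleneck(64 // 4, True, rng=rng).eval()
        y = blk(_fmap(rng, 16, 10, 10))
        assert y.shape == (1, 16, 10, 10)

    def test_zero_weights_residual_is_identity(self, rng):
        blk = PBottleneck(8, True, rng=rng).eval()
        for p in blk.parameters():
            if p.data.ndim == 4:          # conv weights
                p.data[:] = 0.0
        x = _fmap(rng, 8, 5, 5)
        assert np.allclose(blk(x).data, x.data)

    def test_parameter_count_closed_form(self, rng):
        # addition-combine wiring doubles the plain bottleneck count
        for c in (16, 32, 64):
            plain = Bottleneck(c, rng=rng).count_parameters()
            pb = PBottleneck(c, rng=rng).count_parameters()
            assert plain == 10 * c * c + 4 * c
            assert pb == 2 * plain == 20 * c * c + 8 * c

    def test_concat_combine_option(self, rng):
        blk = PBottleneck(8, False, combine="concat", rng=rng).eval()
        assert blk(_fmap(rng, 8, 6, 6)).shape == (1, 8, 6, 6)

    def test_bad_combine_rejected(self):
        with pytest.raises(ValueError):
            PBottleneck(8, combine="mean")


class TestC3:
    def test_shape_and_depth(self, rng):
        blk = PC3(16, 16, n=2, rng=rng).eval()
        assert blk(_fmap(rng, 16, 8, 8)).shape == (1, 16, 8, 8)

    def test_n_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            C3(8, 8, n=0)

    def test_residual_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            C3(8, 16, n=1, use_residual=True)

    def test_bypass_path_receives_gradient_with_frozen_main_path(self, rng):
        blk = C3(8, 8, n=1, rng=rng)
        x = _fmap(rng, 8, 6, 6)
        for p in blk.cv1.parameters() + sum((b.parameters() for b in blk.m), []):
            p.requires_grad = False
        blk.zero_grad()
        N.tsum(blk(x)).backward()
        assert blk.cv2.conv.weight.grad is not None
        assert np.abs(blk.cv2.conv.weight.grad).sum() > 0

    def test_pc3_vs_plain_c3_count_difference(self, rng):
        """Swapping plain bottlenecks back in recovers the standard C3 count;
        the difference is exactly n doubled bottleneck stacks."""
        for c, n in ((16, 1), (32, 2), (64, 3)):
            h = c // 2
            plain = C3(c, c, n=n, rng=rng).count_parameters()
            pc3 = PC3(c, c, n=n, rng=rng).count_parameters()
            assert pc3 - plain == n * (10 * h * h + 4 * h)

    def test_stride1_blocks_preserve_spatial_dims(self, rng):
        for h, w in ((7, 9), (12, 12)):
            blk = C3(8, 8, rng=rng).eval()
            assert blk(_fmap(rng, 8, h, w)).shape == (1, 8, h, w)
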