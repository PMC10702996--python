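"""PCFAN: attention bounds, pyramid wiring, shape contracts, loss, training."""

import numpy as np
import pytest

from pdfuse import nn, pcfan
from pdfuse.pcfan import PCFAN, PCFANConfig
from tests.conftest import make_phantom_set

SMALL = PCFANConfig(stage_channels=(8, 16, 24), attention_reduction=4)


class TestChannelAttention:
    def test_zero_input_gives_zero_output(self, rng):
        ca = pcfan.ChannelAttention(8, 4, rng)
        out = ca.forward(np.zeros((2, 8, 6, 6)))
        assert np.allclose(out, 0.0)

    def test_attention_attenuates_everywhere(self, rng):
        ca = pcfan.ChannelAttention(8, 4, rng)
        x = rng.standard_normal((2, 8, 6, 6))
        out = ca.forward(x)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-15)

    def test_zeroed_weights_halve_the_input(self, rng):
        ca = pcfan.ChannelAttention(8, 4, rng)
        for p in ca.parameters():
            p.data[...] = 0.0
        x = rng.standard_normal((1, 8, 4, 4))
        assert np.allclose(ca.forward(x), 0.5 * x)

    def test_indivisible_channel_count_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            pcfan.ChannelAttention(10, 4, rng)

    def test_gradients(self, rng):
        from tests.test_nn import check_layer_gradients
        ca = pcfan.ChannelAttention(4, 2, rng)
        check_layer_gradients(ca, rng.random((2, 4, 3, 3)))


class TestEncoderShapes:
    @pytest.mark.parametrize("size,shapes", [
        (128, [(32, 128, 128), (64, 64, 64), (128, 32, 32)]),
        (96, [(32, 96, 96), (64, 48, 48), (128, 24, 24)]),
    ])
    def test_shape_contract(self, size, shapes):
        model = PCFAN()
        pyr = model.encode(np.zeros((1, 1, size, size)))
        for f, (c, h, w) in zip((pyr.f1, pyr.f2, pyr.f3), shapes):
            assert f.shape == (1, c, h, w)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            PCFAN(SMALL).encode(np.zeros((1, 1, 4, 4)))

    def test_encode_deterministic(self):
        img = np.random.default_rng(3).random((1, 1, 16, 16))
        a = PCFAN(SMALL).encode(img)
        b = PCFAN(SMALL).encode(img)
        assert np.array_equal(a.f3, b.f3)


class TestPCFA:
    def test_block_counts(self):
        model = PCFAN(SMALL)
        assert len(model.attention_blocks) == 4
        assert len(model.upsample_blocks) == 2
        assert model.n_concats == 2

    def test_output_matches_stage1_resolution(self):
        model = PCFAN(SMALL)
        pyr = model.encode(np.zeros((1, 1, 32, 32)))
        fused = model.pcfa_fuse(pyr)
        assert fused.shape == (1, SMALL.stage_channels[0], 32, 32)

    def test_zero_pyramid_zero_output(self):
        model = PCFAN(SMALL)
        c1, c2, c3 = SMALL.stage_channels
        pyr = pcfan.FeaturePyramid(
            f1=np.zeros((1, c1, 16, 16)),
            f2=np.zeros((1, c2, 8, 8)),
            f3=np.zeros((1, c3, 4, 4)))
        for p in [model.fuse_conv.bias]:
            p.data[...] = 0.0
        assert np.allclose(model.pcfa_fuse(pyr), 0.0)

    def test_mismatched_pyramid_rejected(self):
        model = PCFAN(SMALL)
        c1, c2, c3 = SMALL.stage_channels
        pyr = pcfan.FeaturePyramid(
            f1=np.zeros((1, c1, 16, 16)),
            f2=np.zeros((1, c2, 8, 8)),
            f3=np.zeros((1, c3, 5, 5)))
        with pytest.raises(ValueError, match="halve"):
            model.pcfa_fuse(pyr)


class TestReconstruct:
    def test_zero_weights_give_half_gray(self):
        model = PCFAN(SMALL)
        for p in model.recon_conv.parameters():
            p.data[...] = 0.0
        fused = np.random.default_rng(0).random((1, SMALL.stage_channels[0], 8, 8))
        assert np.allclose(model.reconstruct(fused), 0.5)

    def test_full_forward_output_shape_and_range(self):
        model = PCFAN(SMALL)
        out = model.forward(np.random.default_rng(0).random((2, 1, 16, 16)))
        assert out.shape == (2, 1, 16, 16)
        assert out.min() > 0.0 and out.max() < 1.0

    def test_loss_gradient_matches_finite_difference(self):
        model = PCFAN(SMALL)
        img = np.random.default_rng(1).random((1, 1, 8, 8))

        def loss():
            out = model.forward(img)
            return pcfan.mse_loss(img, out)

        out = model.forward(img)
        _, dout = nn.mse_loss_grad(out, img)
        model.zero_grad()
        model.backward(dout)
        p = model.stage2.conv.weight
        idx = (0, 0, 1, 1)
        eps = 1e-6
        orig = p.data[idx]
        p.data[idx] = orig + eps; lp = loss()
        p.data[idx] = orig - eps; lm = loss()
        p.data[idx] = orig
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - p.grad[idx]) / max(abs(fd), 1e-12) < 1e-3


class TestMSELoss:
    def test_identical_images_zero(self, rng):
        img = rng.random((4, 4))
        assert pcfan.mse_loss(img, img) == 0.0

    def test_constant_offset(self):
        a = np.zeros((1, 5, 5))
        assert np.isclose(pcfan.mse_loss(a, a + 0.1), 0.01)

    def test_matches_naive_triple_loop(self, rng):
        a, b = rng.random((2, 6, 6)), rng.random((2, 6, 6))
        total = 0.0
        for c in range(2):
            for i in range(6):
                for j in range(6):
                    total += (a[c, i, j] - b[c, i, j]) ** 2
        assert abs(pcfan.mse_loss(a, b) - total / 72) < 1e-12

    def test_symmetric(self, rng):
        a, b = rng.random((3, 3)), rng.random((3, 3))
        assert pcfan.mse_loss(a, b) == pcfan.mse_loss(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pcfan.mse_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPretraining:
    def test_one_epoch_reproducible(self):
        X, _ = make_phantom_set(3, image_size=32)
        _, h1 = pcfan.pretrain_pcfan(X[:8], SMALL, epochs=1, seed=5)
        _, h2 = pcfan.pretrain_pcfan(X[:8], SMALL, epochs=1, seed=5)
        assert h1.loss.iloc[-1] == h2.loss.iloc[-1]

    def test_zero_learning_rate_constant_loss(self):
        X, _ = make_phantom_set(3, image_size=32)
        _, hist = pcfan.pretrain_pcfan(X[:8], SMALL, epochs=3, lr=0.0, seed=0)
        assert hist.loss.nunique() == 1

    def test_training_reduces_reconstruction_error(self):
        X, _ = make_phantom_set(6, image_size=32)
        model, hist = pcfan.pretrain_pcfan(X, SMALL, epochs=8, seed=0)
        assert hist.loss.iloc[-1] < hist.loss.iloc[0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pcfan.pretrain_pcfan(np.empty((0, 16, 16)), SMALL)
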