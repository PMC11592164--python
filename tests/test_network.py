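"""Architecture contracts: shapes, gating, attention, variants, serialization."""

import numpy as np
import pytest

import lesionmtl as lm
from conftest import TINY_WIDTHS, tiny_model
from lesionmtl import autodiff as ad
from lesionmtl.network import (
    CBAM,
    NetworkConfig,
    ShapeError,
    apply_mask_attention,
    segmentation_probabilities,
)


def rand_input(rng, n=1, h=64, w=64):
    return rng.random((n, 3, h, w), dtype=np.float32)


class TestShapes:
    def test_encoder_stride_arithmetic_64(self, rng):
        model = tiny_model("seg-only")
        feats = model.encoder_forward(ad.Tensor(rand_input(rng)))
        for level, f in enumerate(feats, start=1):
            assert f.shape == (1, TINY_WIDTHS[level - 1], 64 // 2**level, 64 // 2**level)
        assert feats[-1].shape[2:] == (1, 1)

    def test_full_width_bottleneck_192x256(self, rng):
        model = lm.MultiTaskUNet(NetworkConfig.from_variant("seg-only"), seed=0)
        feats = model.encoder_forward(ad.Tensor(rand_input(rng, h=192, w=256)))
        assert feats[-1].shape == (1, 320, 3, 4)
        assert [f.shape[1] for f in feats] == [32, 64, 128, 256, 320, 320]

    def test_non_divisible_input_rejected_before_compute(self, rng):
        model = tiny_model("seg-only")
        with pytest.raises(ShapeError):
            model.encoder_forward(ad.Tensor(rng.random((1, 3, 100, 100), dtype=np.float32)))

    def test_segmentation_head_softmax_contracts(self, rng):
        equal = np.zeros((1, 2, 4, 4), dtype=np.float32)
        np.testing.assert_allclose(segmentation_probabilities(equal).data, 0.5)
        saturated = np.zeros((1, 2, 2, 2), dtype=np.float32)
        saturated[:, 1] = 30.0  # +/-30 logit gap saturates the softmax
        probs = segmentation_probabilities(saturated).data
        assert np.abs(probs[:, 1] - 1.0).max() < 1e-12
        random = rng.normal(size=(2, 2, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(
            segmentation_probabilities(random).data.sum(axis=1), 1.0, atol=1e-6
        )

    def test_segmentation_output_full_resolution_and_normalized(self, rng):
        model = tiny_model("mtl3")
        out = model.forward(rand_input(rng, n=2))
        assert out.seg_prob.shape == (2, 2, 64, 64)
        np.testing.assert_allclose(out.seg_prob.data.sum(axis=1), 1.0, atol=1e-5)
        assert 0.0 <= out.cls_prob.data.min() and out.cls_prob.data.max() <= 1.0


class TestReverseGating:
    def test_reverse_join_off_single_pass(self, rng):
        model = tiny_model("mtl1")
        out = model.forward(rand_input(rng))
        assert out.gates is None
        np.testing.assert_array_equal(out.seg_prob.data, out.seg_prob_pass1.data)

    def test_unit_gates_reproduce_ungated_pass_exactly(self, rng):
        model = tiny_model("mtl2")
        model.eval()
        x = rand_input(rng)
        dw = model.cfg.decoder_widths
        ones = tuple(ad.Tensor(np.ones((1, k), dtype=np.float32)) for k in dw[-2:])
        out = model.forward(x, gate_override=ones)
        np.testing.assert_array_equal(out.seg_prob.data, out.seg_prob_pass1.data)

    def test_gate_lengths_match_last_two_decoder_widths(self, rng):
        model = lm.MultiTaskUNet(NetworkConfig.from_variant("mtl2"), seed=0)
        hidden = ad.Tensor(rng.normal(size=(1, 128)).astype(np.float32))
        g64, g32 = model.compute_reverse_gates(hidden)
        assert g64.shape == (1, 64) and g32.shape == (1, 32)
        for g in (g64, g32):
            assert (g.data > 0).all() and (g.data < 1).all()

    def test_zero_hidden_gives_sigmoid_of_bias(self):
        model = tiny_model("mtl2")
        hidden = ad.Tensor(np.zeros((1, model.cfg.cls_hidden_units), dtype=np.float32))
        g1, g2 = model.compute_reverse_gates(hidden)
        for g, fc in zip((g1, g2), model.gate_fc):
            np.testing.assert_allclose(g.data[0], 1 / (1 + np.exp(-fc.b.data)), atol=1e-6)

    def test_gates_error_when_disabled(self, rng):
        model = tiny_model("mtl1")
        with pytest.raises(ValueError, match="reverse join"):
            model.compute_reverse_gates(ad.Tensor(np.zeros((1, 128))))

    def test_mismatched_gate_length_rejected(self, rng):
        model = tiny_model("mtl2")
        bad = (ad.Tensor(np.ones((1, 5))), ad.Tensor(np.ones((1, 5))))
        with pytest.raises(ValueError, match="gate length"):
            model.forward(rand_input(rng), gate_override=bad)

    def test_half_gates_scale_linear_decoder_multiplicatively(self, rng):
        """Channel gates act as exact multiplicative scalings.

        The decoder is made positively homogeneous: BN frozen to identity,
        biases zeroed, weights non-negative (every ReLU stays linear for the
        non-negative bottleneck input), and the skip inputs zeroed. Gates of
        0.5 on both of the last two levels then scale the segmentation
        logits by exactly 0.25 relative to unit gates.
        """
        model = tiny_model("mtl2")
        model.eval()
        for up, c1, c2 in model.dec_blocks:
            for layer in (up, c1.conv, c2.conv):
                layer.w.data = np.abs(layer.w.data)
                layer.b.data[:] = 0.0
        for layer in (model.final_up, model.seg_head):
            layer.w.data = np.abs(layer.w.data)
            layer.b.data[:] = 0.0
        for bn in model._bn_layers():
            bn.running_mean[:] = 0.0
            bn.running_var[:] = 1.0 - 1e-5
            bn.gamma.data[:] = 1.0
            bn.beta.data[:] = 0.0
        # synthetic encoder pyramid: non-negative bottleneck, zero skips
        w, h = model.cfg.widths, 64
        enc_maps = [
            ad.Tensor(np.zeros((1, w[i], h // 2 ** (i + 1), h // 2 ** (i + 1)), dtype=np.float32))
            for i in range(5)
        ]
        enc_maps.append(ad.Tensor(rng.random((1, w[5], 1, 1), dtype=np.float32)))
        dw = model.cfg.decoder_widths
        ones = tuple(ad.Tensor(np.ones((1, k), dtype=np.float32)) for k in dw[-2:])
        halves = tuple(ad.Tensor(np.full((1, k), 0.5, dtype=np.float32)) for k in dw[-2:])
        _, logits1 = model.decoder_forward(enc_maps, gates=ones)
        _, logits_h = model.decoder_forward(enc_maps, gates=halves)
        np.testing.assert_allclose(logits_h.data, 0.25 * logits1.data, rtol=1e-4, atol=1e-6)


class TestCBAM:
    def test_output_shape_and_gate_range(self, rng):
        cbam = CBAM(8, 4, 7, rng)
        x = ad.Tensor(rng.normal(size=(2, 8, 5, 5)).astype(np.float32))
        out = cbam(x)
        assert out.shape == x.shape

    def test_zero_input_stays_zero(self, rng):
        cbam = CBAM(8, 4, 7, rng)
        x = ad.Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32))
        np.testing.assert_array_equal(cbam(x).data, 0.0)

    def test_spatially_constant_input_constant_spatial_gate(self, rng):
        cbam = CBAM(4, 2, 3, rng)
        x = ad.Tensor(np.broadcast_to(rng.random((1, 4, 1, 1)), (1, 4, 6, 6)).astype(np.float32).copy())
        out = cbam.spatial_attention(x)
        # interior is constant (border differs only through conv padding)
        inner = out.data[:, :, 2:4, 2:4]
        np.testing.assert_allclose(
            inner, np.broadcast_to(inner[:, :, :1, :1], inner.shape), atol=1e-6
        )

    def test_channel_gate_order_follows_channel_magnitude(self, rng):
        """With an identity-initialized perceptron, a channel at twice the
        magnitude of another receives the larger channel gate."""
        cbam = CBAM(2, 1, 3, rng)
        cbam.fc1.w.data = np.eye(2, dtype=np.float32)
        cbam.fc1.b.data[:] = 0.0
        cbam.fc2.w.data = np.eye(2, dtype=np.float32)
        cbam.fc2.b.data[:] = 0.0
        base = rng.random((1, 1, 4, 4), dtype=np.float32) + 0.5
        x = ad.Tensor(np.concatenate([base, 2.0 * base], axis=1))
        gated = cbam.channel_attention(x)
        g = gated.data / x.data
        assert g[0, 1].mean() > g[0, 0].mean()

    def test_even_spatial_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            NetworkConfig.from_variant("mtl3", cbam_spatial_kernel=4)

    def test_reduction_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divide"):
            NetworkConfig.from_variant("mtl3", widths=(4, 8, 8, 8, 10, 10), cbam_reduction=4)


class TestMaskAttention:
    def test_all_ones_map_is_identity(self, rng):
        feat = ad.Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        ones = ad.Tensor(np.ones((1, 1, 64, 64), dtype=np.float32))
        np.testing.assert_allclose(apply_mask_attention(ones, feat).data, feat.data, atol=1e-6)

    def test_all_zeros_map_annihilates(self, rng):
        feat = ad.Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        zeros = ad.Tensor(np.zeros((1, 1, 32, 32), dtype=np.float32))
        np.testing.assert_array_equal(apply_mask_attention(zeros, feat).data, 0.0)

    def test_half_plane_mask_halves_pooled_constant_feature(self):
        feat = ad.Tensor(np.ones((1, 2, 8, 8), dtype=np.float32))
        m = np.zeros((1, 1, 8, 8), dtype=np.float32)
        m[:, :, :, :4] = 1.0
        pooled = ad.global_avg_pool(apply_mask_attention(ad.Tensor(m), feat))
        np.testing.assert_allclose(pooled.data, 0.5, atol=1e-6)


class TestVariants:
    def test_pooled_vector_widths(self):
        assert lm.MultiTaskUNet(NetworkConfig.from_variant("mtl0"), 0).cls_in_dim == 320
        assert lm.MultiTaskUNet(NetworkConfig.from_variant("mtl1"), 0).cls_in_dim == 320 + 64 + 32
        assert lm.MultiTaskUNet(NetworkConfig.from_variant("mtl3"), 0).cls_in_dim == 736

    def test_parameter_count_strictly_increases_along_ladder(self):
        counts = [
            lm.MultiTaskUNet(NetworkConfig.from_variant(v), 0).count_parameters()
            for v in ("seg-only", "mtl0", "mtl1", "mtl2", "mtl3")
        ]
        assert all(a < b for a, b in zip(counts, counts[1:]))
        # classification-head increments are small relative to the backbone
        assert counts[-1] - counts[0] < 0.1 * counts[0]

    def test_flags_off_equals_segmentation_baseline(self):
        bare = lm.MultiTaskUNet(
            NetworkConfig(cls_enabled=False, decoder_to_cls=False, reverse_join=False, cbam=False),
            0,
        )
        seg_only = lm.MultiTaskUNet(NetworkConfig.from_variant("seg-only"), 0)
        assert bare.count_parameters() == seg_only.count_parameters()
        assert [p.data.shape for p in bare.parameters()] == [
            p.data.shape for p in seg_only.parameters()
        ]

    def test_single_conv_parameter_count(self, rng):
        conv = ad.Conv2d(2, 4, 3, 1, rng)
        assert sum(p.data.size for p in conv.parameters()) == 3 * 3 * 2 * 4 + 4

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            NetworkConfig.from_variant("mtl9")


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        model = tiny_model("mtl3", seed=4)
        model.eval()
        x = rand_input(rng, n=2)
        before = model.forward(x)
        path = tmp_path / "ckpt.npz"
        lm.save_checkpoint(model, path)
        restored = lm.load_checkpoint(path)
        after = restored.forward(x)
        np.testing.assert_array_equal(before.seg_prob.data, after.seg_prob.data)
        np.testing.assert_array_equal(before.cls_prob.data, after.cls_prob.data)
        assert restored.cfg == model.cfg
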