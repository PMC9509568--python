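"""Classifier building blocks: activations, losses, pyramid, full network."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from leafclar import nn
from leafclar.nn import ops
from leafclar.model import (
    MFRANet, ModelConfig, AdaptiveSpatialFusion, DetailPath,
    elu, residual_feature_enhancement, smooth_labels, smoothed_cross_entropy,
    softmax, total_loss, weighted_level_fusion,
)


class TestElu:
    def test_closed_form_values(self):
        assert elu(2.0, 1.0) == 2.0
        assert elu(0.0, 1.0) == 0.0
        assert abs(elu(-1.0, 1.0) - (np.exp(-1) - 1)) < 1e-12

    @given(st.floats(-20, 20), st.floats(0.1, 3))
    def test_continuity_and_lower_bound(self, x, alpha):
        y = elu(x, alpha)
        assert y >= -alpha
        # continuity at 0: both branches meet
        assert abs(elu(1e-9, alpha) - elu(-1e-9, alpha)) < 1e-6

    def test_tensor_op_matches_reference(self, rng):
        x = rng.normal(size=(4, 5))
        np.testing.assert_allclose(ops.elu(nn.Tensor(x), 0.7).data,
                                   elu(x, 0.7), atol=1e-6)

    def test_negative_inputs_keep_live_gradients(self, rng):
        """No dead units: the ELU derivative is alpha*e^x > 0 for x < 0."""
        x = nn.Tensor(-np.abs(rng.normal(size=(8, 8))) - 0.1, requires_grad=True)
        ops.elu(x, 1.0).sum().backward()
        assert (x.grad > 0).all()


class TestSoftmaxAndSmoothing:
    def test_uniform_logits_give_uniform_probabilities(self):
        np.testing.assert_allclose(softmax(np.zeros(6)), 1 / 6, atol=1e-12)

    def test_shift_invariance(self, rng):
        z = rng.normal(size=10)
        np.testing.assert_allclose(softmax(z), softmax(z + 7.3), atol=1e-12)

    def test_two_class_closed_form(self):
        np.testing.assert_allclose(softmax(np.array([0.0, np.log(3.0)])),
                                   [0.25, 0.75], atol=1e-12)

    def test_smooth_labels_canonical_case(self):
        np.testing.assert_allclose(smooth_labels(0, 6, 0.1),
                                   [0.9, 0.02, 0.02, 0.02, 0.02, 0.02], atol=1e-12)

    def test_zero_epsilon_is_one_hot(self):
        np.testing.assert_array_equal(smooth_labels(2, 4, 0.0), [0, 0, 1, 0])

    @given(st.integers(2, 12), st.floats(0, 0.99), st.integers(0, 11))
    def test_smoothed_distribution_sums_to_one(self, k, eps, y):
        p = smooth_labels(y % k, k, eps)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            smooth_labels(0, 6, 1.0)


class TestLosses:
    def test_perfect_one_hot_prediction_has_zero_loss(self):
        q = np.array([0, 1.0, 0])
        assert smoothed_cross_entropy(q, 1, 0.0) < 1e-9

    def test_uniform_prediction_loss_is_log_k_for_any_epsilon(self):
        q = np.full(6, 1 / 6)
        for eps in (0.0, 0.1, 0.5):
            assert abs(smoothed_cross_entropy(q, 3, eps) - np.log(6)) < 1e-12

    def test_two_class_hand_value(self):
        got = smoothed_cross_entropy(np.array([0.75, 0.25]), 0, 0.1)
        want = -0.9 * np.log(0.75) - 0.1 * np.log(0.25)
        assert abs(got - want) < 1e-9
        assert abs(want - 0.3975) < 1e-3

    def test_fused_logits_loss_matches_probability_form(self, rng):
        z = rng.normal(size=(3, 6))
        y = np.array([1, 4, 0])
        fused = ops.smoothed_cross_entropy_logits(nn.Tensor(z), y, 0.1).item()
        manual = np.mean([smoothed_cross_entropy(softmax(z[i]), y[i], 0.1)
                          for i in range(3)])
        assert abs(fused - manual) < 1e-6

    def test_total_loss_reduces_to_main_without_aux(self, rng):
        cfg = ModelConfig(aux_weight=0.0)
        z = rng.normal(size=(2, 6))
        y = np.array([0, 5])
        main_only = total_loss(z, [], y, cfg).item()
        with_ignored_aux = total_loss(z, [rng.normal(size=(2, 6))], y, cfg).item()
        plain = ops.smoothed_cross_entropy_logits(nn.Tensor(z), y, cfg.smoothing).item()
        assert main_only == plain == with_ignored_aux

    def test_total_loss_doubles_with_equal_aux(self, rng):
        cfg = ModelConfig(aux_weight=1.0)
        z = rng.normal(size=(2, 6))
        y = np.array([2, 3])
        total = total_loss(z, [z.copy(), z.copy()], y, cfg).item()
        main = total_loss(z, [], y, cfg).item()
        assert abs(total - 2 * main) < 1e-6

    def test_total_loss_never_below_main(self, rng):
        cfg = ModelConfig(aux_weight=0.7)
        z = rng.normal(size=(2, 6))
        y = np.array([1, 1])
        aux = [rng.normal(size=(2, 6)) for _ in range(4)]
        assert total_loss(z, aux, y, cfg).item() >= total_loss(z, [], y, cfg).item()


class TestDetailRoad:
    def test_rfe_constant_input_scales_by_one_plus_weight_sum(self):
        x = np.full((1, 3, 7, 7), 2.0, dtype=np.float32)
        out = residual_feature_enhancement(x, (0.1, 0.2, 0.3))
        np.testing.assert_allclose(out, 1.6 * 2.0, atol=1e-5)

    def test_rfe_zero_weights_is_identity(self, rng):
        x = rng.normal(size=(1, 2, 7, 7)).astype(np.float32)
        np.testing.assert_array_equal(residual_feature_enhancement(x, (0, 0, 0)), x)

    def test_rfe_preserves_shape(self, rng):
        x = rng.normal(size=(2, 4, 7, 7)).astype(np.float32)
        assert residual_feature_enhancement(x).shape == x.shape

    def _toy_detail_path(self):
        cfg = ModelConfig(width_multiplier=1 / 256, n_classes=6)  # widths (1,2,4,8)
        dp = DetailPath(cfg)
        nn.init_parameters(dp, 0)
        return dp, cfg

    @staticmethod
    def _toy_feats(cfg, fill=0.0):
        return [nn.Tensor(np.full((1, c, s, s), fill, np.float32))
                for c, s in zip(cfg.stage_widths, (8, 4, 2, 1))]

    def test_pyramid_zero_inputs_give_zero_pyramid(self):
        dp, cfg = self._toy_detail_path()
        pyr = dp.pyramid(self._toy_feats(cfg))
        for p in pyr.p + pyr.m:
            np.testing.assert_array_equal(p.data, 0.0)

    def test_pyramid_channel_widths_match_config(self):
        cfg = ModelConfig(width_multiplier=0.0625)
        dp = DetailPath(cfg)
        nn.init_parameters(dp, 1)
        feats = [nn.Tensor(np.zeros((1, c, s, s), np.float32))
                 for c, s in zip(cfg.stage_widths, (56, 28, 14, 7))]
        pyr = dp.pyramid(feats)
        for t in pyr.m + pyr.p:
            assert t.shape[1] == cfg.lateral_width

    def test_top_down_propagates_top_level_signal_everywhere(self):
        """A single nonzero pixel in B4 reaches every pyramid level."""
        dp, cfg = self._toy_detail_path()
        # channel-0 identity projections and smoothing convs
        for conv in list(dp.laterals) + list(dp.smooths):
            w = np.zeros_like(conv.weight.data)
            c = conv.kernel // 2
            w[0, 0, c, c] = 1.0
            conv.weight.data = w
            conv.bias.data[:] = 0
        feats = self._toy_feats(cfg)
        feats[3].data[0, 0, 0, 0] = 1.0
        pyr = dp.pyramid(feats)
        for p in pyr.p:
            assert np.abs(p.data).max() > 0.1

    def test_non_halving_dims_rejected(self):
        dp, cfg = self._toy_detail_path()
        feats = [nn.Tensor(np.zeros((1, c, s, s), np.float32))
                 for c, s in zip(cfg.stage_widths, (8, 4, 3, 1))]
        with pytest.raises(ValueError):
            dp.pyramid(feats)


class TestAdaptiveSpatialFusion:
    def test_weights_sum_to_one_per_pixel(self, rng):
        asf = AdaptiveSpatialFusion(3, 4)
        nn.init_parameters(asf, 0)
        feats = [nn.Tensor(rng.normal(size=(2, 3, 7, 7))) for _ in range(4)]
        w = asf.weight_maps(feats).data
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_inputs_fuse_to_themselves(self, rng):
        asf = AdaptiveSpatialFusion(2, 4)
        nn.init_parameters(asf, 1)
        base = rng.normal(size=(1, 2, 7, 7)).astype(np.float32)
        out = asf([nn.Tensor(base.copy()) for _ in range(4)]).data
        np.testing.assert_allclose(out, base, atol=1e-5)

    def test_hand_weighted_fusion_value(self):
        f1 = np.full((1, 1, 1, 1), 4.0)
        f2 = np.full((1, 1, 1, 1), 8.0)
        w = np.array([0.25, 0.75]).reshape(1, 2, 1, 1)
        assert weighted_level_fusion([f1, f2], w)[0, 0, 0, 0] == 7.0

    def test_module_fusion_matches_reference(self, rng):
        asf = AdaptiveSpatialFusion(2, 4)
        nn.init_parameters(asf, 2)
        feats = [rng.normal(size=(1, 2, 7, 7)).astype(np.float32) for _ in range(4)]
        tensors = [nn.Tensor(f) for f in feats]
        w = asf.weight_maps(tensors).data
        np.testing.assert_allclose(asf(tensors).data,
                                   weighted_level_fusion(feats, w), atol=1e-5)

    def test_shape_mismatch_rejected(self, rng):
        asf = AdaptiveSpatialFusion(2, 2)
        nn.init_parameters(asf, 3)
        with pytest.raises(ValueError):
            asf([nn.Tensor(rng.normal(size=(1, 2, 7, 7))),
                 nn.Tensor(rng.normal(size=(1, 2, 6, 6)))])


class TestFullNetwork:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        return MFRANet(ModelConfig(width_multiplier=0.0625, seed=3))

    def test_backbone_b4_is_7x7_and_logits_length_6(self, tiny_model, rng):
        x = rng.normal(0, 0.3, (1, 3, 224, 224)).astype(np.float32)
        with nn.no_grad():
            feats = tiny_model.backbone(nn.Tensor(x))
            logits, aux, probs = tiny_model(x)
        assert feats[3].shape[-2:] == (7, 7)
        assert [f.shape[-1] for f in feats] == [56, 28, 14, 7]
        assert logits.shape == (1, 6) and len(aux) == 4
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_full_width_channel_counts_are_resnet50(self):
        cfg = ModelConfig(width_multiplier=1.0)
        assert cfg.stage_widths == (256, 512, 1024, 2048)

    def test_eval_forward_is_deterministic(self, tiny_model, rng):
        x = rng.normal(0, 0.3, (1, 3, 224, 224)).astype(np.float32)
        tiny_model.eval()
        with nn.no_grad():
            a = tiny_model(x)[0].data
            b = tiny_model(x)[0].data
        np.testing.assert_array_equal(a, b)

    def test_wrong_input_size_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model(np.zeros((1, 3, 96, 96), np.float32))

    def test_reduced_model_has_fewer_parameters(self):
        small = MFRANet(ModelConfig(width_multiplier=0.0625, seed=0))
        bigger = MFRANet(ModelConfig(width_multiplier=0.125, seed=0))
        assert small.num_parameters() < bigger.num_parameters()

    def test_checkpoint_roundtrip_rejects_config_mismatch(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        clone = MFRANet.load(path)
        np.testing.assert_array_equal(clone.fc.weight.data, tiny_model.fc.weight.data)
        with pytest.raises(ValueError):
            MFRANet.load(path, expected_config=ModelConfig(width_multiplier=0.5))
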