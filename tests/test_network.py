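"""Unit tests for the network components: fusion, attention, pooling
integration, encoder/decoder shape contracts."""

import numpy as np
import pytest

from ddunet.model import (
    DualDecoderUNet, ModelConfig, attention_mask_from_coarse, eam_classify,
    eam_initial_mask, eam_refine, fast_normalized_fusion, fuse_outputs,
)
from ddunet.nn import Tensor
from ddunet.nn import functional as F

RNG = np.random.default_rng(3)


class TestFastNormalizedFusion:
    def test_hand_value_equal_weights_on_zero_and_one(self):
        out = fast_normalized_fusion(
            [Tensor(np.zeros((2, 2))), Tensor(np.ones((2, 2)))],
            Tensor(np.array([1.0, 1.0])))
        assert out.data[0, 0] == pytest.approx(1.0 / (2 + 1e-4), abs=1e-12)

    def test_identical_constant_inputs_nearly_preserved(self):
        v = 0.73
        out = fast_normalized_fusion(
            [Tensor(np.full((3, 3), v)), Tensor(np.full((3, 3), v))],
            Tensor(np.array([0.4, 2.0])))
        np.testing.assert_allclose(out.data, v * 2.4 / (2.4 + 1e-4), rtol=1e-12)

    def test_negative_weight_input_has_no_influence(self):
        a, b = Tensor(RNG.normal(size=(4, 4))), Tensor(RNG.normal(size=(4, 4)))
        out = fast_normalized_fusion([a, b], Tensor(np.array([1.0, -5.0])))
        np.testing.assert_allclose(out.data, a.data * (1.0 / (1.0 + 1e-4)),
                                   rtol=1e-12)

    def test_shape_and_arity_validation(self):
        with pytest.raises(ValueError):
            fast_normalized_fusion([Tensor(np.zeros(3))], Tensor(np.ones(2)))
        with pytest.raises(ValueError):
            fast_normalized_fusion([Tensor(np.zeros(3)), Tensor(np.zeros(4))],
                                   Tensor(np.ones(2)))


class TestEAM:
    def test_zero_candidates_give_half_everywhere(self):
        out = eam_initial_mask(np.zeros((2, 8)), RNG.normal(size=(5, 8)))
        np.testing.assert_array_equal(out.data, np.full((2, 5), 0.5))

    def test_initial_mask_matches_looped_product(self):
        T = RNG.normal(size=(3, 4)) * 0.3
        Q = RNG.normal(size=(6, 4)) * 0.3
        out = eam_initial_mask(T, Q).data
        for a in range(3):
            for p in range(6):
                acc = sum(T[a, d] * Q[p, d] for d in range(4))
                assert out[a, p] == pytest.approx(1 / (1 + np.exp(-acc)), abs=1e-12)

    def test_scaled_candidates_saturate_by_sign(self):
        T = RNG.normal(size=(2, 4))
        Q = RNG.normal(size=(5, 4))
        raw = T @ Q.T
        out = eam_initial_mask(T * 1e4, Q).data
        np.testing.assert_allclose(out, (raw > 0).astype(float), atol=1e-12)

    def test_refine_unmasked_rows_sum_to_one(self):
        from ddunet.nn import softmax
        T = Tensor(RNG.normal(size=(2, 4)))
        Q = Tensor(RNG.normal(size=(7, 4)))
        Mq, Mk, Mv = (Tensor(RNG.normal(size=(4, 4))) for _ in range(3))
        scores = (T @ Mq) @ (Q @ Mk).transpose(1, 0)
        attn = softmax(scores, axis=-1,
                       additive_mask=attention_mask_from_coarse(np.ones((2, 7))))
        np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-12)

    def test_refine_single_unmasked_position_returns_its_value(self):
        T = Tensor(RNG.normal(size=(2, 4)))
        Q = Tensor(RNG.normal(size=(7, 4)))
        Mq, Mk = Tensor(RNG.normal(size=(4, 4))), Tensor(RNG.normal(size=(4, 4)))
        Mv = Tensor(RNG.normal(size=(4, 4)))
        a = np.zeros((2, 7))
        a[:, 3] = 1.0
        out = eam_refine(T, Q, a, Mq, Mk, Mv)
        expected = T.data + (Q.data @ Mv.data)[3]
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_refine_zero_value_projection_is_identity(self):
        T = Tensor(RNG.normal(size=(2, 4)))
        Q = Tensor(RNG.normal(size=(7, 4)))
        Mq, Mk = Tensor(RNG.normal(size=(4, 4))), Tensor(RNG.normal(size=(4, 4)))
        out = eam_refine(T, Q, np.ones((2, 7)), Mq, Mk, Tensor(np.zeros((4, 4))))
        np.testing.assert_allclose(out.data, T.data, atol=1e-12)

    def test_empty_coarse_mask_falls_back_to_unmasked(self):
        add = attention_mask_from_coarse(np.zeros((2, 5)))
        np.testing.assert_array_equal(add, np.zeros((2, 5)))

    def test_classify_argmax_and_tie_break(self):
        L, labels = eam_classify(np.array([[3.2, -1.0], [0.5, 0.5]]),
                                 Tensor(np.eye(2)))
        assert labels.tolist() == [0, 0]  # row 2 ties -> lowest index
        L2, labels2 = eam_classify(np.array([[0.1, 2.0]]), Tensor(np.eye(2)))
        assert labels2.tolist() == [1]


class TestFuseOutputs:
    def test_zero_logits_give_half_in_verbatim(self):
        z = Tensor(np.zeros((2, 2)))
        np.testing.assert_array_equal(fuse_outputs(z, z, "verbatim").data,
                                      np.full((2, 2), 0.5))

    def test_complement_saturates_to_confident_foreground(self):
        mf = Tensor(np.full((2, 2), 50.0))
        mb = Tensor(np.full((2, 2), -50.0))
        np.testing.assert_allclose(fuse_outputs(mf, mb, "complement").data, 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(fuse_outputs(mb, mf, "complement").data, 0.0,
                                   atol=1e-12)

    def test_verbatim_degenerates_for_complementary_decoders(self):
        mf = Tensor(np.full((3, 3), 80.0))
        mb = Tensor(np.full((3, 3), -80.0))
        np.testing.assert_allclose(fuse_outputs(mf, mb, "verbatim").data, 0.5,
                                   atol=1e-12)

    def test_outputs_always_in_unit_interval(self):
        mf = Tensor(RNG.normal(scale=10, size=(8, 8)))
        mb = Tensor(RNG.normal(scale=10, size=(8, 8)))
        for mode in ("verbatim", "complement"):
            o = fuse_outputs(mf, mb, mode).data
            assert o.min() >= 0.0 and o.max() <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_outputs(Tensor(np.zeros((2, 2))), Tensor(np.zeros((3, 3))))


class TestPoolingIntegration:
    def test_average_pool_plateau_from_impulse(self):
        x = np.zeros((1, 1, 7, 7))
        x[0, 0, 3, 3] = 1.0
        out = F.avgpool2d(Tensor(x)).data
        np.testing.assert_allclose(out[0, 0, 2:5, 2:5], np.full((3, 3), 1 / 9),
                                   atol=1e-12)
        assert out.sum() == pytest.approx(1.0)

    def test_average_pool_constant_interior_identity(self):
        out = F.avgpool2d(Tensor(np.full((1, 1, 6, 6), 0.4))).data
        np.testing.assert_allclose(out[0, 0, 1:-1, 1:-1], 0.4, atol=1e-12)

    def test_mismatched_resolutions_rejected(self):
        from ddunet.model import PoolingIntegration
        pil = PoolingIntegration(2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            pil(Tensor(np.zeros((1, 2, 8, 8))), Tensor(np.zeros((1, 2, 4, 4))))


class TestEncoderAndModel:
    def test_default_config_bottleneck_arithmetic(self):
        cfg = ModelConfig()
        assert cfg.bottleneck_channels == 1024
        assert cfg.input_size // 2 ** cfg.n_downsamples == 32

    def test_tiny_encoder_pyramid_shapes_halve_per_level(self):
        cfg = ModelConfig.tiny(64)
        m = DualDecoderUNet(cfg).eval()
        pyramid, bott = m.encoder(Tensor(RNG.random((1, 1, 64, 64))))
        sizes = {i: pyramid[i].shape[-1] for i in sorted(pyramid)}
        assert sizes == {0: 64, 1: 32, 2: 16, 3: 8}
        assert bott.shape == (1, 32, 8, 8)  # 2 * last width at /2^3

    def test_doubling_input_doubles_every_tier(self):
        cfg = ModelConfig.tiny(128)
        m = DualDecoderUNet(cfg).eval()
        pyramid, _ = m.encoder(Tensor(RNG.random((1, 1, 128, 128))))
        assert [pyramid[i].shape[-1] for i in sorted(pyramid)] == [128, 64, 32, 16]

    def test_indivisible_input_rejected_before_compute(self):
        m = DualDecoderUNet(ModelConfig.tiny(64)).eval()
        with pytest.raises(ValueError, match="divisible"):
            m.encoder(Tensor(RNG.random((1, 1, 60, 60))))
        with pytest.raises(ValueError):
            ModelConfig(input_size=100)

    def test_zero_weights_give_zero_encoder_outputs(self):
        m = DualDecoderUNet(ModelConfig.tiny(64)).eval()
        for _, p in m.encoder.named_parameters():
            if p.ndim >= 2:  # conv kernels; leave BN scale/shift
                p.data = np.zeros_like(p.data)
        for _, p in m.encoder.named_parameters():
            if p.ndim == 1:
                p.data = np.zeros_like(p.data)
        pyramid, bott = m.encoder(Tensor(RNG.random((1, 1, 64, 64))))
        assert all(np.abs(pyramid[i].data).max() == 0 for i in pyramid)
        assert np.abs(bott.data).max() == 0

    def test_identical_decoder_weights_give_identical_maps(self):
        m = DualDecoderUNet(ModelConfig.tiny(64)).eval()
        m.decoder_bg.load_state_dict(m.decoder_fg.state_dict())
        out = m(RNG.random((1, 1, 64, 64)))
        np.testing.assert_array_equal(out.M_F.data, out.M_B.data)

    def test_same_seed_builds_identical_models(self):
        a = DualDecoderUNet(ModelConfig.tiny(64, seed=5))
        b = DualDecoderUNet(ModelConfig.tiny(64, seed=5))
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_forward_output_contract(self):
        m = DualDecoderUNet(ModelConfig.tiny(64)).eval()
        out = m(RNG.random((2, 1, 64, 64)))
        for t in (out.M_F, out.M_B, out.O_Final):
            assert t.shape == (2, 1, 64, 64)
        assert out.O_Final.data.min() >= 0.0 and out.O_Final.data.max() <= 1.0
        assert out.eam is not None and out.eam["fg_map"].shape == (2, 1, 8, 8)
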