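import numpy as np
import pytest

from skelmotion import ModelConfig, nn
from skelmotion.datp_core import (
    ASWHead,
    DATPModel,
    ResidualFFN,
    ScaleSpec,
    TransformerBlock,
    asw_fuse,
    crop_to_original,
    cross_attention_fuse,
    datp_forward,
    default_scale_spec,
    inverse_recompose,
    preprocess_sequence,
    temporal_segment,
    train_datp,
)
from skelmotion.skeleton_io import ValidationError
from skelmotion.synthetic_motion import MotionParams, apply_occlusion, gen_pose_sequence


class TestScaleSpec:
    def test_default_for_81(self):
        assert default_scale_spec(5).segment_lengths == (81, 27, 9, 3, 1)

    def test_cap_at_length(self):
        assert default_scale_spec(5, length=24).segment_lengths == (24, 24, 9, 3, 1)

    def test_n_segments(self):
        spec = ScaleSpec((3,))
        assert spec.n_segments(12, 0) == 4
        with pytest.raises(ValidationError):
            spec.n_segments(13, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ScaleSpec(())


class TestResidualFFN:
    def test_zero_init_identity(self, rng):
        block = ResidualFFN(4, 8, rng, zero_init=True)
        x = rng.normal(size=(6, 4))
        np.testing.assert_allclose(block(nn.Tensor(x)).numpy(), x, atol=1e-12)

    def test_shape_contract(self, rng):
        block = ResidualFFN(25, 64, rng)
        assert block(nn.Tensor(rng.normal(size=(91, 25)))).shape == (91, 25)

    def test_hand_computation(self, rng):
        block = ResidualFFN(2, 2, rng)
        x = rng.normal(size=(1, 2))
        mu, var = x.mean(), x.var()
        normed = (x - mu) / np.sqrt(var + 1e-5)
        h = np.maximum(normed @ block.ffn.fc1.weight.numpy() + block.ffn.fc1.bias.numpy(), 0)
        expected = x + h @ block.ffn.fc2.weight.numpy() + block.ffn.fc2.bias.numpy()
        np.testing.assert_allclose(block(nn.Tensor(x)).numpy(), expected, atol=1e-10)

    def test_nan_rejected_downstream(self, rng):
        block = ResidualFFN(2, 2, rng)
        out = block(nn.Tensor(np.full((1, 2), np.nan)))
        assert np.isnan(out.numpy()).any()  # propagates; callers validate


class TestProjectStream:
    def test_identity_1x1_conv(self, rng):
        conv = nn.Conv1d(3, 3, 1, rng)
        conv.weight.data[0] = np.eye(3)
        conv.bias.data[...] = 0.0
        x = rng.normal(size=(10, 3))
        np.testing.assert_allclose(conv(nn.Tensor(x)).numpy(), x, atol=1e-12)

    def test_same_padding_length(self, rng):
        conv = nn.Conv1d(25, 32, 3, rng)
        assert conv(nn.Tensor(rng.normal(size=(91, 25)))).shape == (91, 32)

    def test_difference_kernel_on_ramp(self, rng):
        conv = nn.Conv1d(1, 1, 3, rng)
        conv.weight.data[:, 0, 0] = [1.0, 0.0, -1.0]
        conv.bias.data[...] = 0.0
        ramp = np.arange(8.0)[:, None]
        out = conv(nn.Tensor(ramp)).numpy().ravel()
        # interior: (t-1) - (t+1) = -2 with this tap ordering
        np.testing.assert_allclose(out[1:-1], -2.0, atol=1e-12)


class TestCrossAttentionFuse:
    def test_single_token(self, rng):
        e1 = rng.normal(size=(1, 4))
        e2 = rng.normal(size=(1, 4))
        np.testing.assert_allclose(cross_attention_fuse(e1, e2), e2, atol=1e-12)

    def test_zero_queries_give_column_mean(self, rng):
        e2 = rng.normal(size=(5, 3))
        out = cross_attention_fuse(np.zeros((2, 3)), e2)
        np.testing.assert_allclose(out, np.tile(e2.mean(axis=0), (2, 1)), atol=1e-12)

    def test_hand_value(self):
        out = cross_attention_fuse(np.array([[1.0]]), np.array([[1.0], [2.0]]))
        assert out[0, 0] == pytest.approx(1.7311, abs=1e-4)

    def test_rows_sum_to_one_and_convex(self, rng):
        for _ in range(200):
            n1, n2, d = rng.integers(1, 6), rng.integers(1, 6), rng.integers(1, 5)
            e1 = rng.normal(size=(n1, d)) * 2
            e2 = rng.normal(size=(n2, d)) * 2
            fused, attn = cross_attention_fuse(e1, e2, return_attention=True)
            np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-6)
            assert (fused <= e2.max(axis=0) + 1e-9).all()
            assert (fused >= e2.min(axis=0) - 1e-9).all()

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            e1 = rng.normal(size=(3, 2))
            e2 = rng.normal(size=(4, 2))
            scores = np.zeros((3, 4))
            for i in range(3):
                for k in range(4):
                    scores[i, k] = e1[i] @ e2[k] / np.sqrt(2)
            expected = np.zeros((3, 2))
            for i in range(3):
                w = np.exp(scores[i])
                w /= w.sum()
                for k in range(4):
                    expected[i] += w[k] * e2[k]
            np.testing.assert_allclose(cross_attention_fuse(e1, e2), expected, atol=1e-8)

    def test_dim_mismatch(self, rng):
        with pytest.raises(ValidationError):
            cross_attention_fuse(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)))


class TestCrop:
    def test_p0_identity(self, rng):
        x = rng.normal(size=(7, 2))
        np.testing.assert_array_equal(crop_to_original(x, 0), x)

    def test_91_to_81(self):
        x = np.arange(91.0)[:, None]
        out = crop_to_original(x, 5)
        assert out.shape[0] == 81
        assert out[0, 0] == 5.0

    def test_index_bookkeeping(self):
        labels = np.arange(20.0)
        for p in range(1, 9):
            np.testing.assert_array_equal(crop_to_original(labels, p),
                                          np.arange(p, 20 - p))

    def test_too_small(self):
        with pytest.raises(ValidationError):
            crop_to_original(np.zeros((4, 1)), 2)


class TestSegmentRecompose:
    def test_full_segment(self, rng):
        x = rng.normal(size=(6, 3))
        segs = temporal_segment(x, 6)
        assert segs.shape == (1, 6, 3)
        np.testing.assert_array_equal(segs[0], x)

    def test_unit_segments(self, rng):
        x = rng.normal(size=(5, 2))
        assert temporal_segment(x, 1).shape == (5, 1, 2)

    def test_index_oracle(self):
        x = np.arange(6.0)[:, None]
        segs = temporal_segment(x, 3)
        np.testing.assert_array_equal(segs[:, :, 0], [[0, 1, 2], [3, 4, 5]])
        np.testing.assert_array_equal(inverse_recompose(segs), x)

    @pytest.mark.parametrize("f", [6, 12, 24])
    def test_identity_for_every_divisor(self, f, rng):
        x = rng.normal(size=(f, 4))
        for s in range(1, f + 1):
            if f % s == 0:
                np.testing.assert_array_equal(
                    inverse_recompose(temporal_segment(x, s)), x)

    def test_non_divisible_raises(self, rng):
        with pytest.raises(ValidationError):
            temporal_segment(rng.normal(size=(7, 2)), 3)


class TestTransformerBlock:
    def test_zero_init_identity(self, rng):
        block = TransformerBlock(8, 2, 16, rng, zero_init=True)
        x = rng.normal(size=(5, 8))
        np.testing.assert_allclose(block(nn.Tensor(x)).numpy(), x, atol=1e-12)

    def test_shape_preserved(self, rng):
        block = TransformerBlock(8, 2, 16, rng)
        assert block(nn.Tensor(rng.normal(size=(81, 8)))).shape == (81, 8)

    def test_locality_of_segmented_attention(self, rng):
        # perturbing one frame in segment 0 leaves other segments bit-identical
        block = TransformerBlock(4, 2, 8, rng)
        x = rng.normal(size=(4, 3, 4))  # 4 segments of 3 frames
        out1 = block(nn.Tensor(x)).numpy()
        x2 = x.copy()
        x2[0, 1] += 5.0
        out2 = block(nn.Tensor(x2)).numpy()
        np.testing.assert_array_equal(out1[1:], out2[1:])
        assert np.abs(out1[0] - out2[0]).max() > 0

    def test_single_token_segments_reduce_to_residual(self, rng):
        # with s=1 attention over one token passes the value path through
        block = TransformerBlock(4, 1, 8, rng)
        x = rng.normal(size=(3, 1, 4))
        out = block(nn.Tensor(x)).numpy()
        # oracle: softmax over a single logit is 1 -> attn output = Wo(Wv(LN(x)))
        for i in range(3):
            xi = x[i]
            mu, var = xi.mean(axis=-1, keepdims=True), xi.var(axis=-1, keepdims=True)
            ln1 = (xi - mu) / np.sqrt(var + 1e-5) * block.norm1.gamma.numpy() \
                + block.norm1.beta.numpy()
            v = ln1 @ block.attn.wv.weight.numpy() + block.attn.wv.bias.numpy()
            att = v @ block.attn.wo.weight.numpy() + block.attn.wo.bias.numpy()
            inner = xi + att
            mu2 = inner.mean(axis=-1, keepdims=True)
            var2 = inner.var(axis=-1, keepdims=True)
            ln2 = (inner - mu2) / np.sqrt(var2 + 1e-5) * block.norm2.gamma.numpy() \
                + block.norm2.beta.numpy()
            h = np.maximum(ln2 @ block.mlp.fc1.weight.numpy()
                           + block.mlp.fc1.bias.numpy(), 0)
            expected = xi + h @ block.mlp.fc2.weight.numpy() + block.mlp.fc2.bias.numpy()
            np.testing.assert_allclose(out[i], expected, atol=1e-10)


class TestASW:
    def test_zero_mlp_gives_half(self, rng):
        head = ASWHead(4, rng)
        for p in head.parameters():
            p.data[...] = 0.0
        alpha = head(nn.Tensor(rng.normal(size=4))).numpy()
        np.testing.assert_allclose(alpha, 0.5)

    def test_range(self, rng):
        head = ASWHead(4, rng)
        for _ in range(20):
            a = head(nn.Tensor(rng.normal(size=4) * 10)).numpy()
            assert 0.0 < a[0] < 1.0

    def test_sigmoid_of_unit_logit(self, rng):
        # configure the head so the pre-sigmoid logit is exactly 1:
        # alpha must equal sigmoid(1) = 0.731059
        head = ASWHead(1, rng)
        head.mlp.fc1.weight.data[...] = 0.0
        head.mlp.fc1.bias.data[...] = 0.0
        head.mlp.fc2.weight.data[...] = 0.0
        head.mlp.fc2.bias.data[...] = 1.0
        alpha = head(nn.Tensor(np.array([3.7]))).numpy()
        np.testing.assert_allclose(alpha, 0.731059, atol=1e-6)

    def test_fuse_single_scale(self, rng):
        f = rng.normal(size=(4, 3))
        np.testing.assert_array_equal(asw_fuse([f], [1.0]), f)

    def test_fuse_zero_weights(self, rng):
        f = rng.normal(size=(4, 3))
        np.testing.assert_array_equal(asw_fuse([f, f], [0.0, 0.0]), np.zeros_like(f))

    def test_fuse_hand_value(self):
        out = asw_fuse([np.array([[2.0]]), np.array([[4.0]])], [0.25, 0.75])
        assert out[0, 0] == pytest.approx(3.5)

    def test_fuse_matches_loop_oracle(self, rng):
        for _ in range(100):
            d = int(rng.integers(1, 5))
            feats = [rng.normal(size=(3, 2)) for _ in range(d)]
            alphas = rng.uniform(size=d)
            expected = sum(a * f for a, f in zip(alphas, feats))
            np.testing.assert_allclose(asw_fuse(feats, alphas), expected, atol=1e-12)

    def test_fuse_shape_mismatch(self, rng):
        with pytest.raises(ValidationError):
            asw_fuse([rng.normal(size=(2, 2)), rng.normal(size=(3, 2))], [0.5, 0.5])


class TestForward:
    def test_output_has_input_frame_count(self, layout, toy_config, small_pair):
        seq2d, _ = small_pair
        model = DATPModel(layout, toy_config, max_len=64)
        out = datp_forward(model, seq2d, toy_config)
        assert out.coords.shape == (12, 17, 3)
        assert np.isfinite(out.coords).all()

    def test_determinism(self, layout, toy_config, small_pair):
        seq2d, _ = small_pair
        model = DATPModel(layout, toy_config, max_len=64)
        a = datp_forward(model, seq2d, toy_config)
        b = datp_forward(model, seq2d, toy_config)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_regress_head_shapes(self, layout, toy_config, rng):
        model = DATPModel(layout, toy_config, max_len=64)
        out = model.head(nn.Tensor(rng.normal(size=(12, toy_config.unified_dim))))
        assert out.shape == (12, 17 * 3)

    def test_zero_head_gives_zero_pose(self, layout, toy_config, small_pair):
        seq2d, _ = small_pair
        model = DATPModel(layout, toy_config, max_len=64)
        model.head.weight.data[...] = 0.0
        model.head.bias.data[...] = 0.0
        out = datp_forward(model, seq2d, toy_config)
        np.testing.assert_array_equal(out.coords, 0.0)

    def test_gradient_flows_to_every_weight(self, layout):
        cfg = ModelConfig(dm=8, df=16, attention_heads=4, n_scales=2,
                          segment_lengths=(12, 4), pad=3, seed=1)
        lay5 = __import__("skelmotion").skeleton_io.JointLayout(
            ("a", "b", "c", "d", "e"), (-1, 0, 1, 1, 3))
        seq3d, seq2d = gen_pose_sequence(lay5, MotionParams(n_frames=12, seed=2))
        model = DATPModel(lay5, cfg, max_len=32)
        coords, pad = preprocess_sequence(seq2d, cfg)
        pred = model.forward(coords, pad)
        loss = ((pred - nn.Tensor(seq3d.coords)) ** 2.0).mean()
        loss.backward()
        for p in model.parameters():
            assert p.grad is not None
            assert np.abs(p.grad).sum() > 0 or p.data.size == 0

    def test_non_divisible_scale_handled(self, layout):
        # F=10 with segment 4 requires internal edge padding
        cfg = ModelConfig(dm=8, df=16, attention_heads=4, n_scales=2,
                          segment_lengths=(10, 4), pad=2, seed=1)
        seq3d, seq2d = gen_pose_sequence(layout, MotionParams(n_frames=10, seed=3))
        model = DATPModel(layout, cfg, max_len=32)
        out = datp_forward(model, seq2d, cfg)
        assert out.coords.shape == (10, 17, 3)


class TestPreprocess:
    def test_tlsi_ablation_zero_fills(self, layout):
        _, seq2d = gen_pose_sequence(layout, MotionParams(n_frames=10, seed=3))
        occ = apply_occlusion(seq2d, 4, seed=4)
        cfg = ModelConfig(dm=8, df=16, attention_heads=4, n_scales=2,
                          segment_lengths=(10, 2), pad=0, seed=1)
        coords, _ = preprocess_sequence(occ, cfg, ablate={"tlsi"})
        np.testing.assert_array_equal(coords[~occ.observed], 0.0)

    def test_ttep_ablation_no_padding(self, layout):
        _, seq2d = gen_pose_sequence(layout, MotionParams(n_frames=10, seed=3))
        cfg = ModelConfig(dm=8, df=16, attention_heads=4, n_scales=2,
                          segment_lengths=(10, 2), pad=4, seed=1)
        coords, pad = preprocess_sequence(seq2d, cfg, ablate={"ttep"})
        assert pad == 0
        assert coords.shape[0] == 10

    def test_confidence_ablation_changes_imputation(self, layout):
        _, seq2d = gen_pose_sequence(layout, MotionParams(n_frames=14, seed=3))
        occ = apply_occlusion(seq2d, 5, seed=4)
        occ.confidence[occ.observed] = np.random.default_rng(0).uniform(
            0.1, 0.9, size=int(occ.observed.sum()))
        cfg = ModelConfig(dm=8, df=16, attention_heads=4, n_scales=2,
                          segment_lengths=(14, 2), pad=0, seed=1)
        with_conf, _ = preprocess_sequence(occ, cfg)
        without_conf, _ = preprocess_sequence(occ, cfg, ablate={"confidence"})
        assert np.abs(with_conf - without_conf).max() > 0


class TestTraining:
    def test_empty_dataset(self, layout, toy_config):
        with pytest.raises(ValidationError, match="empty"):
            train_datp([], layout, toy_config)

    def test_zero_lr_constant_history(self, layout, toy_config, small_pair):
        seq2d, seq3d = small_pair
        cfg = ModelConfig(**{**toy_config.__dict__, "learning_rate": 0.0, "epochs": 3})
        _, history = train_datp([(seq2d, seq3d)], layout, cfg)
        losses = [h["loss"] for h in history]
        assert losses[0] == pytest.approx(losses[-1])

    def test_lr_decay_applied(self, layout, toy_config, small_pair):
        seq2d, seq3d = small_pair
        _, history = train_datp([(seq2d, seq3d)], layout, toy_config)
        assert history[1]["lr"] == pytest.approx(history[0]["lr"] * 0.95)

    def test_loss_decreases(self, layout, small_pair):
        seq2d, seq3d = small_pair
        cfg = ModelConfig(dm=8, df=16, attention_heads=4, n_scales=2,
                          segment_lengths=(12, 4), pad=3, epochs=15, seed=0)
        _, history = train_datp([(seq2d, seq3d)], layout, cfg)
        assert history[-1]["loss"] < history[0]["loss"]

    def test_horizontal_flip_augmentation(self, layout, small_pair):
        from skelmotion.skeleton_io import H36M_FLIP_PAIRS

        seq2d, seq3d = small_pair
        cfg = ModelConfig(dm=8, df=16, attention_heads=4, n_scales=2,
                          segment_lengths=(12, 4), pad=3, epochs=2, seed=0,
                          horizontal_flip=True)
        _, history = train_datp([(seq2d, seq3d)], layout, cfg,
                                flip_pairs=H36M_FLIP_PAIRS)
        assert np.isfinite(history[-1]["loss"])

    def test_flip_requires_pairs(self, layout, small_pair):
        seq2d, seq3d = small_pair
        cfg = ModelConfig(dm=8, df=16, attention_heads=4, n_scales=2,
                          segment_lengths=(12, 4), pad=3, epochs=1, seed=0,
                          horizontal_flip=True)
        with pytest.raises(ValidationError, match="flip_pairs"):
            train_datp([(seq2d, seq3d)], layout, cfg)
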