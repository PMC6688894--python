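import numpy as np
import pytest

from cineqc import (
    ModelSpec, TrainConfig, augment_gaussian_blur, augment_translation,
    binary_cross_entropy, build_model, inverse_frequency_weights, predict, train,
)
from cineqc.classifiers import Trainer, encode_dataset
from cineqc.nn import Dense, LSTMLast
from cineqc.phantom import CineSequence


class TestBuildModel:
    def test_3dcnn_has_two_dense_layers_of_spec_widths(self):
        spec = ModelSpec("3dcnn", input_shape=(32, 32, 16), conv_channels=(2, 2, 2, 2, 2, 2),
                         fc_width=1024)
        state = build_model(spec, seed=0)
        dense = [l for l in state.net.layers if isinstance(l, Dense)]
        assert len(dense) == 2
        assert dense[0].w.shape[1] == 1024
        assert dense[1].w.shape == (1024, 2)

    def test_3dcnn_layer_counts(self):
        from cineqc.nn import Conv3d, MaxPool3d
        spec = ModelSpec.tiny("3dcnn", (32, 32, 16))
        state = build_model(spec, seed=0)
        assert sum(isinstance(l, Conv3d) for l in state.net.layers) == 6
        assert sum(isinstance(l, MaxPool3d) for l in state.net.layers) == 4

    def test_lrcn_feature_extractor_counts_and_fixed_length_features(self):
        from cineqc.nn import Conv2d, MaxPool2d
        spec = ModelSpec.tiny("lrcn", (16, 16, 4))
        state = build_model(spec, seed=0)
        assert sum(isinstance(l, Conv2d) for l in state.net.features.layers) == 6
        assert sum(isinstance(l, MaxPool2d) for l in state.net.features.layers) == 3
        x = np.random.default_rng(0).normal(size=(3 * 4, 1, 16, 16)).astype(np.float32)
        feats = state.net.features.forward(x)
        assert feats.ndim == 2 and feats.shape[0] == 12
        assert isinstance(state.net.lstm, LSTMLast)

    def test_seeded_initialisation_is_deterministic(self):
        spec = ModelSpec.tiny("lrcn", (16, 16, 4))
        a = build_model(spec, seed=3)
        b = build_model(spec, seed=3)
        for pa, pb in zip(a.net.params(), b.net.params()):
            assert np.array_equal(pa, pb)

    def test_incompatible_pooling_depth_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec.tiny("3dcnn", (16, 16, 6))   # time dim dies after 3 pools


class TestBinaryCrossEntropy:
    def test_perfect_prediction_is_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert binary_cross_entropy(y, y) <= 1e-6

    def test_half_confidence_is_ln2(self):
        assert np.isclose(binary_cross_entropy([1.0], [0.5]), np.log(2), rtol=1e-9)

    def test_two_sample_closed_form(self):
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert np.isclose(binary_cross_entropy([1.0, 0.0], [0.9, 0.2]), expected, rtol=1e-12)

    def test_unit_weights_reduce_to_unweighted_exactly(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        p = np.array([0.7, 0.3, 0.9, 0.6])
        assert binary_cross_entropy(y, p, class_weights=np.ones(2)) == binary_cross_entropy(y, p)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            binary_cross_entropy([1.0, 0.0], [0.5])

    def test_inverse_frequency_ratio(self):
        y = np.array([0] * 224 + [1] * 10)
        w = inverse_frequency_weights(y)
        assert np.isclose(w[1] / w[0], 22.4)
        assert w[0] == 1.0


class TestTraining:
    def test_separable_set_loss_decreases_and_fits(self, separable_batch):
        spec = ModelSpec.tiny("lrcn", (16, 16, 6))
        state = build_model(spec, seed=0)
        cfg = TrainConfig(batch_size=8, learning_rate=0.05, patience=100,
                          max_epochs=60, seed=0)
        state = train(state, separable_batch[4:], separable_batch[:4], cfg)
        losses = [r["train_loss"] for r in state.training_log]
        first_five = losses[:5]
        assert all(a > b for a, b in zip(first_five, first_five[1:]))
        assert state.training_log[-1]["train_accuracy"] == 1.0

    def test_patience_zero_runs_exactly_one_epoch(self, separable_batch):
        spec = ModelSpec.tiny("lrcn", (16, 16, 6))
        state = build_model(spec, seed=0)
        cfg = TrainConfig(batch_size=8, learning_rate=0.01, patience=0, seed=0)
        state = train(state, separable_batch[4:], separable_batch[:4], cfg)
        assert len(state.training_log) == 1

    def test_single_class_training_set_requires_class_weights(self, separable_batch):
        good_only = [s for s in separable_batch if s.label == "good"]
        spec = ModelSpec.tiny("lrcn", (16, 16, 6))
        state = build_model(spec, seed=0)
        with pytest.raises(ValueError):
            train(state, good_only, separable_batch[:4], TrainConfig(patience=0, seed=0))

    def test_returned_checkpoint_attains_best_logged_validation_metric(self, separable_batch):
        spec = ModelSpec.tiny("lrcn", (16, 16, 6))
        state = build_model(spec, seed=1)
        cfg = TrainConfig(batch_size=8, learning_rate=0.05, patience=3, max_epochs=30, seed=1)
        state = train(state, separable_batch[4:], separable_batch[:4], cfg)
        best_logged = max(r["val_balanced_accuracy"] for r in state.training_log)
        trainer = Trainer(state, cfg, separable_batch[:4])
        assert np.isclose(trainer.validation_metric(), best_logged)


class TestPredict:
    def test_probabilities_sum_to_one_and_deterministic(self, separable_batch):
        spec = ModelSpec.tiny("lrcn", (16, 16, 6))
        state = build_model(spec, seed=0)
        p1 = predict(state, separable_batch[0])
        p2 = predict(state, separable_batch[0])
        assert abs(p1.sum() - 1.0) < 1e-6 and len(p1) == 2
        assert np.array_equal(p1, p2)

    def test_shape_mismatch_errors(self, separable_batch):
        spec = ModelSpec.tiny("lrcn", (16, 16, 4))
        state = build_model(spec, seed=0)
        with pytest.raises(ValueError):
            predict(state, separable_batch[0])     # 6 frames vs spec's 4

    def test_trained_model_flags_held_out_corruption(self, separable_batch):
        spec = ModelSpec.tiny("lrcn", (16, 16, 6))
        state = build_model(spec, seed=0)
        cfg = TrainConfig(batch_size=8, learning_rate=0.05, patience=5, max_epochs=40, seed=0)
        # hold out the last corrupted sample (odd index)
        held_out = separable_batch[-1]
        assert held_out.label == "mistriggering"
        state = train(state, separable_batch[4:-1], separable_batch[:4], cfg)
        assert predict(state, held_out)[1] > 0.5


class TestAugmentation:
    def test_translation_bounds_for_fifth_fraction(self):
        seq = CineSequence(frames=np.random.default_rng(0).random((80, 80, 3)))
        import re
        for seed in range(20):
            out = augment_translation(seq, max_frac=0.2, seed=seed)
            m = re.search(r"shift=\((-?\d+),(-?\d+)\)", out.provenance[-1])
            sr, sc = int(m.group(1)), int(m.group(2))
            assert abs(sr) <= 16 and abs(sc) <= 16

    def test_zero_shift_is_identity_and_label_preserved(self):
        seq = CineSequence(frames=np.random.default_rng(1).random((20, 20, 2)), label="good")
        out = augment_translation(seq, shift=(0, 0))
        assert np.array_equal(out.frames, seq.frames)
        assert out.label == "good"

    def test_forced_shift_moves_impulse_exactly(self):
        frames = np.zeros((20, 20, 1))
        frames[10, 10, 0] = 1.0
        out = augment_translation(CineSequence(frames=frames), shift=(3, -2))
        assert out.frames[13, 8, 0] == 1.0 and out.frames.sum() == 1.0

    def test_blur_sigma_zero_identity_and_constant_invariance(self):
        seq = CineSequence(frames=np.random.default_rng(2).random((16, 16, 2)))
        assert np.array_equal(augment_gaussian_blur(seq, 0.0).frames, seq.frames)
        const = CineSequence(frames=np.full((16, 16, 2), 3.0))
        assert np.allclose(augment_gaussian_blur(const, 2.0).frames, 3.0)

    def test_blurred_impulse_matches_sampled_gaussian_kernel(self):
        sigma = 2.0
        n = 41
        frames = np.zeros((n, n, 1))
        frames[n // 2, n // 2, 0] = 1.0
        out = augment_gaussian_blur(CineSequence(frames=frames), sigma)
        # independent oracle: truncated, normalised separable Gaussian kernel
        radius = int(4 * sigma + 0.5)
        k1 = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        lo, hi = n // 2 - radius, n // 2 + radius + 1
        assert np.abs(out.frames[lo:hi, lo:hi, 0] - kernel).max() < 1e-6
        assert abs(out.frames.sum() - 1.0) < 1e-6

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            augment_gaussian_blur(CineSequence(frames=np.zeros((4, 4, 1))), -1.0)
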