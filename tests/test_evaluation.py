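import numpy as np
import pytest

from cineqc import (
    ConfusionCounts, confusion, evaluate_multiclass, metrics, roc_auc,
    stratified_kfold, variance_of_laplacian,
)
from cineqc.phantom import CineSequence


def pairwise_auc_oracle(y, s):
    """AUC as P(score_pos > score_neg) + 0.5 P(tie), by full enumeration."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_positive_prediction(self):
        c = confusion([1, 0], [1, 1])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 0)

    def test_hand_counted_example(self):
        y = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        p = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        c = confusion(y, p)
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 2, 1, 4)
        assert c.total == 10

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_closed_form_values(self):
        m = metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=4))
        assert np.isclose(m.accuracy, 0.7)
        assert np.isclose(m.precision, 0.75)
        assert np.isclose(m.recall, 0.6)
        assert np.isclose(m.balanced_accuracy, 0.675)   # (precision+recall)/2

    def test_standard_variant_behind_flag(self):
        m = metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=4),
                    balanced_variant="sensitivity_specificity")
        assert np.isclose(m.balanced_accuracy, (0.6 + 0.8) / 2)

    def test_perfect_classifier_all_ones(self):
        m = metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert m.accuracy == m.precision == m.recall == m.balanced_accuracy == 1.0

    def test_undefined_denominators_reported_as_none(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=2))
        assert m.recall == 0.0
        assert m.precision is None
        assert m.balanced_accuracy is None

    def test_brute_force_agreement_on_random_label_sets(self):
        """metrics() agrees with direct recomputation from raw label pairs."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            m = metrics(confusion(y, p))
            acc = (y == p).mean()
            assert np.isclose(m.accuracy, acc)
            if p.sum() > 0:
                assert np.isclose(m.precision, ((y == 1) & (p == 1)).sum() / p.sum())
            else:
                assert m.precision is None
            if y.sum() > 0:
                assert np.isclose(m.recall, ((y == 1) & (p == 1)).sum() / y.sum())
            else:
                assert m.recall is None


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.4])
        assert auc == 1.0

    def test_three_of_four_pairs_won(self):
        _, auc = roc_auc([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2])
        assert np.isclose(auc, 0.75)

    def test_all_tied_scores_give_half(self):
        _, auc = roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert np.isclose(auc, 0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.9])

    def test_curve_endpoints_and_monotonicity(self):
        curve, _ = roc_auc([1, 0, 1, 0, 1], [0.9, 0.1, 0.5, 0.5, 0.3])
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_trapezoid_matches_pairwise_oracle_on_random_inputs(self):
        """Exhaustive pairwise-comparison oracle, inputs up to 50 samples."""
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(2, 51))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 2)   # rounding forces ties
            _, auc = roc_auc(y, s)
            assert np.isclose(auc, pairwise_auc_oracle(y, s), atol=1e-12)


class TestStratifiedKFold:
    def test_ninety_ten_split_exact_fold_composition(self):
        y = np.array([0] * 90 + [1] * 10)
        fa = stratified_kfold(y, k=10, repeats=1, seed=0)
        for fold in range(10):
            members = y[fa.folds[0] == fold]
            assert len(members) == 10
            assert (members == 1).sum() == 1 and (members == 0).sum() == 9

    def test_partition_property_per_repeat(self):
        y = np.array([0] * 40 + [1] * 20)
        fa = stratified_kfold(y, k=5, repeats=3, seed=1)
        for rep in range(3):
            assert np.all(fa.folds[rep] >= 0)
            counts = np.bincount(fa.folds[rep], minlength=5)
            assert counts.sum() == 60

    def test_deterministic_per_seed(self):
        y = np.array([0] * 30 + [1] * 10)
        a = stratified_kfold(y, k=5, seed=3)
        b = stratified_kfold(y, k=5, seed=3)
        assert np.array_equal(a.folds, b.folds)

    def test_small_class_errors_naming_it(self):
        y = np.array([0] * 50 + [1] * 3)
        with pytest.raises(ValueError, match="1"):
            stratified_kfold(y, k=10)


class TestVarianceOfLaplacian:
    def test_constant_frames_score_zero(self):
        assert variance_of_laplacian(CineSequence(frames=np.full((16, 16, 3), 2.0))) == 0.0

    def test_blur_strictly_lowers_score(self, small_phantom):
        from cineqc import augment_gaussian_blur
        sharp = variance_of_laplacian(small_phantom)
        blurred = variance_of_laplacian(augment_gaussian_blur(small_phantom, 2.0))
        assert sharp > blurred

    def test_checkerboard_closed_form_under_periodic_boundaries(self):
        """4-neighbour Laplacian of a +-1 checkerboard is -8x: the response
        alternates +-8 with zero mean, so its variance is exactly 64."""
        n = 16
        board = (-1.0) ** (np.add.outer(np.arange(n), np.arange(n)))
        seq = CineSequence(frames=board[:, :, None] + 1.0)   # shifted to >= 0
        score = variance_of_laplacian(seq, mode="wrap")
        assert np.isclose(score, 64.0)


class TestMulticlass:
    def test_perfect_three_class_prediction(self):
        y = ["good", "breathing", "mistriggering"] * 4
        out = evaluate_multiclass(y, y)
        assert out["breathing"] == 1.0 and out["mistriggering"] == 1.0

    def test_collapsed_artefact_classes_match_hand_built_table(self):
        y = np.array(["good"] * 4 + ["breathing"] * 3 + ["mistriggering"] * 3)
        p = np.array(["good"] * 4 + ["breathing"] * 6)    # collapses both artefacts
        out = evaluate_multiclass(y, p)
        # breathing one-vs-rest: TP=3, FP=3, FN=0 -> precision .5, recall 1
        assert np.isclose(out["breathing"], (0.5 + 1.0) / 2)
        # mistriggering: never predicted -> TP=0, FN=3, FP=0
        assert out["mistriggering"] is None

    def test_reduces_to_binary_when_third_class_absent(self):
        y = np.array(["good", "good", "breathing", "breathing"])
        p = np.array(["good", "breathing", "breathing", "good"])
        out = evaluate_multiclass(y, p)
        c = confusion([0, 0, 1, 1], [0, 1, 1, 0])
        assert np.isclose(out["breathing"], metrics(c).balanced_accuracy)
        assert out["mistriggering"] is None

    def test_missing_class_reported_undefined(self):
        y = ["good"] * 4
        out = evaluate_multiclass(y, y)
        assert out["breathing"] is None and out["mistriggering"] is None
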