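"""Augmentation scheme, balanced training, AUROC and DeLong statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synthex import classifier_core as cc
from synthex.cli import make_fixture_dataset


@pytest.fixture(scope="module")
def small_tile():
    rng = np.random.default_rng(0)
    return rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)


class TestAugment:
    def test_all_off_is_identity(self, small_tile):
        cfg = cc.AugmentConfig(flip_rotate=False, jpeg_prob=0.0, blur_prob=0.0)
        out = cc.augment(small_tile, cfg, np.random.default_rng(0))
        assert np.array_equal(out, small_tile)

    def test_dihedral_orbit(self, small_tile):
        orbit = {cc._dihedral(small_tile, k).tobytes() for k in range(8)}
        assert len(orbit) <= 8
        assert small_tile.tobytes() in orbit

    def test_jpeg_application_rate_matches_half(self, small_tile):
        """Empirical JPEG round-trip frequency over 10,000 draws ~ 50%."""
        cfg = cc.AugmentConfig(flip_rotate=False, blur_prob=0.0)
        rng = np.random.default_rng(123)
        applied = 0
        for _ in range(10_000):
            out = cc.augment(small_tile, cfg, rng)
            applied += not np.array_equal(out, small_tile)
        assert 0.48 <= applied / 10_000 <= 0.52

    def test_augment_deterministic_given_rng_state(self, small_tile):
        cfg = cc.AugmentConfig()
        a = cc.augment(small_tile, cfg, np.random.default_rng(7))
        b = cc.augment(small_tile, cfg, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestTraining:
    def test_holdout_accuracy_on_separable_textures(self, trained_classifier):
        images, labels = trained_classifier.holdout
        probs = trained_classifier.predict(images)
        pred = [trained_classifier.classes[i] for i in probs.argmax(axis=1)]
        acc = np.mean([p == l for p, l in zip(pred, labels)])
        assert acc >= 0.9

    def test_batch_prediction_equals_single(self, trained_classifier):
        images, _ = trained_classifier.holdout
        batch = trained_classifier.predict(images[:6])
        singles = np.concatenate(
            [trained_classifier.predict(images[i]) for i in range(6)])
        assert np.abs(batch - singles).max() < 1e-5

    def test_balanced_batches_under_imbalance(self):
        """9:1 imbalance still yields near-equal per-batch class counts."""
        rng = np.random.default_rng(0)
        cats = np.array([0] * 900 + [1] * 100)
        counts = np.zeros(2)
        for _ in range(1000):
            idx = cc._balanced_batch_indices(cats, 32, rng)
            counts += np.bincount(cats[idx], minlength=2)
        assert abs(counts[0] - counts[1]) / 1000 <= 1.0

    def test_continuous_mode_learns_the_score(self):
        images, scores = make_fixture_dataset(150, 32, 5, continuous=True)
        cfg = cc.ClassifierConfig(loss="mean_squared_error", steps=250, seed=5)
        model = cc.train_classifier(images[:240], np.asarray(scores[:240]), cfg)
        pred = model.predict(images[240:])
        r = np.corrcoef(pred, scores[240:])[0, 1]
        assert r >= 0.8
        assert pred.min() >= -1.0 and pred.max() <= 1.0

    def test_single_category_rejected(self):
        images, _ = make_fixture_dataset(4, 16, 0)
        with pytest.raises(cc.BalancingError):
            cc.train_classifier(images, ["A"] * len(images),
                                cc.ClassifierConfig(steps=1))


def _brute_force_auroc(labels, scores):
    pos = [s for l, s in zip(labels, scores) if l]
    neg = [s for l, s in zip(labels, scores) if not l]
    pairs = [(1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg]
    return float(np.mean(pairs))


class TestAUROC:
    def test_perfect_separation(self):
        assert cc.auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 4000)
        scores = rng.normal(size=4000)
        assert abs(cc.auroc(labels, scores) - 0.5) < 0.05

    def test_toy_set_with_tie_matches_pair_counting(self):
        labels = [0, 0, 0, 1, 1, 1]
        scores = [0.1, 0.4, 0.4, 0.4, 0.7, 0.9]
        assert cc.auroc(labels, scores) == pytest.approx(
            _brute_force_auroc(labels, scores))

    def test_single_class_undefined(self):
        with pytest.raises(cc.UndefinedMetricError):
            cc.auroc([1, 1, 1], [0.1, 0.2, 0.3])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(),
                              st.integers(min_value=0, max_value=5)),
                    min_size=2, max_size=12))
    def test_matches_brute_force_oracle(self, pairs):
        labels = [l for l, _ in pairs]
        scores = [s for _, s in pairs]  # small ints force ties
        if not (any(labels) and not all(labels)):
            return
        assert cc.auroc(labels, scores) == pytest.approx(
            _brute_force_auroc(labels, scores))


class TestDeLong:
    # reference values computed once with pROC (roc/ci.auc/roc.test, DeLong)
    LABELS = [0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1]
    SCORES = [0.12, 0.35, 0.48, 0.22, 0.61, 0.33, 0.45, 0.50,
              0.55, 0.40, 0.72, 0.88, 0.64, 0.91, 0.38, 0.77]
    SCORES2 = [0.2, 0.3, 0.4, 0.1, 0.5, 0.25, 0.35, 0.45,
               0.6, 0.5, 0.65, 0.8, 0.65, 0.85, 0.45, 0.7]

    def test_matches_reference_implementation(self):
        a, lo, hi = cc.delong_ci(self.LABELS, self.SCORES)
        assert a == pytest.approx(0.859375)
        assert lo == pytest.approx(0.6692, abs=1e-4)
        assert hi == pytest.approx(1.0)

    def test_paired_test_matches_reference(self):
        p = cc.delong_test(self.LABELS, self.SCORES, self.SCORES2)
        assert p == pytest.approx(0.1406452, abs=1e-6)

    def test_separable_data_collapses_ci(self):
        a, lo, hi = cc.delong_ci([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert (a, lo, hi) == (1.0, 1.0, 1.0)

    def test_score_vector_against_itself(self):
        assert cc.delong_test(self.LABELS, self.SCORES, self.SCORES) == 1.0

    def test_ci_coverage_of_binormal_model(self):
        """Empirical 95% CI coverage over binormal simulations at n=200."""
        from scipy.stats import norm

        rng = np.random.default_rng(42)
        true_auc = norm.cdf(1.0 / np.sqrt(2))
        labels = np.r_[np.zeros(100), np.ones(100)]
        covered = 0
        reps = 500
        for _ in range(reps):
            scores = np.r_[rng.normal(0, 1, 100), rng.normal(1, 1, 100)]
            _, lo, hi = cc.delong_ci(labels, scores)
            covered += lo <= true_auc <= hi
        assert 0.92 <= covered / reps <= 0.98
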