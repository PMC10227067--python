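"""Seed triage: strength rules, seed labeling, summaries, set overlap."""

import numpy as np
import pytest

from synthex import concordance as cn, fixtures as fx
from synthex.classifier_core import Prediction

CFG = cn.ConcordanceConfig()


def _oracle_strength_categorical(p0, p1, tau=0.75):
    """Independent enumeration of the categorical rule."""
    if p0 == p1:
        return 0, "weak"
    cls = 0 if p0 > p1 else 1
    return cls, "strong" if max(p0, p1) > tau else "weak"


def _oracle_strength_continuous(v, tau=0.5):
    if v == 0:
        return None, "weak"
    return (1 if v > 0 else -1), "strong" if abs(v) > tau else "weak"


class TestPredictionStrength:
    @pytest.mark.parametrize("p, expected", [
        ((0.80, 0.20), (0, "strong")),
        ((0.75, 0.25), (0, "weak")),     # boundary: strict inequality
        ((0.60, 0.40), (0, "weak")),
        ((0.20, 0.80), (1, "strong")),
        ((0.5, 0.5), (0, "weak")),       # tie: lowest index, weak
    ])
    def test_categorical_rule(self, p, expected):
        assert cn.prediction_strength(Prediction("categorical", p), CFG) == expected

    @pytest.mark.parametrize("v, expected", [
        (0.35, (1, "weak")),
        (-0.7, (-1, "strong")),
        (0.5, (1, "weak")),              # boundary: weak
        (-0.5, (-1, "weak")),
        (0.0, (None, "weak")),           # signless: matches neither class
        (0.51, (1, "strong")),
    ])
    def test_continuous_rule(self, v, expected):
        assert cn.prediction_strength(Prediction("continuous", v), CFG) == expected

    def test_grid_agrees_with_enumeration_oracle(self):
        for p0 in np.linspace(0, 1, 101):
            pred = Prediction("categorical", (p0, 1 - p0))
            assert cn.prediction_strength(pred, CFG) == \
                _oracle_strength_categorical(p0, 1 - p0)
        for v in np.linspace(-1, 1, 201):
            pred = Prediction("continuous", v)
            assert cn.prediction_strength(pred, CFG) == \
                _oracle_strength_continuous(v)

    def test_raising_tau_never_adds_strong_seeds(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.5, 1.0, 500)
        strongs = []
        for tau in (0.6, 0.75, 0.9):
            cfg = cn.ConcordanceConfig(tau_categorical=tau)
            strongs.append(sum(
                cn.prediction_strength(
                    Prediction("categorical", (v, 1 - v)), cfg)[1] == "strong"
                for v in values))
        assert strongs[0] >= strongs[1] >= strongs[2]


class _ConstantClassifier:
    outcome_type = "categorical"
    classes = ("A", "B")

    def predict(self, images):
        images = np.asarray(images)
        n = 1 if images.ndim == 3 else len(images)
        return np.full((n, 2), 0.5)


class TestEvaluateSeed:
    def test_oracle_classifier_yields_all_strong(self, analytic_generator,
                                                 oracle_classifier):
        for seed in range(10):
            rec = cn.evaluate_seed(analytic_generator, oracle_classifier, seed)
            assert rec.label == "strong"

    def test_constant_classifier_yields_all_non(self, analytic_generator):
        # (0.5, 0.5) ties resolve to class A, mismatching the class-B image
        for seed in range(5):
            rec = cn.evaluate_seed(analytic_generator, _ConstantClassifier(), seed)
            assert rec.label == "non"

    def test_noisy_oracle_matches_binomial_closed_form(self, analytic_generator):
        """10% independent sign flips per image: P(non) = 1 - 0.9^2 = 0.19."""
        noisy = fx.OracleClassifier(flip_rate=0.1, seed=3)
        records = cn.evaluate_seeds(analytic_generator, noisy, n_seeds=1000)
        frac_non = np.mean([r.label == "non" for r in records])
        se = np.sqrt(0.19 * 0.81 / 1000)
        assert abs(frac_non - 0.19) <= 3 * se

    def test_labels_partition_seed_set(self, analytic_generator):
        noisy = fx.OracleClassifier(flip_rate=0.3, seed=5)
        records = cn.evaluate_seeds(analytic_generator, noisy, n_seeds=200)
        summary = cn.concordance_summary(records)
        assert sum(summary["counts"].values()) == 200
        assert sum(summary["proportions_exact"].values()) == 1


class TestSummary:
    def test_exact_proportions(self):
        recs = [cn.SeedRecord(i, {}, {}, lab) for i, lab in
                enumerate(["strong", "strong", "weak", "non"])]
        s = cn.concordance_summary(recs)
        assert s["proportions"] == {"strong": 0.5, "weak": 0.25, "non": 0.25}

    def test_all_strong(self):
        recs = [cn.SeedRecord(i, {}, {}, "strong") for i in range(3)]
        s = cn.concordance_summary(recs)
        assert s["proportions"] == {"strong": 1.0, "weak": 0.0, "non": 0.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cn.concordance_summary([])


class TestSeedOverlap:
    def test_identical_sets(self):
        out = cn.seed_overlap({1, 2}, {1, 2}, set(range(10)))
        assert out["fraction_A_in_B"] == out["jaccard"] == 1.0

    def test_disjoint_sets(self):
        out = cn.seed_overlap({1}, {2}, set(range(10)))
        assert out["fraction_A_in_B"] == out["jaccard"] == 0.0

    def test_hand_counted_example(self):
        a = set(range(1, 11))
        b = set(range(6, 21))
        out = cn.seed_overlap(a, b, set(range(0, 30)))
        assert out["fraction_A_in_B"] == 0.5
        assert out["jaccard"] == pytest.approx(5 / 20)

    def test_empty_side_reported_missing(self):
        out = cn.seed_overlap(set(), {1}, {1, 2})
        assert out["fraction_A_in_B"] is None

    def test_not_subset_of_universe(self):
        with pytest.raises(ValueError):
            cn.seed_overlap({1, 99}, {1}, {1, 2})
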