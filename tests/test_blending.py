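"""Class/layer blending and transition-curve statistics."""

import numpy as np
import pytest

from synthex import blending as bl, fixtures as fx
from synthex.concordance import ConcordanceConfig


class TestInterpolation:
    def test_endpoints_exact(self):
        e0, e1 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert np.array_equal(bl.interpolate_embedding(e0, e1, 0.0), e0)
        assert np.array_equal(bl.interpolate_embedding(e0, e1, 1.0), e1)

    def test_midpoint(self):
        e0, e1 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert np.array_equal(bl.interpolate_embedding(e0, e1, 0.5), [0.5, 0.5])

    def test_quarter_point_drives_analytic_response(self):
        e = bl.interpolate_embedding(fx.EMBEDDING_A, fx.EMBEDDING_B, 0.25)
        assert fx.analytic_response([e] * 4) == 0.25 * (1 - (-1)) + (-1)

    def test_extrapolation_and_mismatch_rejected(self):
        e0, e1 = np.zeros(3), np.ones(3)
        with pytest.raises(bl.ParameterError):
            bl.interpolate_embedding(e0, e1, 1.5)
        with pytest.raises(bl.ParameterError):
            bl.interpolate_embedding(e0, np.ones(4), 0.5)


class TestBlendPath:
    def test_endpoints_bit_identical_to_pure_class_generation(
            self, analytic_generator, oracle_classifier):
        spec = bl.BlendSpec(seed=13, n_steps=5)
        path = bl.blend_path(analytic_generator, oracle_classifier, spec,
                             keep_images=True)
        pure_a = analytic_generator.generate(
            13, [analytic_generator.embed_class("A")] * 4)
        pure_b = analytic_generator.generate(
            13, [analytic_generator.embed_class("B")] * 4)
        assert np.array_equal(path.images[0], pure_a)
        assert np.array_equal(path.images[-1], pure_b)

    def test_predictions_exactly_linear_for_analytic_fixture(
            self, analytic_generator, oracle_classifier):
        spec = bl.BlendSpec(seed=11, n_steps=100)
        path = bl.blend_path(analytic_generator, oracle_classifier, spec)
        t = path.t
        linear = (1 - t) * path.predictions[0] + t * path.predictions[-1]
        assert np.abs(path.predictions - linear).max() == 0.0

    def test_trained_models_move_in_correct_direction(self, trained_gan,
                                                      trained_classifier):
        cfg = ConcordanceConfig(normalization_method="none")
        spec = bl.BlendSpec(seed=0, class_from="A", class_to="B", n_steps=10)
        path = bl.blend_path(trained_gan, trained_classifier, spec, cfg=cfg)
        # readout is P(class B); blending toward B must raise it
        assert path.predictions[-1] > path.predictions[0]


class TestLayerBlend:
    def test_uniform_assignment_equals_pure_class(self, trained_gan):
        img = bl.layer_blend(trained_gan, 4, ["A"] * trained_gan.n_layers)
        assert np.array_equal(img, trained_gan.generate_class(4, "A"))

    def test_half_half_assignment_is_closed_form_zero(self, analytic_generator):
        img = bl.layer_blend(analytic_generator, 5, ["A", "A", "B", "B"])
        assert fx.read_score_tag(img) == 0.0

    def test_permuting_layers_preserves_fixture_score_not_gan_image(
            self, analytic_generator, trained_gan):
        a = bl.layer_blend(analytic_generator, 5, ["A", "A", "B", "B"])
        b = bl.layer_blend(analytic_generator, 5, ["B", "B", "A", "A"])
        assert fx.read_score_tag(a) == fx.read_score_tag(b) == 0.0
        ga = bl.layer_blend(trained_gan, 5, ["A", "A", "B", "B"])
        gb = bl.layer_blend(trained_gan, 5, ["B", "B", "A", "A"])
        assert not np.array_equal(ga, gb)

    def test_wrong_length_rejected(self, trained_gan):
        from synthex.generator_core import InterfaceError

        with pytest.raises(InterfaceError):
            bl.layer_blend(trained_gan, 0, ["A"])


def _path(predictions, seed=0):
    p = bl.BlendPath(spec=bl.BlendSpec(seed=seed, n_steps=len(predictions)),
                     t=np.linspace(0, 1, len(predictions)), embeddings=[],
                     predictions=np.asarray(predictions, float))
    return p


class TestTransitionStats:
    def test_linear_path_gives_uniform_fractions(self):
        stats = bl.transition_stats([_path(np.linspace(-1, 1, 100))])
        assert np.allclose(stats["mean_change_fraction"], 1 / 99)
        assert np.allclose(stats["std"], 0.0)

    def test_per_path_fractions_telescope_to_one(self):
        rng = np.random.default_rng(0)
        paths = [_path(np.cumsum(rng.uniform(-0.1, 0.3, 50)), seed=i)
                 for i in range(20)]
        stats = bl.transition_stats([p for p in paths
                                     if p.predictions[-1] != p.predictions[0]])
        assert np.allclose(stats["per_path_sums"], 1.0, atol=1e-9)

    def test_planted_sigmoid_changepoint_recovered(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 1, 100)
        paths = []
        for i in range(100):
            mid = 0.5 + rng.normal(0, 0.02)
            paths.append(_path(1 / (1 + np.exp(-10 * (t - mid))), seed=i))
        stats = bl.transition_stats(paths)
        peak = int(np.argmax(stats["mean_change_fraction"]))
        # the step nearest t*=0.5 among the 99 increments is index 49
        assert abs(peak - 49) <= 2

    def test_flat_path_excluded(self):
        flat = _path(np.ones(10))
        rising = _path(np.linspace(0, 1, 10), seed=1)
        stats = bl.transition_stats([flat, rising])
        assert stats["n_paths"] == 1
        with pytest.raises(ValueError):
            bl.transition_stats([flat])
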