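"""Class blending, layer blending, and transition-curve statistics.

Class blending interpolates linearly between two class embeddings while the
seed's latent is held fixed, producing a path of K images that morph from
one class to the other; the classifier is run at every step through the
same calibrate -> normalize -> predict path the concordance triage uses.
Layer blending instead assigns different embeddings to different generator
layers, localizing class influence by scale.

The transition statistic normalizes each path's step-to-step prediction
changes by its total change, so the per-step fractions sum to 1 and the
mean curve across paths reads as a distribution of "where the transition
happens" over the blending axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from synthex import stain
from synthex.concordance import ConcordanceConfig, calibrate_image, _predict_one

log = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class BlendSpec:
    """One class-blending run: seed, endpoint classes, K uniform steps."""

    seed: int
    class_from: object = "A"
    class_to: object = "B"
    n_steps: int = 100

    def __post_init__(self):
        if self.n_steps < 2:
            raise ParameterError("n_steps must be >= 2")

    @property
    def t_grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_steps)


@dataclass
class BlendPath:
    spec: BlendSpec
    t: np.ndarray
    embeddings: list
    predictions: np.ndarray
    images: list | None = None


def interpolate_embedding(e0, e1, t: float) -> np.ndarray:
    """(1-t)·e0 + t·e1 with endpoints returned exactly."""
    e0 = np.asarray(e0, dtype=float)
    e1 = np.asarray(e1, dtype=float)
    if e0.shape != e1.shape:
        raise ParameterError(f"dimension mismatch {e0.shape} vs {e1.shape}")
    if not (0.0 <= t <= 1.0):
        raise ParameterError(f"t must lie in [0, 1], got {t} (extrapolation disabled)")
    if t == 0.0:
        return e0.copy()
    if t == 1.0:
        return e1.copy()
    return (1.0 - t) * e0 + t * e1


def blend_path(generator, classifier, spec: BlendSpec,
               cfg: ConcordanceConfig | None = None,
               keep_images: bool = False) -> BlendPath:
    """Generate and classify the K-step interpolation path for one seed."""
    cfg = cfg or ConcordanceConfig()
    e0 = generator.embed_class(spec.class_from)
    e1 = generator.embed_class(spec.class_to)
    params = (stain.fit(cfg.normalization_method, stain.default_target())
              if cfg.normalization_method != "none" else None)
    t_grid = spec.t_grid
    preds = np.empty(spec.n_steps)
    embs, imgs = [], []
    for k, t in enumerate(t_grid):
        e = interpolate_embedding(e0, e1, float(t))
        img = generator.generate(spec.seed, [e] * generator.n_layers)
        img = calibrate_image(img, generator, classifier)
        if params is not None:
            img = stain.apply(img, params)
        pred = _predict_one(classifier, img)
        if pred.outcome_type == "categorical":
            # scalar readout: probability of the destination class
            to_idx = list(generator.classes).index(spec.class_to)
            preds[k] = float(np.asarray(pred.value)[to_idx])
        else:
            preds[k] = float(pred.value)
        embs.append(e)
        if keep_images:
            imgs.append(img)
    return BlendPath(spec=spec, t=t_grid, embeddings=embs, predictions=preds,
                     images=imgs if keep_images else None)


def layer_blend(generator, seed: int, assignment) -> np.ndarray:
    """Generate with a per-layer embedding assignment of length L.

    Entries may be class ids (resolved via embed_class) or embedding vectors.
    """
    from synthex.generator_core import InterfaceError

    assignment = list(assignment)
    if len(assignment) != generator.n_layers:
        raise InterfaceError(
            f"assignment length {len(assignment)} != {generator.n_layers} layers"
        )
    embs = []
    for entry in assignment:
        if isinstance(entry, str) or np.isscalar(entry):
            embs.append(generator.embed_class(entry))
        else:
            embs.append(np.asarray(entry, dtype=float))
    return generator.generate(seed, embs)


def transition_stats(paths) -> dict:
    """Per-step normalized change fractions, aggregated across paths.

    For each path, δ_k = (p_{k+1} − p_k) / (p_K − p_1); the δ sum to 1 by
    telescoping. Paths with zero total change are excluded (logged). Returns
    per-step mean, std, normal 95% CI, plus the raw mean prediction curve.
    """
    deltas, raw = [], []
    for p in paths:
        total = p.predictions[-1] - p.predictions[0]
        if total == 0:
            log.warning("path (seed %s) has zero total change; excluded",
                        p.spec.seed)
            continue
        deltas.append(np.diff(p.predictions) / total)
        raw.append(p.predictions)
    if not deltas:
        raise ValueError("no usable paths (all had zero total change)")
    D = np.stack(deltas)  # n_paths x (K-1)
    mean = D.mean(axis=0)
    std = D.std(axis=0, ddof=1) if len(D) > 1 else np.zeros(D.shape[1])
    se = std / np.sqrt(len(D))
    return {
        "n_paths": len(D),
        "mean_change_fraction": mean,
        "std": std,
        "ci95_low": mean - 1.96 * se,
        "ci95_high": mean + 1.96 * se,
        "mean_prediction": np.stack(raw).mean(axis=0),
        "per_path_sums": D.sum(axis=1),
    }
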