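"""Classifier-concordance triage of generator seeds.

For every seed the generator renders one image per class (that class's
embedding at all layers); each image is calibrated to the classifier's field
of view, stain normalized, and classified. A seed is strongly concordant if
both predictions match their conditioning class and both are strong
(post-softmax > 0.75, or |continuous| > 0.5), weakly concordant if both
match but at least one is weak, and non-concordant if either mismatches.
Boundary values (exactly 0.75 / ±0.5) are weak: the strength rules are
strict inequalities. A continuous prediction of exactly 0 carries no sign
and matches neither class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from synthex import stain
from synthex.classifier_core import Prediction

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Generator field of view cannot cover the classifier's."""


@dataclass(frozen=True)
class ConcordanceConfig:
    """Strength thresholds and the normalization applied before predict."""

    tau_categorical: float = 0.75
    tau_continuous: float = 0.5
    normalization_method: str = "none"
    n_seeds: int = 1000

    def __post_init__(self):
        if not (0.5 < self.tau_categorical < 1.0):
            raise ValueError("tau_categorical must lie in (0.5, 1)")
        if not (0.0 < self.tau_continuous < 1.0):
            raise ValueError("tau_continuous must lie in (0, 1)")


@dataclass
class SeedRecord:
    seed: int
    images: dict
    predictions: dict
    label: str  # strong | weak | non
    per_class_strength: dict = field(default_factory=dict)


def prediction_strength(pred: Prediction, cfg: ConcordanceConfig):
    """(predicted_class_index_or_sign, 'strong'|'weak') for one prediction.

    Categorical: argmax wins (ties -> lowest index, logged, weak); strong iff
    the winning post-softmax value strictly exceeds tau_categorical.
    Continuous: the sign is the class (+1 / -1; exact 0 -> None); strong iff
    |value| strictly exceeds tau_continuous.
    """
    if pred.outcome_type == "categorical":
        v = np.asarray(pred.value, dtype=float)
        winners = np.flatnonzero(v == v.max())
        cls = int(winners[0])
        if len(winners) > 1:
            log.info("argmax tie at %s; lowest index wins, strength weak", v)
            return cls, "weak"
        return cls, "strong" if v[cls] > cfg.tau_categorical else "weak"
    value = float(pred.value)
    if value == 0.0:
        return None, "weak"
    cls = 1 if value > 0 else -1
    return cls, "strong" if abs(value) > cfg.tau_continuous else "weak"


def _matches(predicted, class_index, outcome_type, classes):
    if predicted is None:
        return False
    if outcome_type == "categorical":
        return predicted == class_index
    # continuous: first class maps to the negative pole, second to positive
    return predicted == (-1 if class_index == 0 else 1)


def calibrate_image(image: np.ndarray, generator, classifier) -> np.ndarray:
    """Center-crop to the classifier's μm field of view, then resample.

    Uses tile_um/mpp metadata on both models; identity when the fields of
    view and pixel sizes already agree.
    """
    gen_um = getattr(generator, "tile_um", None)
    clf_um = getattr(classifier, "tile_um", None)
    clf_px = getattr(classifier, "tile_px", None)
    if gen_um is None or clf_um is None or clf_px is None:
        return image
    if clf_um > gen_um + 1e-9:
        raise CalibrationError(
            f"classifier field of view {clf_um} μm exceeds generator's {gen_um} μm"
        )
    h = image.shape[0]
    crop_px = int(round(h * clf_um / gen_um))
    off = (h - crop_px) // 2
    out = image[off : off + crop_px, off : off + crop_px]
    if crop_px != clf_px:
        from skimage.transform import resize

        x = resize(out.astype(float) / 255.0, (clf_px, clf_px), order=1,
                   anti_aliasing=crop_px > clf_px, preserve_range=True)
        out = np.clip(np.rint(x * 255.0), 0, 255).astype(np.uint8)
    return out


def _norm_params(cfg: ConcordanceConfig):
    if cfg.normalization_method == "none":
        return None
    return stain.fit(cfg.normalization_method, stain.default_target())


def _predict_one(classifier, image) -> Prediction:
    out = classifier.predict(image[None] if image.ndim == 3 else image)
    if getattr(classifier, "outcome_type", "continuous") == "categorical":
        return Prediction("categorical", np.asarray(out)[0])
    return Prediction("continuous", float(np.asarray(out).reshape(-1)[0]))


def evaluate_seed(generator, classifier, seed: int,
                  cfg: ConcordanceConfig | None = None,
                  norm_params="unset") -> SeedRecord:
    """Generate the per-class image pair for one seed and label the seed."""
    cfg = cfg or ConcordanceConfig()
    if norm_params == "unset":
        norm_params = _norm_params(cfg)
    classes = tuple(generator.classes)
    images, predictions, strengths = {}, {}, {}
    match_all, any_weak = True, False
    for idx, c in enumerate(classes):
        emb = generator.embed_class(c)
        img = generator.generate(seed, [emb] * generator.n_layers)
        img = calibrate_image(img, generator, classifier)
        if norm_params is not None:
            img = stain.apply(img, norm_params)
        pred = _predict_one(classifier, img)
        predicted, strength = prediction_strength(pred, cfg)
        images[c] = img
        predictions[c] = pred
        strengths[c] = strength
        if not _matches(predicted, idx, pred.outcome_type, classes):
            match_all = False
        if strength == "weak":
            any_weak = True
    label = "non" if not match_all else ("weak" if any_weak else "strong")
    return SeedRecord(seed=seed, images=images, predictions=predictions,
                      label=label, per_class_strength=strengths)


def evaluate_seeds(generator, classifier, n_seeds: int | None = None,
                   cfg: ConcordanceConfig | None = None,
                   keep_images: bool = False) -> list[SeedRecord]:
    """Triage seeds 0..N-1; images are dropped unless keep_images."""
    cfg = cfg or ConcordanceConfig()
    n = cfg.n_seeds if n_seeds is None else n_seeds
    params = _norm_params(cfg)
    records = []
    for s in range(n):
        rec = evaluate_seed(generator, classifier, s, cfg, norm_params=params)
        if not keep_images:
            rec.images = {}
        records.append(rec)
    return records


def concordance_summary(records) -> dict:
    """Exact proportions of strong / weak / non labels (rational arithmetic)."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    n = len(records)
    counts = {k: sum(r.label == k for r in records) for k in ("strong", "weak", "non")}
    fracs = {k: Fraction(v, n) for k, v in counts.items()}
    assert sum(fracs.values()) == 1
    return {
        "n": n,
        "counts": counts,
        "proportions": {k: float(v) for k, v in fracs.items()},
        "proportions_exact": fracs,
    }


def seed_overlap(set_a, set_b, universe) -> dict:
    """Directional fractions, Jaccard, and the in-both share of the universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    inter = a & b
    union = a | b
    return {
        "fraction_A_in_B": len(inter) / len(a) if a else None,
        "fraction_B_in_A": len(inter) / len(b) if b else None,
        "jaccard": len(inter) / len(union) if union else None,
        "fraction_universe_in_both": len(inter) / len(u) if u else None,
    }
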