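"""Construction and scoring of the pre/post-test teaching instrument.

Tiles with continuous predictions are stratified per slide into weakly
correct (correct sign, |prediction| <= 0.5) and strongly correct
(correct sign, |prediction| > 0.5). For every slide with at least three
tiles in each stratum, one weak trio and one strong trio are sampled
without replacement and merged side by side — two items per eligible
slide, so 48 eligible slides yield a 96-item test. Participant accuracy
before and after a teaching session is compared with a one-sided paired
t-test (alternative: post > pre).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

log = logging.getLogger(__name__)

#: white gutter between the three tiles of a merged trio, in pixels
TRIO_GUTTER_PX = 4


@dataclass
class TestItem:
    item_id: int
    slide_id: str
    strength: str  # weak | strong
    tile_ids: tuple
    merged_image: np.ndarray | None
    truth: object


@dataclass
class TestResult:
    participant_id: str
    responses: list
    accuracy: float

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")


def stratify_tiles(predictions, truth_labels, tau_continuous: float = 0.5) -> dict:
    """Per-slide weak-correct / strong-correct tile index sets.

    predictions: mapping slide_id -> sequence of continuous predictions (one
    per tile); truth_labels: mapping slide_id -> label in {-1, +1} (or any
    sign-carrying float). A tile is correct iff sign(prediction) matches the
    slide label; |prediction| values at exactly tau fall in the weak stratum
    (the strong rule is a strict inequality).
    """
    strata = {}
    for slide_id, preds in predictions.items():
        label = np.sign(float(truth_labels[slide_id]))
        if label == 0:
            raise ValueError(f"slide {slide_id} has a signless label")
        weak, strong = [], []
        for i, p in enumerate(np.asarray(preds, dtype=float)):
            if p == 0 or np.sign(p) != label:
                continue
            (strong if abs(p) > tau_continuous else weak).append(i)
        strata[slide_id] = {"weak_correct": weak, "strong_correct": strong}
    return strata


def merge_trio(images, gutter_px: int = TRIO_GUTTER_PX) -> np.ndarray:
    """Concatenate three tiles horizontally with white gutters."""
    imgs = [np.asarray(im) for im in images]
    h = imgs[0].shape[0]
    gut = np.full((h, gutter_px, 3), 255, dtype=np.uint8)
    parts = []
    for i, im in enumerate(imgs):
        if i:
            parts.append(gut)
        parts.append(im)
    return np.concatenate(parts, axis=1)


def build_test(slides, strata, rng, tiles=None) -> list[TestItem]:
    """Assemble the test: one weak trio + one strong trio per eligible slide.

    slides: mapping slide_id -> truth label. strata: output of
    stratify_tiles. rng: seeded numpy Generator (or int seed). tiles:
    optional mapping slide_id -> image array list for trio rendering; merged
    images are None when absent. Slides lacking three tiles in either
    stratum are excluded (logged). Item order is a seeded uniform shuffle,
    invariant to the input ordering of slides.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.Generator(np.random.Philox([int(rng), 733]))
    items = []
    for slide_id in sorted(slides):
        st = strata.get(slide_id, {"weak_correct": [], "strong_correct": []})
        if set(st["weak_correct"]) & set(st["strong_correct"]):
            raise ValueError(f"slide {slide_id}: strata overlap")
        if len(st["weak_correct"]) < 3 or len(st["strong_correct"]) < 3:
            log.info("slide %s excluded: needs >= 3 tiles per stratum "
                     "(weak %d, strong %d)", slide_id,
                     len(st["weak_correct"]), len(st["strong_correct"]))
            continue
        for strength in ("weak", "strong"):
            pool = st[f"{strength}_correct"]
            chosen = tuple(int(i) for i in rng.choice(pool, size=3, replace=False))
            order = rng.permutation(3)
            merged = None
            if tiles is not None and slide_id in tiles:
                trio = [tiles[slide_id][chosen[j]] for j in order]
                merged = merge_trio(trio)
            items.append(TestItem(item_id=-1, slide_id=slide_id,
                                  strength=strength, tile_ids=chosen,
                                  merged_image=merged, truth=slides[slide_id]))
    order = rng.permutation(len(items))
    shuffled = [items[i] for i in order]
    for i, item in enumerate(shuffled):
        item.item_id = i
    return shuffled


def score_responses(items, responses, participant_id: str = "anon") -> TestResult:
    """Fraction of items whose response matches the truth sign/label."""
    correct = 0
    resp = list(responses)
    if len(resp) != len(items):
        raise ValueError("one response per item required")
    for item, r in zip(items, resp):
        truth = np.sign(float(item.truth)) if not isinstance(item.truth, str) else item.truth
        if (np.sign(float(r)) if not isinstance(r, str) else r) == truth:
            correct += 1
    return TestResult(participant_id=participant_id, responses=resp,
                      accuracy=correct / len(items) if items else 0.0)


def paired_one_sided_ttest(pre_accuracies, post_accuracies, level: float = 0.95):
    """Paired t-test of post > pre.

    Returns (t, df, p, mean_diff, one_sided_ci_lower). Zero variance of the
    differences is reported degenerately: p = 0.5 for a zero mean difference,
    else p = 0.0 (all-improved) or 1.0 (all-worsened); t is ±inf or 0.
    """
    pre = np.asarray(pre_accuracies, dtype=float)
    post = np.asarray(post_accuracies, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = post - pre
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 0.5, 0.0, 0.0
        t = float(np.inf if mean > 0 else -np.inf)
        return t, df, (0.0 if mean > 0 else 1.0), mean, mean
    t = mean / (sd / np.sqrt(n))
    p = float(sp_stats.t.sf(t, df))
    t_crit = float(sp_stats.t.ppf(level, df))
    ci_lower = mean - t_crit * sd / np.sqrt(n)
    return float(t), df, p, mean, float(ci_lower)
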