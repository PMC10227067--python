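"""Miniature trainable classifier plus evaluation statistics.

The classifier is a compact numpy multilayer perceptron on flattened RGB
tiles: two hidden layers of width 1024 with dropout (p = 0.1) after each,
trained with Adam under cross-entropy (categorical) or mean-squared-error
(continuous score in [-1, 1]) loss, with category-level mini-batch balancing
(continuous targets are balanced on their sign). Stain normalization is
applied inside predict(), mirroring the generate -> normalize -> classify
pipeline ordering.

Training augmentation: random flip and cardinal rotation (the 8 dihedral
states), JPEG compression (50% chance, quality uniform in [50, 100]), and
Gaussian blur (10% chance, sigma uniform in [0.5, 2.0]).

AUROC is the Mann-Whitney statistic (ties counted half); its confidence
interval and the paired comparison of two score vectors use the DeLong
structural-components variance estimator.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import stats as sp_stats
from scipy.ndimage import gaussian_filter

from synthex import stain

log = logging.getLogger(__name__)


class BalancingError(ValueError):
    """A category required for balanced sampling is empty."""


class UndefinedMetricError(ValueError):
    """Metric needs both classes present."""


@dataclass(frozen=True)
class AugmentConfig:
    """The training-time augmentation scheme."""

    flip_rotate: bool = True
    jpeg_prob: float = 0.5
    jpeg_quality_range: tuple = (50, 100)
    blur_prob: float = 0.1
    blur_sigma_range: tuple = (0.5, 2.0)

    def __post_init__(self):
        for p in (self.jpeg_prob, self.blur_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.jpeg_quality_range[0] > self.jpeg_quality_range[1]:
            raise ValueError("jpeg_quality_range must be ordered")
        if self.blur_sigma_range[0] > self.blur_sigma_range[1]:
            raise ValueError("blur_sigma_range must be ordered")


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture, loss, and training settings for the mini classifier."""

    hidden_widths: tuple = (1024, 1024)
    dropout: float = 0.1
    loss: str = "cross_entropy"  # or "mean_squared_error"
    normalization_method: str = "none"
    input_px: int = 32
    batch_size: int = 32
    steps: int = 600
    learning_rate: float = 1e-3
    augment: AugmentConfig | None = None
    seed: int = 0

    def __post_init__(self):
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if self.loss not in ("cross_entropy", "mean_squared_error"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class Prediction:
    """Categorical (post-softmax vector) or continuous (scalar) prediction."""

    outcome_type: str
    value: object

    def __post_init__(self):
        if self.outcome_type == "categorical":
            v = np.asarray(self.value, dtype=float)
            if abs(float(v.sum()) - 1.0) > 1e-6:
                raise ValueError("post-softmax vector must sum to 1")
            self.value = v
        elif self.outcome_type == "continuous":
            self.value = float(np.clip(self.value, -1.0, 1.0))
        else:
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _dihedral(img: np.ndarray, k: int) -> np.ndarray:
    """Apply element k (0..7) of the dihedral group of the square."""
    out = np.rot90(img, k % 4)
    if k >= 4:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def augment(image: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """One stochastic augmentation draw; deterministic given the rng state."""
    out = image
    if cfg.flip_rotate:
        out = _dihedral(out, int(rng.integers(0, 8)))
    if rng.random() < cfg.jpeg_prob:
        quality = int(rng.integers(cfg.jpeg_quality_range[0],
                                   cfg.jpeg_quality_range[1] + 1))
        buf = io.BytesIO()
        Image.fromarray(out).save(buf, format="JPEG", quality=quality)
        buf.seek(0)
        out = np.asarray(Image.open(buf).convert("RGB"))
    if rng.random() < cfg.blur_prob:
        sigma = float(rng.uniform(*cfg.blur_sigma_range))
        blurred = gaussian_filter(out.astype(float), sigma=(sigma, sigma, 0))
        out = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# The mini classifier (numpy MLP, manual backprop, Adam)
# ---------------------------------------------------------------------------


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MiniClassifier:
    """MLP on flattened tiles satisfying the predict() contract.

    predict() resizes to the training resolution, applies the configured
    stain normalization, and returns post-softmax rows (categorical) or a
    clipped scalar per image (continuous). Dropout is train-time only, so
    prediction is deterministic and batch-invariant.
    """

    def __init__(self, cfg: ClassifierConfig, classes=("A", "B")):
        self.cfg = cfg
        self.classes = tuple(classes)
        self.outcome_type = (
            "categorical" if cfg.loss == "cross_entropy" else "continuous"
        )
        self.normalization_method = cfg.normalization_method
        self._norm_params = (
            stain.fit(cfg.normalization_method, stain.default_target())
            if cfg.normalization_method != "none"
            else None
        )
        d_in = cfg.input_px * cfg.input_px * 3
        d_out = len(self.classes) if self.outcome_type == "categorical" else 1
        rng = np.random.Generator(np.random.Philox([cfg.seed, 1009]))
        sizes = (d_in, *cfg.hidden_widths, d_out)
        self.weights = [
            rng.normal(0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.history: list[dict] = []
        # calibration metadata used by the concordance pipeline
        self.tile_px = cfg.input_px
        self.tile_um = float(cfg.input_px)
        self.mpp = 1.0

    # -- forward -----------------------------------------------------------

    def _prepare(self, images) -> np.ndarray:
        from skimage.transform import resize

        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        px = self.cfg.input_px
        batch = np.empty((len(images), px * px * 3))
        for i, img in enumerate(images):
            if self._norm_params is not None:
                img = stain.apply(img, self._norm_params)
            x = img.astype(float) / 255.0 if img.dtype == np.uint8 else np.asarray(img, float)
            if x.shape[:2] != (px, px):
                x = resize(x, (px, px), order=1,
                           anti_aliasing=x.shape[0] > px, preserve_range=True)
            batch[i] = x.reshape(-1)
        return batch

    def _forward(self, x: np.ndarray, dropout_rng=None):
        acts = [x]
        masks = []
        h = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < len(self.weights) - 1:
                h = np.maximum(h, 0.0)
                if dropout_rng is not None and self.cfg.dropout > 0:
                    mask = (dropout_rng.random(h.shape) >= self.cfg.dropout) / (
                        1.0 - self.cfg.dropout
                    )
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            acts.append(h)
        return acts, masks

    def predict(self, images) -> np.ndarray:
        """Post-softmax rows (categorical) or clipped scalars (continuous)."""
        x = self._prepare(images)
        acts, _ = self._forward(x, dropout_rng=None)
        z = acts[-1]
        if self.outcome_type == "categorical":
            return _softmax(z)
        return np.clip(z[:, 0], -1.0, 1.0)

    def predictions(self, images) -> list:
        out = self.predict(images)
        if self.outcome_type == "categorical":
            return [Prediction("categorical", row) for row in out]
        return [Prediction("continuous", v) for v in out]


def _balanced_batch_indices(categories: np.ndarray, batch_size: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Category-level balanced sampling: equal expected count per category."""
    cats = np.unique(categories)
    per = batch_size // len(cats)
    extra = batch_size - per * len(cats)
    idx = []
    order = rng.permutation(len(cats))
    for j, ci in enumerate(order):
        want = per + (1 if j < extra else 0)
        pool = np.flatnonzero(categories == cats[ci])
        if len(pool) == 0:
            raise BalancingError(f"category {cats[ci]!r} is empty")
        idx.append(rng.choice(pool, size=want, replace=len(pool) < want))
    return np.concatenate(idx)


def train_classifier(tiles, labels, cfg: ClassifierConfig,
                     classes=None) -> MiniClassifier:
    """Train the mini classifier on (tiles, labels).

    Categorical: labels are class ids; continuous: labels are scores in
    [-1, 1] and balancing categories are their signs.
    """
    tiles = np.asarray(tiles)
    labels = np.asarray(labels)
    if cfg.loss == "cross_entropy":
        found = sorted(set(labels.tolist()))
        if len(found) < 2:
            raise BalancingError("need at least 2 categories")
        if classes is None:
            classes = found
        y_idx = np.array([list(classes).index(l) for l in labels])
        balance_cats = y_idx
    else:
        if float(labels.std()) == 0.0:
            raise BalancingError("continuous target is constant")
        classes = classes or ("A", "B")
        y_cont = labels.astype(float)
        balance_cats = (y_cont >= 0).astype(int)
        if len(np.unique(balance_cats)) < 2:
            balance_cats = np.zeros(len(labels), dtype=int)

    model = MiniClassifier(cfg, classes=classes)
    rng = np.random.Generator(np.random.Philox([cfg.seed, 31337]))
    aug_cfg = cfg.augment

    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    for step in range(1, cfg.steps + 1):
        idx = _balanced_batch_indices(balance_cats, cfg.batch_size, rng)
        batch_imgs = tiles[idx]
        if aug_cfg is not None:
            batch_imgs = np.stack([augment(im, aug_cfg, rng) for im in batch_imgs])
        x = model._prepare(batch_imgs)
        acts, masks = model._forward(x, dropout_rng=rng)
        z = acts[-1]
        n = len(idx)

        if cfg.loss == "cross_entropy":
            probs = _softmax(z)
            yb = y_idx[idx]
            loss = -np.log(np.maximum(probs[np.arange(n), yb], 1e-12)).mean()
            dz = probs.copy()
            dz[np.arange(n), yb] -= 1.0
            dz /= n
        else:
            yb = y_cont[idx]
            diff = z[:, 0] - yb
            loss = float((diff**2).mean())
            dz = (2.0 * diff / n)[:, None]

        grads_w, grads_b = [], []
        delta = dz
        for i in reversed(range(len(model.weights))):
            grads_w.append(acts[i].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = delta @ model.weights[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        grads_w.reverse()
        grads_b.reverse()

        t = step
        for i in range(len(model.weights)):
            for (params, grads, ms, vs) in (
                (model.weights, grads_w, m_w, v_w),
                (model.biases, grads_b, m_b, v_b),
            ):
                ms[i] = beta1 * ms[i] + (1 - beta1) * grads[i]
                vs[i] = beta2 * vs[i] + (1 - beta2) * grads[i] ** 2
                mhat = ms[i] / (1 - beta1**t)
                vhat = vs[i] / (1 - beta2**t)
                params[i] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

        if step % 50 == 0 or step == 1:
            model.history.append({"step": step, "loss": float(loss)})
    return model


# ---------------------------------------------------------------------------
# AUROC and DeLong
# ---------------------------------------------------------------------------


def auroc(labels, scores) -> float:
    """Mann-Whitney AUROC (ties counted half)."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("both classes must be present")
    ranks = sp_stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _delong_components(labels: np.ndarray, scores: np.ndarray):
    """Structural components: per-positive and per-negative placements."""
    pos = scores[labels]
    neg = scores[~labels]
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_variance(labels, scores) -> float:
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    _, v10, v01 = _delong_components(labels, scores)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_ci(labels, scores, level: float = 0.95):
    """(auroc, lower, upper) via the DeLong variance, normal approximation."""
    a = auroc(labels, scores)
    var = delong_variance(labels, scores)
    if var <= 0:
        log.warning("degenerate DeLong variance; CI collapses to the estimate")
        clipped = float(np.clip(a, 0, 1))
        return a, clipped, clipped
    z = sp_stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return a, float(np.clip(a - half, 0, 1)), float(np.clip(a + half, 0, 1))


def delong_test(labels, scores_a, scores_b, two_sided: bool = True) -> float:
    """DeLong comparison of two paired AUROCs; returns the p-value."""
    labels = np.asarray(labels).astype(bool)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if labels.all() or not labels.any():
        raise UndefinedMetricError("both classes must be present")
    ta, v10a, v01a = _delong_components(labels, sa)
    tb, v10b, v01b = _delong_components(labels, sb)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return 1.0 if ta == tb else 0.0
    z = (ta - tb) / np.sqrt(var_diff)
    if two_sided:
        return float(2 * sp_stats.norm.sf(abs(z)))
    return float(sp_stats.norm.sf(z))
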