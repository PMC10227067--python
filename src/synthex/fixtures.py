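"""Synthetic pseudo-histology fixtures.

Everything downstream of a whole-slide scanner is emulated here: textured
tiles belonging to two visually separable classes joined by a continuous
morphology score, synthetic slides with known tissue / background / blurred
regions, and an analytic conditional generator whose class response is an
exact linear function of its per-layer embeddings.

Class A (score -1) renders round "follicle" blobs with a cool tint; class B
(score +1) renders striated bands with a warm tint. Intermediate scores
alpha-blend the two renderings of the same seed, so every per-channel image
mean is linear in the score before quantization.

All operations are pure functions of their arguments (seeds included); no
global RNG state is touched.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

# Cool (class A) and warm (class B) tints, chosen far apart in RGB so the
# class axis is recoverable from mean color alone.
DEFAULT_PALETTE = ((90, 80, 200), (220, 90, 70))

# Per-pixel speckle amplitude. Tissue must carry enough high-frequency
# energy that an in-focus tile clears the blur-QC threshold of 0.02
# (variance of the Gaussian-residual on a [0,1] scale).
_SPECKLE_STD = 0.18

# Tile background: near-white with an eosin-like cast (channel spread > the
# grayspace threshold, so tissue is never mistaken for background).
_TILE_BG = (0.97, 0.90, 0.94)

# Darker base used when tissue is rendered onto a slide, separating tissue
# from the white slide background under slide-level Otsu thresholding.
_SLIDE_TISSUE_BG = (0.72, 0.62, 0.70)

#: Layer count and embedding dimension of the analytic generator.
ANALYTIC_LAYERS = 4
ANALYTIC_DIM = 4


class ParameterError(ValueError):
    """An argument violates a fixture precondition."""


@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one synthetic tile.

    class_score runs from -1 (pure class A morphology) to +1 (pure class B);
    identical (spec, seed) pairs yield bit-identical images.
    """

    class_score: float
    size_px: int = 64
    seed: int = 0
    palette: tuple = DEFAULT_PALETTE
    structure_density: float = 0.5
    background: tuple = _TILE_BG

    def __post_init__(self):
        if not (-1.0 <= self.class_score <= 1.0):
            raise ParameterError(
                f"class_score must lie in [-1, 1], got {self.class_score}"
            )
        if self.size_px <= 0:
            raise ParameterError(f"size_px must be positive, got {self.size_px}")
        if self.seed < 0:
            raise ParameterError(f"seed must be non-negative, got {self.seed}")
        if not (0.0 <= self.structure_density <= 1.0):
            raise ParameterError("structure_density must lie in [0, 1]")


@dataclass
class SyntheticSlide:
    """A miniature stand-in for a calibrated whole-slide image.

    tissue_mask is ground truth (True over tissue); blur_regions are
    (x, y, w, h) rectangles that were defocused after rendering; roi is a
    list of polygons, each an (n, 2) array of (x, y) pixel vertices.
    """

    image: np.ndarray
    mpp: float
    tissue_mask: np.ndarray
    roi: list
    blur_regions: list
    label: object = None
    slide_id: str = "synthetic"

    def save(self, png_path, sidecar_path=None):
        """Write the slide as PNG plus a JSON sidecar with its metadata."""
        Image.fromarray(self.image).save(png_path)
        meta = {
            "slide_id": self.slide_id,
            "mpp": self.mpp,
            "roi": [np.asarray(p).tolist() for p in self.roi],
            "blur_regions": [list(map(int, r)) for r in self.blur_regions],
            "label": self.label,
        }
        if sidecar_path is None:
            sidecar_path = str(png_path) + ".json"
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh)


def _float_to_u8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def _follicle_mask(rng: np.random.Generator, n: int, density: float) -> np.ndarray:
    """Round blobs on a grid-jittered layout (class A architecture)."""
    yy, xx = np.mgrid[0:n, 0:n]
    mask = np.zeros((n, n), dtype=float)
    n_blobs = max(3, int(density * (n / 8) ** 2 * 0.5))
    cx = rng.uniform(0, n, n_blobs)
    cy = rng.uniform(0, n, n_blobs)
    radii = rng.uniform(n / 24, n / 8, n_blobs)
    for x0, y0, r in zip(cx, cy, radii):
        d2 = (xx - x0) ** 2 + (yy - y0) ** 2
        mask = np.maximum(mask, np.exp(-d2 / (2 * (r / 1.5) ** 2)))
    return mask


def _band_mask(rng: np.random.Generator, n: int, density: float) -> np.ndarray:
    """Striated diagonal bands (class B architecture)."""
    yy, xx = np.mgrid[0:n, 0:n]
    theta = rng.uniform(0, np.pi)
    freq = (2 + 6 * density) * 2 * np.pi / n
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
    return 0.5 + 0.5 * wave


def _render_class_images(spec: TextureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the pure class A and class B float images for spec's seed.

    Both use the same speckle field so the alpha blend is the only thing the
    class score changes.
    """
    n = spec.size_px
    rng = np.random.Generator(np.random.Philox(spec.seed))
    mask_a = _follicle_mask(rng, n, spec.structure_density)
    mask_b = _band_mask(rng, n, spec.structure_density)
    speckle = rng.normal(0.0, _SPECKLE_STD, (n, n, 1))

    bg = np.asarray(spec.background, float)
    tint_a = np.asarray(spec.palette[0], float) / 255.0
    tint_b = np.asarray(spec.palette[1], float) / 255.0

    # The speckle field is shared by both class renderings with a constant
    # amplitude, so blending the two images is linear in alpha and the
    # high-frequency energy is uniform across the class axis.
    img_a = bg * (1 - mask_a[..., None]) + tint_a * mask_a[..., None] + speckle
    img_b = bg * (1 - mask_b[..., None]) + tint_b * mask_b[..., None] + speckle
    return img_a, img_b


def gen_texture_tile(spec: TextureSpec) -> np.ndarray:
    """Deterministically render one RGB uint8 tile for the given spec.

    The float image is an exact alpha blend of the seed's pure class A and
    class B renderings with alpha = (class_score + 1) / 2, so channel means
    are monotone (linear, pre-quantization) in the class score.
    """
    img_a, img_b = _render_class_images(spec)
    alpha = (spec.class_score + 1.0) / 2.0
    return _float_to_u8((1.0 - alpha) * img_a + alpha * img_b)


# ---------------------------------------------------------------------------
# Synthetic slides
# ---------------------------------------------------------------------------

#: Slide geometry is laid out on multiples of this many pixels, so tissue and
#: blur boundaries coincide with tile boundaries for the default tiling
#: presets and QC decisions are never borderline.
SLIDE_GRID_UNIT = 128


def gen_synthetic_slide(
    n_tissue_blobs: int = 3,
    background_fraction: float = 0.5,
    blur_fraction: float = 0.0,
    seed: int = 0,
    size_px: int = 1024,
    mpp: float = 1.0,
    label=None,
) -> SyntheticSlide:
    """Compose a slide of rectangular tissue patches on a white background.

    Patches are axis-aligned rectangles snapped to SLIDE_GRID_UNIT, pairwise
    non-adjacent (so the tissue mask has exactly n_tissue_blobs connected
    components), textured like class tiles; blur_fraction of the tissue cells
    are defocused with a sigma-8 Gaussian. The ROI covers all tissue patches.
    """
    if not (0.0 <= background_fraction <= 1.0) or not (0.0 <= blur_fraction <= 1.0):
        raise ParameterError("fractions must lie in [0, 1]")
    if background_fraction + blur_fraction > 1.0:
        raise ParameterError("background_fraction + blur_fraction must not exceed 1")
    if size_px % SLIDE_GRID_UNIT:
        raise ParameterError(f"size_px must be a multiple of {SLIDE_GRID_UNIT}")

    rng = np.random.Generator(np.random.Philox([seed, 17]))
    u = SLIDE_GRID_UNIT
    cells = size_px // u

    # Background: near-white with faint sensor noise (gray, low frequency).
    img = np.full((size_px, size_px, 3), 0.97)
    img += rng.normal(0, 0.004, (size_px, size_px, 1))

    tissue_mask = np.zeros((size_px, size_px), dtype=bool)
    blur_regions: list[tuple[int, int, int, int]] = []
    roi_polys: list[np.ndarray] = []

    if background_fraction < 1.0 and n_tissue_blobs > 0:
        target_cells = max(
            n_tissue_blobs, int(round((1.0 - background_fraction) * cells * cells))
        )
        # Split the budget into n rectangles on a parity-offset lattice so no
        # two patches touch (8-connectivity safe): patch corners sit on even
        # cell coordinates and each patch spans an odd region? Simpler: place
        # rectangles greedily with a one-cell empty margin.
        occupied = np.zeros((cells, cells), dtype=bool)
        per_blob = max(1, target_cells // n_tissue_blobs)
        placed = 0
        attempts = 0
        while placed < n_tissue_blobs and attempts < 4000:
            attempts += 1
            # shrink the requested patch as attempts accumulate, so dense
            # layouts still terminate with non-adjacent rectangles
            want = max(1, int(round(per_blob * max(0.25, 1.0 - attempts / 1000))))
            bw = min(cells, int(np.ceil(np.sqrt(want))))
            bh = min(cells, int(np.ceil(want / bw)))
            x0 = int(rng.integers(0, cells - bw + 1))
            y0 = int(rng.integers(0, cells - bh + 1))
            lo_x, hi_x = max(0, x0 - 1), min(cells, x0 + bw + 1)
            lo_y, hi_y = max(0, y0 - 1), min(cells, y0 + bh + 1)
            if occupied[lo_y:hi_y, lo_x:hi_x].any():
                continue
            occupied[y0 : y0 + bh, x0 : x0 + bw] = True
            placed += 1
            px, py, pw, ph = x0 * u, y0 * u, bw * u, bh * u
            tissue_mask[py : py + ph, px : px + pw] = True
            score = float(rng.uniform(-1, 1)) if label is None else (
                -1.0 if label == "A" else 1.0 if label == "B" else float(label)
            )
            patch = gen_texture_tile(
                TextureSpec(
                    class_score=score,
                    size_px=max(pw, ph),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    background=_SLIDE_TISSUE_BG,
                )
            )
            img[py : py + ph, px : px + pw] = (
                patch[:ph, :pw].astype(float) / 255.0
            )
            roi_polys.append(
                np.array(
                    [[px, py], [px + pw, py], [px + pw, py + ph], [px, py + ph]],
                    dtype=float,
                )
            )
        if placed < n_tissue_blobs:
            raise ParameterError(
                "could not place non-adjacent tissue patches; lower "
                "n_tissue_blobs or background_fraction"
            )

        # Defocus a blur_fraction share of tissue cells, snapped to the grid.
        if blur_fraction > 0:
            from scipy.ndimage import gaussian_filter

            ys, xs = np.nonzero(occupied)
            n_blur = int(round(blur_fraction * len(xs)))
            order = rng.permutation(len(xs))[:n_blur]
            for i in order:
                px, py = int(xs[i]) * u, int(ys[i]) * u
                region = img[py : py + u, px : px + u]
                img[py : py + u, px : px + u] = gaussian_filter(
                    region, sigma=(8, 8, 0)
                )
                blur_regions.append((px, py, u, u))

    return SyntheticSlide(
        image=_float_to_u8(img),
        mpp=mpp,
        tissue_mask=tissue_mask,
        roi=roi_polys,
        blur_regions=blur_regions,
        label=label,
        slide_id=f"synthetic-{seed}",
    )


# ---------------------------------------------------------------------------
# Analytic conditional generator
# ---------------------------------------------------------------------------

# The corner tag lets oracle code recover the generator's exact float64
# class response from the rendered image: pixel (0,0) is a magic marker and
# pixels (0,1..3) carry the 8 payload bytes + a parity byte.
_TAG_MAGIC = (7, 121, 233)


def _stamp_score(img: np.ndarray, score: float) -> np.ndarray:
    out = img.copy()
    payload = struct.pack("<d", float(score))
    parity = 0
    for b in payload:
        parity ^= b
    bytes9 = payload + bytes([parity])
    out[0, 0] = _TAG_MAGIC
    out[0, 1:4] = np.frombuffer(bytes9, dtype=np.uint8).reshape(3, 3)
    return out


def read_score_tag(img: np.ndarray):
    """Return the stamped class response, or None if the tag is absent."""
    if img.shape[0] < 1 or img.shape[1] < 4:
        return None
    if tuple(int(v) for v in img[0, 0]) != _TAG_MAGIC:
        return None
    bytes9 = bytes(img[0, 1:4].reshape(-1).astype(np.uint8).tolist())
    payload, parity = bytes9[:8], bytes9[8]
    check = 0
    for b in payload:
        check ^= b
    if check != parity:
        return None
    return struct.unpack("<d", payload)[0]


class InterfaceError(ValueError):
    """Embedding list has the wrong length or dimension."""


def analytic_layer_weights() -> np.ndarray:
    """The fixed unit vectors w_l; with d = L they are the standard basis."""
    return np.eye(ANALYTIC_LAYERS, ANALYTIC_DIM)


#: Published fixture embeddings: class A responds -1 at every layer, B +1.
EMBEDDING_A = -np.ones(ANALYTIC_DIM)
EMBEDDING_B = np.ones(ANALYTIC_DIM)


def analytic_response(per_layer_embeddings) -> float:
    """Closed-form class response (1/L) * sum_l <w_l, e_l>."""
    embs = [np.asarray(e, dtype=float) for e in per_layer_embeddings]
    if len(embs) != ANALYTIC_LAYERS:
        raise InterfaceError(
            f"expected {ANALYTIC_LAYERS} embeddings, got {len(embs)}"
        )
    w = analytic_layer_weights()
    acc = 0.0
    for l, e in enumerate(embs):
        if e.shape != (ANALYTIC_DIM,):
            raise InterfaceError(
                f"embedding {l} has shape {e.shape}, expected ({ANALYTIC_DIM},)"
            )
        acc += float(w[l] @ e)
    return acc / ANALYTIC_LAYERS


def analytic_generator(seed: int, per_layer_embeddings, size_px: int = 64) -> np.ndarray:
    """Render the tile whose class score is the closed-form embedding response.

    The exact float64 response is stamped into a 4-pixel corner tag so oracle
    classifiers can check blending arithmetic bit-exactly.
    """
    score = analytic_response(per_layer_embeddings)
    img = gen_texture_tile(
        TextureSpec(class_score=float(np.clip(score, -1, 1)), size_px=size_px, seed=seed)
    )
    return _stamp_score(img, score)


class AnalyticGenerator:
    """Deterministic generator satisfying the conditional-generator contract.

    Its class response is exactly linear in every per-layer embedding, which
    makes it the closed-form oracle for class and layer blending.
    """

    n_layers = ANALYTIC_LAYERS
    embedding_dim = ANALYTIC_DIM
    classes = ("A", "B")
    #: field of view, so concordance can match classifier calibration
    tile_um = 64.0
    mpp = 1.0

    def __init__(self, image_size: int = 64):
        self.image_size = image_size

    def embed_class(self, class_id):
        if class_id == "A":
            return EMBEDDING_A.copy()
        if class_id == "B":
            return EMBEDDING_B.copy()
        raise KeyError(f"unknown class {class_id!r}")

    def generate(self, seed: int, embeddings) -> np.ndarray:
        return analytic_generator(seed, embeddings, size_px=self.image_size)


class OracleClassifier:
    """Classifier that reads the analytic generator's stamped class response.

    Continuous outcome on [-1, 1]; falls back to a mean-color projection for
    untagged images (trained-texture tiles), so it stays usable on plain
    fixture tiles. An optional flip rate corrupts the sign with a seeded coin
    per image, for Monte-Carlo concordance studies.
    """

    outcome_type = "continuous"
    classes = ("A", "B")
    tile_um = 64.0
    mpp = 1.0
    tile_px = 64
    normalization_method = "none"

    def __init__(self, flip_rate: float = 0.0, seed: int = 0):
        self.flip_rate = flip_rate
        self._rng = np.random.Generator(np.random.Philox([seed, 41]))
        a = np.asarray(DEFAULT_PALETTE[0], float)
        b = np.asarray(DEFAULT_PALETTE[1], float)
        self._axis = (b - a) / np.dot(b - a, b - a)
        self._mid = (a + b) / 2.0

    def predict(self, images) -> np.ndarray:
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        out = np.empty(len(images))
        for i, img in enumerate(images):
            tag = read_score_tag(img)
            if tag is not None:
                out[i] = tag
            else:
                mean = img.reshape(-1, 3).mean(axis=0)
                out[i] = float(np.clip(2.0 * (mean - self._mid) @ self._axis, -1, 1))
            if self.flip_rate > 0 and self._rng.random() < self.flip_rate:
                out[i] = -out[i]
        return out
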