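"""Tile extraction and quality control for calibrated slides.

Tiles are cut on a non-overlapping grid of half-open windows addressed by
their 0-based top-left corner; the source window width in pixels is
round(tile_um / mpp) and each window is resampled (bilinear) to tile_px.
With a region of interest, a tile is emitted iff its center lies inside one
of the ROI polygons.

QC mirrors standard whole-slide background removal: grayspace filtering,
slide-level Otsu thresholding on a grayscale thumbnail, and Gaussian-blur
filtering (sigma 3, threshold 0.02 on the residual-variance score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.transform import resize

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """The slide lacks the μm-per-pixel calibration tiling requires."""


@dataclass(frozen=True)
class TilingSpec:
    """Tile geometry: physical width, output pixels, and slide calibration.

    Classifier preset: 302 μm at 299 px. Generator presets: 400 or 302 μm at
    512 px.
    """

    tile_um: float = 302.0
    tile_px: int = 299
    mpp: float | None = None

    def source_window_px(self, mpp: float | None = None) -> int:
        mpp = self.mpp if mpp is None else mpp
        if mpp is None or mpp <= 0:
            raise CalibrationError("μm-per-pixel calibration is missing")
        return int(round(self.tile_um / mpp))


@dataclass(frozen=True)
class TileQCConfig:
    """Thresholds for the three background/blur filters.

    blur_sigma / blur_threshold are the Gaussian-blur filter parameters; the
    grayspace and Otsu parameters are package defaults (exposed here) in the
    spirit of standard WSI QC.
    """

    blur_sigma: float = 3.0
    blur_threshold: float = 0.02
    grayspace_pixel_threshold: float = 0.05
    grayspace_fraction_max: float = 0.7
    otsu_foreground_min: float = 0.5

    def __post_init__(self):
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")
        for name in (
            "blur_threshold",
            "grayspace_pixel_threshold",
            "grayspace_fraction_max",
            "otsu_foreground_min",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class Tile:
    """One extracted tile with its QC scores and keep/reject decision."""

    slide_id: str
    x: int
    y: int
    image: np.ndarray
    qc: dict = field(default_factory=dict)
    keep: bool = True
    reject_reasons: frozenset = frozenset()


def _slide_image(slide) -> np.ndarray:
    return slide.image if hasattr(slide, "image") else np.asarray(slide)


def _slide_mpp(slide, spec: TilingSpec) -> float:
    mpp = getattr(slide, "mpp", None)
    if mpp is None:
        mpp = spec.mpp
    if mpp is None or mpp <= 0:
        raise CalibrationError("slide has no μm-per-pixel calibration")
    return float(mpp)


def _roi_polygons(roi):
    if roi is None:
        return None
    polys = [Polygon(np.asarray(p, dtype=float)) for p in roi]
    return [p for p in polys if not p.is_empty] or None


def grid_tiles(slide, spec: TilingSpec, roi=None) -> list[Tile]:
    """Cut the non-overlapping tile grid (pre-QC).

    Windows are half-open [x, x+w) × [y, y+h); a window is emitted iff it
    fits entirely inside the slide and (with an ROI) its center lies inside
    an ROI polygon. A slide smaller than one window yields an empty list.
    """
    img = _slide_image(slide)
    mpp = _slide_mpp(slide, spec)
    w = spec.source_window_px(mpp)
    H, W = img.shape[:2]
    if roi is None:
        roi = getattr(slide, "roi", None) or None
    polys = _roi_polygons(roi)
    slide_id = getattr(slide, "slide_id", "slide")

    tiles = []
    for y in range(0, H - w + 1, w):
        for x in range(0, W - w + 1, w):
            if polys is not None:
                center = Point(x + w / 2.0, y + w / 2.0)
                if not any(p.contains(center) for p in polys):
                    continue
            window = img[y : y + w, x : x + w]
            if spec.tile_px != w:
                out = resize(
                    window.astype(float) / 255.0,
                    (spec.tile_px, spec.tile_px),
                    order=1,
                    anti_aliasing=w > spec.tile_px,
                    preserve_range=True,
                )
                window = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
            tiles.append(Tile(slide_id=slide_id, x=x, y=y, image=window))
    return tiles


def slide_otsu_threshold(slide, max_thumbnail: int = 1024) -> float:
    """Slide-level Otsu threshold on a grayscale thumbnail, [0, 1] scale.

    Foreground (tissue) is darker than the near-white background, so tissue
    pixels fall BELOW the returned threshold.
    """
    img = _slide_image(slide)
    gray = rgb2gray(img)
    scale = max(gray.shape) / max_thumbnail
    if scale > 1:
        step = int(np.ceil(scale))
        gray = gray[::step, ::step]
    return float(threshold_otsu(gray))


def blur_score(image: np.ndarray, sigma: float = 3.0) -> float:
    """High-frequency energy: variance of (gray − gaussian(gray, σ))."""
    gray = rgb2gray(image)
    residual = gray - gaussian_filter(gray, sigma=sigma)
    return float(residual.var())


def qc_filter(tile: Tile, cfg: TileQCConfig, otsu_threshold: float) -> Tile:
    """Populate a tile's QC scores and keep/reject decision (idempotent).

    otsu_threshold is the slide-level value from slide_otsu_threshold; the
    tile's otsu_foreground_fraction is its share of pixels darker than that.
    """
    img = tile.image.astype(float) / 255.0
    spread = img.max(axis=2) - img.min(axis=2)
    grayspace_fraction = float((spread < cfg.grayspace_pixel_threshold).mean())
    gray = rgb2gray(tile.image)
    otsu_foreground_fraction = float((gray < otsu_threshold).mean())
    score = blur_score(tile.image, sigma=cfg.blur_sigma)

    reasons = set()
    if grayspace_fraction > cfg.grayspace_fraction_max:
        reasons.add("grayspace")
    if otsu_foreground_fraction < cfg.otsu_foreground_min:
        reasons.add("background")
    if score < cfg.blur_threshold:
        reasons.add("blur")

    return Tile(
        slide_id=tile.slide_id,
        x=tile.x,
        y=tile.y,
        image=tile.image,
        qc={
            "grayspace_fraction": grayspace_fraction,
            "otsu_foreground_fraction": otsu_foreground_fraction,
            "blur_score": score,
        },
        keep=not reasons,
        reject_reasons=frozenset(reasons),
    )


def extract_tiles(slide, spec: TilingSpec, qc: TileQCConfig | None = None, roi=None):
    """grid_tiles + qc_filter against the slide-level Otsu threshold."""
    qc = qc or TileQCConfig()
    threshold = slide_otsu_threshold(slide)
    return [qc_filter(t, qc, threshold) for t in grid_tiles(slide, spec, roi=roi)]


def manifest(tiles) -> "pandas.DataFrame":
    """Tab-separable manifest of tile coordinates, QC scores, decisions."""
    import pandas as pd

    rows = []
    for t in tiles:
        rows.append(
            {
                "slide_id": t.slide_id,
                "x": t.x,
                "y": t.y,
                "keep": t.keep,
                "reject_reasons": ",".join(sorted(t.reject_reasons)),
                **{k: t.qc.get(k) for k in
                   ("grayspace_fraction", "otsu_foreground_fraction", "blur_score")},
            }
        )
    return pd.DataFrame(rows)
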