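"""Stain normalization: Reinhard, modified Reinhard, Macenko, or none.

Reinhard color transfer matches per-channel mean and standard deviation in
CIELAB. The full variant first standardizes brightness (rescales the image
so its 95th-percentile luminance maps to 0.95) before fitting/applying; the
modified variant omits that step, trading brightness invariance for speed.

Macenko estimates the two stain vectors (hematoxylin, eosin) as the extreme
angles of the optical-density point cloud within its top-2 principal plane,
then rescales stain concentrations to a target's percentile maxima.

Normalization is applied before classifier inference only; generated images
are left untouched at generation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import lab2rgb, rgb2gray, rgb2lab

log = logging.getLogger(__name__)

#: Reference luminance the 95th percentile maps to during brightness
#: standardization (full Reinhard only).
BRIGHTNESS_REFERENCE = 0.95
BRIGHTNESS_PERCENTILE = 95.0


class DegenerateTargetError(ValueError):
    """Fit target has no color variance."""


class InsufficientTissueError(ValueError):
    """Too few optical-density pixels above beta to fit stain vectors."""


@dataclass(frozen=True)
class ReinhardParams:
    target_means: tuple
    target_stds: tuple
    modified: bool

    def __post_init__(self):
        if any(s <= 0 for s in self.target_stds):
            raise ValueError("target stds must be strictly positive")

    def to_dict(self):
        return {
            "method": "reinhard_mod" if self.modified else "reinhard",
            "target_means": list(self.target_means),
            "target_stds": list(self.target_stds),
        }


@dataclass(frozen=True)
class MacenkoParams:
    stain_matrix: np.ndarray  # 3x2 OD basis, columns H then E, unit norm
    max_concentrations: np.ndarray  # length-2, percentile-based

    def to_dict(self):
        return {
            "method": "macenko",
            "stain_matrix": self.stain_matrix.tolist(),
            "max_concentrations": self.max_concentrations.tolist(),
        }


def _as_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    return img.astype(float)


def _to_u8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def _standardize_brightness(img: np.ndarray) -> np.ndarray:
    """Scale so the 95th-percentile luminance maps to the reference."""
    p = np.percentile(rgb2gray(img), BRIGHTNESS_PERCENTILE)
    if p <= 0:
        return img
    return np.clip(img * (BRIGHTNESS_REFERENCE / p), 0.0, 1.0)


def fit_reinhard(target_image: np.ndarray, modified: bool = True) -> ReinhardParams:
    """Fit per-channel LAB mean/std on the target image."""
    img = _as_float(target_image)
    if float(img.std()) == 0.0:
        raise DegenerateTargetError("target image is constant")
    if not modified:
        img = _standardize_brightness(img)
    lab = rgb2lab(img)
    means = tuple(float(m) for m in lab.reshape(-1, 3).mean(axis=0))
    stds = tuple(float(s) for s in lab.reshape(-1, 3).std(axis=0))
    if any(s == 0 for s in stds):
        raise DegenerateTargetError("target has a zero-variance LAB channel")
    return ReinhardParams(target_means=means, target_stds=stds, modified=modified)


def apply_reinhard(image: np.ndarray, params: ReinhardParams) -> np.ndarray:
    """Linear per-channel transfer (x−μ_src)·(σ_tgt/σ_src)+μ_tgt in LAB."""
    was_u8 = np.asarray(image).dtype == np.uint8
    img = _as_float(image)
    if not params.modified:
        img = _standardize_brightness(img)
    lab = rgb2lab(img)
    flat = lab.reshape(-1, 3)
    mu_s = flat.mean(axis=0)
    sd_s = flat.std(axis=0)
    out = np.empty_like(flat)
    for c in range(3):
        if sd_s[c] == 0:
            log.warning("zero source std in LAB channel %d; passing through", c)
            out[:, c] = flat[:, c] - mu_s[c] + params.target_means[c]
        else:
            out[:, c] = (flat[:, c] - mu_s[c]) * (
                params.target_stds[c] / sd_s[c]
            ) + params.target_means[c]
    rgb = np.clip(lab2rgb(out.reshape(lab.shape)), 0.0, 1.0)
    return _to_u8(rgb) if was_u8 else rgb


# ---------------------------------------------------------------------------
# Macenko
# ---------------------------------------------------------------------------

_OD_FLOOR = 1e-6
_MIN_OD_PIXELS = 100


def _optical_density(img01: np.ndarray) -> np.ndarray:
    return -np.log(np.maximum(img01, _OD_FLOOR))


def fit_macenko(
    image: np.ndarray, beta: float = 0.15, alpha_percentile: float = 1.0
) -> MacenkoParams:
    """Estimate the 3×2 stain basis and 99th-percentile concentrations.

    Pixels with all OD channels above beta form the point cloud; the basis
    columns are the extreme-angle directions (alpha_percentile from either
    end) within the cloud's top-2 principal plane, oriented non-negative,
    unit norm, hematoxylin (higher red absorption) first.
    """
    img = _as_float(image)
    od = _optical_density(img).reshape(-1, 3)
    tissue = od[(od > beta).all(axis=1)]
    if len(tissue) < _MIN_OD_PIXELS:
        raise InsufficientTissueError(
            f"only {len(tissue)} OD pixels above beta={beta}; need >= {_MIN_OD_PIXELS}"
        )
    # top-2 principal plane of the OD cloud
    _, _, vt = np.linalg.svd(tissue - tissue.mean(axis=0), full_matrices=False)
    plane = vt[:2].copy()  # 2 x 3
    # orient so projections are mostly positive
    proj = tissue @ plane.T
    for k in range(2):
        if proj[:, k].mean() < 0:
            plane[k] = -plane[k]
            proj[:, k] = -proj[:, k]
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha_percentile, 100.0 - alpha_percentile])
    v1 = np.array([np.cos(lo), np.sin(lo)]) @ plane
    v2 = np.array([np.cos(hi), np.sin(hi)]) @ plane
    vecs = []
    for v in (v1, v2):
        if v.sum() < 0:
            v = -v
        v = np.maximum(v, 0.0)
        n = np.linalg.norm(v)
        if n == 0:
            raise InsufficientTissueError("degenerate stain direction")
        vecs.append(v / n)
    # hematoxylin absorbs red light more strongly than eosin: higher red OD first
    if vecs[0][0] < vecs[1][0]:
        vecs = [vecs[1], vecs[0]]
    M = np.stack(vecs, axis=1)  # 3 x 2
    conc = np.linalg.lstsq(M, od.T, rcond=None)[0]  # 2 x N
    maxc = np.percentile(conc, 99.0, axis=1)
    return MacenkoParams(stain_matrix=M, max_concentrations=np.maximum(maxc, _OD_FLOOR))


def apply_macenko(image: np.ndarray, params: MacenkoParams) -> np.ndarray:
    """Refit the image's own stain basis, rescale concentrations to target."""
    was_u8 = np.asarray(image).dtype == np.uint8
    img = _as_float(image)
    src = fit_macenko(image)
    od = _optical_density(img).reshape(-1, 3)
    conc = np.linalg.lstsq(src.stain_matrix, od.T, rcond=None)[0]
    scale = params.max_concentrations / np.maximum(src.max_concentrations, _OD_FLOOR)
    conc = conc * scale[:, None]
    od_out = (params.stain_matrix @ conc).T
    rgb = np.clip(np.exp(-od_out), 0.0, 1.0).reshape(img.shape)
    return _to_u8(rgb) if was_u8 else rgb


# ---------------------------------------------------------------------------
# Uniform front-end
# ---------------------------------------------------------------------------

METHODS = ("reinhard", "reinhard_mod", "macenko", "none")


def fit(method: str, target_image):
    """Fit normalization parameters for the named method (None for 'none')."""
    if method == "none":
        return None
    if method == "reinhard":
        return fit_reinhard(target_image, modified=False)
    if method == "reinhard_mod":
        return fit_reinhard(target_image, modified=True)
    if method == "macenko":
        return fit_macenko(target_image)
    raise ValueError(f"unknown normalization method {method!r}; choose from {METHODS}")


def apply(image, params):
    if params is None:
        return image
    if isinstance(params, ReinhardParams):
        return apply_reinhard(image, params)
    if isinstance(params, MacenkoParams):
        return apply_macenko(image, params)
    raise TypeError(f"unsupported params type {type(params).__name__}")


def default_target(size_px: int = 96) -> np.ndarray:
    """Fixture normalization target shipped with the package (deterministic)."""
    from synthex.fixtures import TextureSpec, gen_texture_tile

    return gen_texture_tile(TextureSpec(class_score=0.0, size_px=size_px, seed=2024))
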