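"""Fréchet distance between Gaussian fits of embedded image features.

FID(a, b) = ||mu_a - mu_b||^2 + tr(S_a + S_b - 2 (S_a S_b)^(1/2)).

The matrix square root is taken through symmetric eigendecompositions
(sqrt(S_a) first, then sqrt(sqrt(S_a) S_b sqrt(S_a)), which shares its
spectrum with S_a S_b), clipping small negative eigenvalues that arise from
floating-point noise. Covariances use the unbiased (n-1) divisor.

The feature embedder is pluggable; the shipped default is a fixed-seed
random-projection network (two leaky-ReLU layers), fully deterministic and
dependency-free. Any callable mapping an image batch to an (n, d) feature
array — e.g. an Inception network from an external weights file — can stand
in for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

_EIG_FLOOR = 0.0  # negative eigenvalues are clipped to this
_IMAG_RTOL = 1e-6


class DimensionMismatchError(ValueError):
    """Feature Gaussians have different dimensions."""


@dataclass(frozen=True)
class FeatureGaussian:
    """Sufficient statistics (mean, covariance, count) of a feature cloud."""

    mean: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 samples")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")


@dataclass(frozen=True)
class FIDConfig:
    embedder: str = "randproj-v1"
    n_generated: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.n_generated < 2:
            raise ValueError("n_generated must be >= 2")


def gaussian_stats(features: np.ndarray) -> FeatureGaussian:
    """Sample mean and unbiased covariance of an (n, d) feature array."""
    feats = np.asarray(features, dtype=float)
    if feats.ndim != 2 or feats.shape[0] < 2:
        raise ValueError("features must be (n >= 2, d)")
    mean = feats.mean(axis=0)
    cov = np.cov(feats, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return FeatureGaussian(mean=mean, cov=cov, n=feats.shape[0])


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, _EIG_FLOOR, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(a: FeatureGaussian, b: FeatureGaussian) -> float:
    """Fréchet distance between two feature Gaussians (>= 0)."""
    if a.mean.shape != b.mean.shape:
        raise DimensionMismatchError(
            f"dimension mismatch: {a.mean.shape} vs {b.mean.shape}"
        )
    diff = a.mean - b.mean
    sqrt_a = _psd_sqrt(a.cov)
    inner = sqrt_a @ b.cov @ sqrt_a
    tr_sqrt = float(np.trace(_psd_sqrt(inner)))
    val = float(diff @ diff + np.trace(a.cov) + np.trace(b.cov) - 2.0 * tr_sqrt)
    # numerical noise can leave a tiny negative residue
    if val < 0:
        if abs(val) > _IMAG_RTOL * max(1.0, abs(np.trace(a.cov))):
            raise linalg.LinAlgError(f"FID came out negative beyond tolerance: {val}")
        val = 0.0
    return val


# ---------------------------------------------------------------------------
# Shipped embedder: fixed-seed random projection network
# ---------------------------------------------------------------------------


class RandomProjectionEmbedder:
    """Deterministic two-layer random-feature embedder.

    Weights are drawn once from a fixed Philox stream; images are resized to
    a canonical input size, scaled to [0, 1], and passed through two
    leaky-ReLU random projections. Not a trained network — a fixed embedding
    under which FID's distributional comparison is still meaningful.
    """

    identifier = "randproj-v1"

    def __init__(self, input_px: int = 32, dim: int = 64, seed: int = 77):
        rng = np.random.Generator(np.random.Philox([seed, 2718]))
        d_in = input_px * input_px * 3
        self.input_px = input_px
        self.dim = dim
        self.w1 = rng.normal(0, 1.0 / np.sqrt(d_in), (d_in, 256))
        self.b1 = rng.normal(0, 0.1, 256)
        self.w2 = rng.normal(0, 1.0 / np.sqrt(256), (256, dim))
        self.b2 = rng.normal(0, 0.1, dim)

    def __call__(self, images) -> np.ndarray:
        from skimage.transform import resize

        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        batch = np.empty((len(images), self.input_px * self.input_px * 3))
        for i, img in enumerate(images):
            x = img.astype(float) / 255.0 if img.dtype == np.uint8 else img.astype(float)
            if x.shape[:2] != (self.input_px, self.input_px):
                x = resize(x, (self.input_px, self.input_px), order=1,
                           anti_aliasing=x.shape[0] > self.input_px,
                           preserve_range=True)
            batch[i] = x.reshape(-1)
        h = batch @ self.w1 + self.b1
        h = np.where(h > 0, h, 0.2 * h)
        z = h @ self.w2 + self.b2
        return np.where(z > 0, z, 0.2 * z)


_DEFAULT_EMBEDDER = None


def default_embedder() -> RandomProjectionEmbedder:
    global _DEFAULT_EMBEDDER
    if _DEFAULT_EMBEDDER is None:
        _DEFAULT_EMBEDDER = RandomProjectionEmbedder()
    return _DEFAULT_EMBEDDER


def fid_between_image_sets(images_a, images_b, cfg: FIDConfig | None = None,
                           embedder=None) -> float:
    """Embed both image sets and return the Fréchet distance."""
    if embedder is None:
        embedder = default_embedder()
    ga = gaussian_stats(embedder(images_a))
    gb = gaussian_stats(embedder(images_b))
    return fid(ga, gb)
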