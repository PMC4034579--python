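"""Center-surround dissimilarity scoring, map algebra and fusion.

The CSD operator scores patch ``i`` by its average feature dissimilarity
to every other patch, damped by inter-patch distance:

    S_i = (1 / (n - 1)) * sum_{j != i}  ||a_i - a_j||_1 / (1 + ||X_i - X_j||_2)

where ``a`` are per-patch feature vectors (sparse codes or sigma-point
embeddings) and ``X`` are patch centers normalized per axis to [0, 1], so
the ``+1`` in the denominator is resolution-free.  The surround is the
whole image (w = n - 1); the 1/(1+dist) weight supplies locality.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .geometry import resize_bilinear

logger = logging.getLogger(__name__)

_CHUNK = 128  # rows of the pairwise blocks held in memory at once


@dataclass(frozen=True)
class FusionConfig:
    """How the two branch maps are fused into the final saliency map.

    sigma_fraction : float
        Std of the final Gaussian smoothing, as a fraction of map width.
        The default 0.04 is in the range this model family reports as
        optimal for fixation prediction.
    """

    sigma_fraction: float = 0.04

    def __post_init__(self) -> None:
        if self.sigma_fraction < 0:
            raise ValueError("sigma_fraction must be >= 0")


def csd_scores(
    features: np.ndarray,
    centers: np.ndarray,
    image_extent: tuple[int, int],
) -> np.ndarray:
    """Distance-weighted center-surround dissimilarity of every patch.

    Parameters
    ----------
    features : (n, q) array
        One feature vector per patch.
    centers : (n, 2) array
        Patch centers, (row, col) in source-image pixels.
    image_extent : (H, W)
        Source image shape used to normalize centers to [0, 1] per axis.

    Returns
    -------
    (n,) non-negative array of saliency scores.
    """
    features = np.asarray(features, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if features.ndim != 2 or centers.shape != (features.shape[0], 2):
        raise ValueError("features must be (n, q) and centers (n, 2)")
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite feature values")
    n = features.shape[0]
    if n < 2:
        warnings.warn("csd_scores called with fewer than 2 patches; returning 0")
        return np.zeros(n)

    h, w = image_extent
    norm = np.array([max(h - 1, 1), max(w - 1, 1)], dtype=float)
    pos = centers / norm

    scores = np.empty(n)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        dissim = cdist(features[start:stop], features, metric="cityblock")
        dist = cdist(pos[start:stop], pos, metric="euclidean")
        # the i == j diagonal contributes 0 to the numerator, so summing
        # over all j and dividing by n - 1 equals the j != i average
        scores[start:stop] = (dissim / (1.0 + dist)).sum(axis=1)
    return scores / (n - 1)


def normalize_map(values: np.ndarray) -> np.ndarray:
    """Min-max rescale a map to [0, 1].

    A constant map maps to all zeros when the constant is 0 and to all
    ones otherwise; the operation is idempotent.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite map values")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values) if hi == 0 else np.ones_like(values)
    return (values - lo) / (hi - lo)


def multiscale_combine(maps: list[np.ndarray]) -> np.ndarray:
    """Normalize each scale's map, multiply elementwise, renormalize."""
    if len(maps) == 0:
        raise ValueError("need at least one map")
    shape = np.shape(maps[0])
    product = np.ones(shape)
    for m in maps:
        if np.shape(m) != shape:
            raise ValueError("all maps must share one resolution")
        product = product * normalize_map(m)
    return normalize_map(product)


def smooth_map(values: np.ndarray, sigma_fraction: float) -> np.ndarray:
    """Gaussian-smooth a map with sigma expressed in image widths.

    Reflective boundary handling; ``sigma_fraction = 0`` is the identity.
    """
    values = np.asarray(values, dtype=float)
    sigma = sigma_fraction * values.shape[1]
    if sigma <= 0:
        return values.copy()
    return gaussian_filter(values, sigma=sigma, mode="reflect")


def fuse_and_smooth(
    sparse_map: np.ndarray,
    cov_map: np.ndarray,
    fusion: FusionConfig | None = None,
    out_height: int | None = None,
    out_width: int | None = None,
) -> np.ndarray:
    """Fuse the two branch maps: resize, multiply, normalize, smooth.

    The sparse-branch map is bilinearly resized to the covariance map's
    resolution (the only dimensionally consistent order, given the two
    branches' working resolutions), the maps are multiplied elementwise
    and normalized, Gaussian smoothing is applied, and the result is
    resized to the requested output shape and normalized again.
    """
    fusion = fusion or FusionConfig()
    cov_map = np.asarray(cov_map, dtype=float)
    h, w = cov_map.shape
    fused = resize_bilinear(np.asarray(sparse_map, dtype=float), h, w) * cov_map
    fused = smooth_map(normalize_map(fused), fusion.sigma_fraction)
    if out_height is not None and out_width is not None:
        fused = resize_bilinear(fused, out_height, out_width)
    return normalize_map(fused)


def run_full_model(
    img: np.ndarray,
    sparse_config=None,
    cov_config=None,
    fusion: FusionConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Run both representation branches and fuse them at native resolution.

    If the sparse branch degenerates (an image with no patch variance has
    no learnable basis), the covariance branch is smoothed and returned
    alone, with a warning.
    """
    from .covariance import covariance_saliency_map
    from .sparse import SparseBranchConfig, sparse_saliency_map

    img = np.asarray(img, dtype=float)
    h, w = img.shape[:2]
    fusion = fusion or FusionConfig()
    if seed is not None:
        sparse_config = (sparse_config or SparseBranchConfig()).with_seed(seed)

    t0 = time.perf_counter()
    s_map, info = sparse_saliency_map(img, sparse_config, return_info=True)
    t1 = time.perf_counter()
    c_map = covariance_saliency_map(img, cov_config)
    t2 = time.perf_counter()
    logger.info(
        "stage timings: sparse=%.2fs covariance=%.2fs", t1 - t0, t2 - t1
    )

    if info["degenerate"]:
        warnings.warn(
            "sparse branch degenerate; returning smoothed covariance branch"
        )
        out = smooth_map(normalize_map(c_map), fusion.sigma_fraction)
        return normalize_map(resize_bilinear(out, h, w))
    return fuse_and_smooth(s_map, c_map, fusion, h, w)
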