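"""Region-covariance color features with first-order sigma-point embedding.

Every pixel carries a 5-vector (R, G, B, x, y).  A patch is summarized by
the covariance matrix of its pixel vectors together with their mean — a
second-order, nonlinear integration of color and position, deliberately
without any gradient or orientation planes.  The (mean, covariance) pair
is flattened into a vector by the sigma-point construction: with Cholesky
factor C = L L^T and columns l_1..l_d,

    psi = (mu, mu + sqrt(d) l_1, ..., mu + sqrt(d) l_d,
               mu - sqrt(d) l_1, ..., mu - sqrt(d) l_d)

so the biased covariance of the 2d offset points reproduces C exactly and
the first block is mu.  The embedding keeps the descriptor in plain
vector form, which is what the L1-based center-surround operator needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .csd import csd_scores, normalize_map
from .exceptions import EmbeddingError
from .geometry import assemble_patch_map, resize_bilinear


@dataclass(frozen=True)
class CovBranchConfig:
    """Parameters of the covariance saliency branch.

    The image is resized to ``resolution`` squared and tiled without
    overlap at each patch size (all sizes divide 512); the five per-scale
    maps are combined by normalized product.

    coordinate_mode : {"local", "global"}
        ``local`` (default) builds the positional planes per patch, so two
        identical textures anywhere in the image get identical descriptors
        and a featureless image scores exactly zero; spatial locality is
        already supplied by the CSD distance weighting.  ``global`` uses
        image-wide normalized coordinates, which adds an explicit spatial
        term to the descriptor itself.
    """

    resolution: int = 512
    patch_sizes: tuple[int, ...] = (8, 16, 32, 64, 128)
    coordinate_mode: str = "local"

    def __post_init__(self) -> None:
        if self.coordinate_mode not in ("local", "global"):
            raise ValueError(f"unknown coordinate_mode {self.coordinate_mode!r}")
        for s in self.patch_sizes:
            if self.resolution % s:
                raise ValueError(
                    f"patch size {s} does not tile resolution {self.resolution}"
                )


@dataclass(frozen=True)
class RegionCovariance:
    """Covariance and mean of the per-pixel feature vectors of one region."""

    covariance: np.ndarray  # (d, d), unbiased (divisor m - 1)
    mean: np.ndarray  # (d,)
    pixel_count: int


@dataclass(frozen=True)
class SigmaFeature:
    """Vector-form sigma-point embedding of a (mean, covariance) pair."""

    vector: np.ndarray  # ((2d + 1) * d,)
    alpha: float  # sigma-point scaling, sqrt(d)


def build_feature_matrix(img: np.ndarray) -> np.ndarray:
    """Per-pixel (R, G, B, x, y) features; coordinates normalized to [0, 1]."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {img.shape}")
    h, w = img.shape[:2]
    x = np.tile(np.arange(w, dtype=float) / max(w - 1, 1), (h, 1))
    y = np.tile((np.arange(h, dtype=float) / max(h - 1, 1))[:, None], (1, w))
    return np.concatenate([img, x[..., None], y[..., None]], axis=2)


def region_covariance(
    features: np.ndarray, top: int, left: int, size: int
) -> RegionCovariance:
    """Unbiased covariance and mean of a square region of a feature image.

    ``features`` is any (H, W, d) per-pixel feature array; the region is
    ``size x size`` pixels with its top-left corner at (top, left).
    """
    features = np.asarray(features, dtype=float)
    h, w = features.shape[:2]
    if size < 2:
        raise ValueError("region size must be >= 2 pixels")
    if top < 0 or left < 0 or top + size > h or left + size > w:
        raise ValueError(
            f"region ({top},{left}) size {size} out of bounds for {h}x{w}"
        )
    pixels = features[top:top + size, left:left + size].reshape(-1, features.shape[2])
    mean = pixels.mean(axis=0)
    # constant feature dimensions get an exact zero, not summation round-off
    constant = np.ptp(pixels, axis=0) == 0
    mean = np.where(constant, pixels[0], mean)
    centered = np.where(constant, 0.0, pixels - mean)
    cov = centered.T @ centered / (pixels.shape[0] - 1)
    return RegionCovariance(covariance=cov, mean=mean, pixel_count=pixels.shape[0])


_JITTER_SCALE = 1e-10
_JITTER_ESCALATIONS = 3


def _cholesky_with_jitter(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    cov = (cov + cov.T) / 2.0
    trace = float(np.trace(cov))
    if trace <= 0:
        if np.allclose(cov, 0):
            return np.zeros_like(cov)
        raise EmbeddingError("covariance has non-positive trace")
    eps = _JITTER_SCALE * trace / d
    for _ in range(_JITTER_ESCALATIONS + 1):
        try:
            return np.linalg.cholesky(cov + eps * np.eye(d))
        except np.linalg.LinAlgError:
            eps *= 10.0
    raise EmbeddingError(
        f"Cholesky failed after jitter escalation (trace={trace:.3g})"
    )


def embed_first_order(rc: RegionCovariance) -> SigmaFeature:
    """Flatten (mu, C) into the sigma-point vector of length (2d + 1) d."""
    mu = np.asarray(rc.mean, dtype=float)
    d = mu.size
    chol = _cholesky_with_jitter(np.asarray(rc.covariance, dtype=float))
    alpha = np.sqrt(d)
    offsets = alpha * chol.T  # row c = alpha * l_c
    points = np.vstack([mu[None, :], mu + offsets, mu - offsets])
    return SigmaFeature(vector=points.ravel(), alpha=float(alpha))


def _tile_sigma_vectors(
    img512: np.ndarray, size: int, coordinate_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Sigma-point vectors and centers for a non-overlapping tiling."""
    res = img512.shape[0]
    g = res // size
    d = 5
    tiles = (
        img512.reshape(g, size, g, size, 3)
        .transpose(0, 2, 1, 3, 4)
        .reshape(g * g, size * size, 3)
    )
    denom = float(max(size - 1, 1))
    local = np.arange(size, dtype=float)
    if coordinate_mode == "local":
        xs = np.tile(local / denom, size)
        ys = np.repeat(local / denom, size)
        coords = np.broadcast_to(
            np.column_stack([xs, ys]), (g * g, size * size, 2)
        )
    else:
        gnorm = float(max(res - 1, 1))
        offs = np.arange(g, dtype=float) * size
        ox = np.tile(offs, g)  # tile raster order: row-major over (gy, gx)
        oy = np.repeat(offs, g)
        xs = (np.tile(local, size)[None, :] + ox[:, None]) / gnorm
        ys = (np.repeat(local, size)[None, :] + oy[:, None]) / gnorm
        coords = np.stack([xs, ys], axis=2)
    pixels = np.concatenate([tiles, coords], axis=2)  # (nt, m, 5)

    means = pixels.mean(axis=1)
    constant = np.ptp(pixels, axis=1) == 0  # (nt, 5)
    means = np.where(constant, pixels[:, 0, :], means)
    centered = np.where(constant[:, None, :], 0.0, pixels - means[:, None, :])
    covs = np.einsum("nij,nik->njk", centered, centered) / (size * size - 1)

    nt = covs.shape[0]
    vectors = np.empty((nt, (2 * d + 1) * d))
    traces = np.trace(covs, axis1=1, axis2=2)
    alpha = np.sqrt(d)
    eye = np.eye(d)
    try:
        eps = _JITTER_SCALE * np.maximum(traces, np.finfo(float).tiny) / d
        chols = np.linalg.cholesky(covs + eps[:, None, None] * eye)
    except np.linalg.LinAlgError:
        chols = np.stack([_cholesky_with_jitter(c) for c in covs])
    chols[traces <= 0] = 0.0
    offsets = alpha * chols.transpose(0, 2, 1)  # (nt, d, d), row c = alpha l_c
    points = np.concatenate(
        [means[:, None, :], means[:, None, :] + offsets, means[:, None, :] - offsets],
        axis=1,
    )
    vectors = points.reshape(nt, -1)

    half = (size - 1) / 2.0
    pos = np.arange(g, dtype=float) * size + half
    rr, cc = np.meshgrid(pos, pos, indexing="ij")
    centers = np.column_stack([rr.ravel(), cc.ravel()])
    return vectors, centers


def covariance_saliency_map(
    img: np.ndarray, config: CovBranchConfig | None = None
) -> np.ndarray:
    """Saliency from the color region-covariance branch.

    The image is resized to 512x512; at each patch size the image is tiled
    without overlap, each tile's (mean, covariance) descriptor is embedded
    as a sigma-point vector and scored by center-surround dissimilarity.
    The per-scale maps are normalized and averaged (the scale combination
    the region-covariance saliency literature uses by default; a product
    would let one scale's multiplicative noise veto the others).  The
    branch is fully deterministic.
    """
    config = config or CovBranchConfig()
    img = np.asarray(img, dtype=float)
    res = config.resolution
    img512 = resize_bilinear(img, res, res)

    acc = np.zeros((res, res))
    for size in config.patch_sizes:
        vectors, centers = _tile_sigma_vectors(img512, size, config.coordinate_mode)
        scores = csd_scores(vectors, centers, (res, res))
        g = res // size
        acc += normalize_map(resize_bilinear(scores.reshape(g, g), res, res))
    return normalize_map(acc / len(config.patch_sizes))
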