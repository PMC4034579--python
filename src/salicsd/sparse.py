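"""Adaptive per-image ICA sparse coding of image patches.

Each input image gets its own complete basis dictionary A (and unmixing
W = A^{-1}) learned by FastICA from the image's own 5x5 RGB patches, so
the representation adapts to the current stimulus instead of relying on
a fixed ensemble-learned dictionary.  Patches are encoded as sparse
coefficient vectors s = W (p - mean); with a complete dictionary the
round trip p = A s + mean is exact, which is the representational
advantage over under-complete fixed dictionaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .csd import csd_scores, multiscale_combine
from .exceptions import DegenerateDictionaryError
from .geometry import PatchGrid, assemble_patch_map, extract_patches, resize_bilinear


@dataclass(frozen=True)
class SparseBranchConfig:
    """Parameters of the adaptive-sparse saliency branch.

    The working resolution is 80x60 (width x height) with dense 5x5 RGB
    patches (d = 75) and a complete dictionary, the setting at which this
    branch peaks on fixation benchmarks.  ``scales`` > 1 adds coarser /
    finer working resolutions (x0.5, x2) whose maps are combined by
    normalized product; the default is the single base scale.
    """

    resolution_w: int = 80
    resolution_h: int = 60
    patch_size: int = 5
    stride: int = 1
    n_components: int = 75
    seed: int = 0
    scales: int = 1

    def with_seed(self, seed: int) -> "SparseBranchConfig":
        return replace(self, seed=seed)

    def scale_resolutions(self) -> list[tuple[int, int]]:
        """(height, width) of each scale: base, then x0.5, then x2."""
        factors = [1.0, 0.5, 2.0][: self.scales]
        return [
            (max(round(self.resolution_h * f), self.patch_size),
             max(round(self.resolution_w * f), self.patch_size))
            for f in factors
        ]


@dataclass(frozen=True)
class AdaptiveDictionary:
    """A per-image ICA basis with its inverse and centering offsets.

    basis : (d, m) array
        Columns are basis functions (the mixing matrix A).
    unmixing : (m, d) array
        Maps centered patch vectors to coefficients (W); when m = d,
        ``unmixing @ basis`` is the identity.
    dimension_means : (d,) array
        Per-dimension means removed before ICA and restored on
        reconstruction.
    converged : bool
        False when FastICA failed to converge and the PCA whitening basis
        was used instead.
    """

    basis: np.ndarray
    unmixing: np.ndarray
    dimension_means: np.ndarray
    converged: bool
    seed: int

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]


@dataclass(frozen=True)
class SparseCodeSet:
    """Sparse coefficient vectors for every patch of one grid."""

    codes: np.ndarray  # (n, m)
    dictionary: AdaptiveDictionary
    grid: PatchGrid


_MAX_RESTARTS = 3


def _whitening_fallback(
    u_sv_vt: tuple[np.ndarray, np.ndarray, np.ndarray], m: int, n: int
) -> tuple[np.ndarray, np.ndarray]:
    _, sv, vt = u_sv_vt
    scale = sv[:m] / np.sqrt(n - 1)
    unmixing = vt[:m] / scale[:, None]
    basis = vt[:m].T * scale
    return basis, unmixing


def learn_adaptive_dictionary(
    grid: PatchGrid,
    n_components: int | None = None,
    seed: int = 0,
) -> AdaptiveDictionary:
    """Learn an ICA basis from the patches of a single image.

    Patches are centered per dimension, whitened, and unmixed with
    symmetric FastICA (tanh/logcosh contrast).  If the patch matrix is
    rank deficient the component count is reduced to the numerical rank.
    Non-convergence triggers up to 3 restarts with incremented seeds and
    finally falls back to the PCA whitening basis (``converged=False``).

    Raises
    ------
    DegenerateDictionaryError
        If the patches carry no variance at all (constant image).
    """
    x = np.asarray(grid.patch_vectors, dtype=float)
    n, d = x.shape
    if np.ptp(x, axis=0).max() <= 1e-12:  # constant image up to round-off
        raise DegenerateDictionaryError(
            "patch matrix has zero variance; no basis can be learned"
        )
    means = x.mean(axis=0)
    xc = x - means

    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    tol = sv[0] * max(n, d) * np.finfo(float).eps if sv.size else 0.0
    rank = int(np.sum(sv > tol))
    if rank == 0:
        raise DegenerateDictionaryError(
            "patch matrix has zero variance; no basis can be learned"
        )

    requested = d if n_components is None else int(n_components)
    if requested < 1:
        raise ValueError("n_components must be >= 1")
    if requested > n:
        raise ValueError("more components than patches")
    m = min(requested, rank)

    for attempt in range(_MAX_RESTARTS + 1):
        ica = FastICA(
            n_components=m,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=300,
            tol=1e-4,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica.fit(xc)
        if not any(issubclass(c.category, ConvergenceWarning) for c in caught):
            return AdaptiveDictionary(
                basis=np.asarray(ica.mixing_, dtype=float),
                unmixing=np.asarray(ica.components_, dtype=float),
                dimension_means=means,
                converged=True,
                seed=seed,
            )
    basis, unmixing = _whitening_fallback((u, sv, vt), m, n)
    return AdaptiveDictionary(
        basis=basis, unmixing=unmixing, dimension_means=means,
        converged=False, seed=seed,
    )


def encode_patches(grid: PatchGrid, dictionary: AdaptiveDictionary) -> SparseCodeSet:
    """Project centered patch vectors onto the dictionary: s = W (p - mean)."""
    x = np.asarray(grid.patch_vectors, dtype=float)
    if x.shape[1] != dictionary.unmixing.shape[1]:
        raise ValueError(
            f"patch dimension {x.shape[1]} does not match dictionary "
            f"dimension {dictionary.unmixing.shape[1]}"
        )
    codes = (x - dictionary.dimension_means) @ dictionary.unmixing.T
    return SparseCodeSet(codes=codes, dictionary=dictionary, grid=grid)


def reconstruct_patches(codes: SparseCodeSet) -> np.ndarray:
    """Invert the encoding: p_hat = A s + mean.  Exact when m = d."""
    d = codes.dictionary
    return codes.codes @ d.basis.T + d.dimension_means


def sparse_saliency_map(
    img: np.ndarray,
    config: SparseBranchConfig | None = None,
    return_info: bool = False,
):
    """Saliency from the adaptive-sparse branch.

    The image is resized to the working resolution, densely cut into 5x5
    RGB patches, encoded under its own ICA dictionary, and each patch's
    sparse code is scored by center-surround dissimilarity.  Per-scale
    maps are combined by normalized product (a single scale by default)
    and the result is normalized to [0, 1].

    A degenerate (zero-variance) image yields an all-zero map and, with
    ``return_info=True``, ``info["degenerate"] = True``.
    """
    config = config or SparseBranchConfig()
    img = np.asarray(img, dtype=float)

    maps = []
    degenerate = False
    base_h, base_w = config.scale_resolutions()[0]
    for h, w in config.scale_resolutions():
        resized = resize_bilinear(img, h, w)
        grid = extract_patches(resized, config.patch_size, config.stride, "rgb")
        try:
            dictionary = learn_adaptive_dictionary(
                grid, n_components=min(config.n_components, grid.n_patches),
                seed=config.seed,
            )
        except DegenerateDictionaryError:
            warnings.warn("degenerate dictionary; sparse branch map is zero")
            degenerate = True
            maps.append(np.zeros((base_h, base_w)))
            continue
        codes = encode_patches(grid, dictionary)
        scores = csd_scores(codes.codes, grid.centers, (h, w))
        maps.append(resize_bilinear(assemble_patch_map(scores, grid, h, w),
                                    base_h, base_w))
    out = multiscale_combine(maps)
    if return_info:
        return out, {"degenerate": degenerate}
    return out
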