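"""Resizing, patch extraction and patch-to-map reassembly.

Conventions used throughout the package:

* arrays are indexed ``(row, col)``, 0-based;
* images are ``H x W x 3`` float arrays with intensities in ``[0, 1]``;
* saliency maps are ``H x W`` non-negative float arrays;
* patch vectorization is row-major within a patch, one channel at a time,
  channels concatenated ``R|G|B`` (``R|G|B|X|Y`` when coordinate planes are
  requested).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _sk_resize


@dataclass(frozen=True)
class PatchGrid:
    """A regular grid of vectorized square patches from one image.

    Attributes
    ----------
    patch_vectors : (n, d) float array
        One row per patch, grid raster order (row-major over grid cells).
    patch_size : int
        Side length ``k`` of each square patch, in pixels.
    stride : int
        Offset between neighbouring patch top-left corners, in pixels.
    grid_rows, grid_cols : int
        Lattice shape; ``n = grid_rows * grid_cols``.
    centers : (n, 2) float array
        Patch centers, ``(row, col)`` in source-image pixel coordinates.
        Fractional for even patch sizes; never rounded.
    source_height, source_width : int
        Shape of the image the patches were cut from.
    """

    patch_vectors: np.ndarray
    patch_size: int
    stride: int
    grid_rows: int
    grid_cols: int
    centers: np.ndarray
    source_height: int
    source_width: int

    @property
    def n_patches(self) -> int:
        return self.grid_rows * self.grid_cols


def _resize2d(arr: np.ndarray, out_height: int, out_width: int) -> np.ndarray:
    out = _sk_resize(
        arr,
        (out_height, out_width),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    # bilinear interpolation is a convex combination; clamp float fuzz
    return np.clip(out, arr.min(), arr.max())


def resize_bilinear(arr: np.ndarray, out_height: int, out_width: int) -> np.ndarray:
    """Bilinearly resample an image (H,W,3) or map (H,W) to a new shape.

    The output never leaves the input's value range.  Resizing to the
    current shape returns an exact copy.
    """
    if out_height < 1 or out_width < 1:
        raise ValueError(
            f"target size must be positive, got {out_height}x{out_width}"
        )
    arr = np.asarray(arr, dtype=float)
    if arr.shape[:2] == (out_height, out_width):
        return arr.copy()
    if arr.ndim == 2:
        return _resize2d(arr, out_height, out_width)
    if arr.ndim == 3:
        planes = [
            _resize2d(arr[..., c], out_height, out_width)
            for c in range(arr.shape[2])
        ]
        return np.stack(planes, axis=-1)
    raise ValueError(f"expected a 2-D map or 3-D image, got ndim={arr.ndim}")


def extract_patches(
    img: np.ndarray,
    patch_size: int,
    stride: int = 1,
    channels: str = "rgb",
) -> PatchGrid:
    """Cut an image into a dense grid of fully interior square patches.

    No padding is applied: ``grid_rows = floor((H - k) / stride) + 1`` and
    likewise for columns, so every patch lies entirely inside the image.

    Parameters
    ----------
    img : (H, W, 3) array
        Input image.
    patch_size : int
        Square side ``k``; must not exceed either image dimension.
    stride : int
        Step between patches, >= 1.  ``stride == patch_size`` tiles the
        image without overlap.
    channels : {"rgb", "rgbxy"}
        ``rgb`` vectorizes the three color planes (d = 3 k^2); ``rgbxy``
        appends normalized global coordinate planes (d = 5 k^2).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {img.shape}")
    h, w = img.shape[:2]
    if patch_size > min(h, w):
        raise ValueError(
            f"patch_size {patch_size} exceeds image dimensions {h}x{w}"
        )
    if patch_size < 1 or stride < 1:
        raise ValueError("patch_size and stride must be >= 1")
    if channels not in ("rgb", "rgbxy"):
        raise ValueError(f"unknown channel mode {channels!r}")

    planes = img
    if channels == "rgbxy":
        x = np.tile(np.arange(w, dtype=float) / max(w - 1, 1), (h, 1))
        y = np.tile((np.arange(h, dtype=float) / max(h - 1, 1))[:, None], (1, w))
        planes = np.concatenate([img, x[..., None], y[..., None]], axis=2)

    k = patch_size
    windows = sliding_window_view(planes, (k, k), axis=(0, 1))
    windows = windows[::stride, ::stride]  # (gr, gc, C, k, k)
    gr, gc = windows.shape[:2]
    # channel-major, row-major within each channel plane
    vectors = windows.reshape(gr * gc, -1)

    half = (k - 1) / 2.0
    rows = np.arange(gr) * stride + half
    cols = np.arange(gc) * stride + half
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    centers = np.column_stack([rr.ravel(), cc.ravel()])

    return PatchGrid(
        patch_vectors=np.ascontiguousarray(vectors, dtype=float),
        patch_size=k,
        stride=stride,
        grid_rows=gr,
        grid_cols=gc,
        centers=centers,
        source_height=h,
        source_width=w,
    )


def assemble_patch_map(
    values: np.ndarray,
    grid: PatchGrid,
    out_height: int,
    out_width: int,
) -> np.ndarray:
    """Arrange per-patch scores on the grid lattice and resize to a map.

    Scores are laid out on the ``grid_rows x grid_cols`` lattice in raster
    order (each score sitting at its patch center) and bilinearly
    interpolated up to the requested resolution.  Non-negative inputs give
    a non-negative map.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size != grid.n_patches:
        raise ValueError(
            f"got {values.size} scores for a grid of {grid.n_patches} patches"
        )
    lattice = values.reshape(grid.grid_rows, grid.grid_cols)
    return resize_bilinear(lattice, out_height, out_width)
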