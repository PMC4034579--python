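"""Seeded generators for pop-out search arrays and synthetic fixations.

The pattern generator renders the classic psychophysical singleton
displays (one target item among homogeneous distractors, differing in a
single attribute: color, orientation, a feature conjunction, curvature,
junction type, axial symmetry, or size) together with a binary mask of
the target's footprint, so end-to-end saliency claims can be tested
without any external dataset.  The fixation generator draws identically
center-biased fixation clouds for a set of images — exactly the shared
spatial bias the shuffled-AUC metric is designed to cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PATTERN_KINDS = (
    "color_singleton",
    "orientation_singleton",
    "conjunction",
    "curvature",
    "intersection",
    "symmetry",
    "size_singleton",
    "dense_texture",
)

_RED = np.array([0.9, 0.05, 0.05])
_GREEN = np.array([0.05, 0.7, 0.1])
_BG = 0.5  # mid-gray background


@dataclass(frozen=True)
class PatternSpec:
    """A pop-out search display: item grid, geometry jitter, and seed.

    ``jitter`` displaces each item center uniformly by up to that
    fraction of a grid cell per axis, breaking perfect regularity the way
    hand-built psychophysics arrays do.  All randomness (target cell,
    jitter, distractor attribute draws) flows from ``seed``.
    """

    kind: str = "color_singleton"
    grid: tuple[int, int] = (6, 6)
    image_size: int = 256
    jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValueError(
                f"unknown pattern kind {self.kind!r}; choose from {PATTERN_KINDS}"
            )
        rows, cols = self.grid
        cell = self.image_size / (max(rows, cols) + 1)
        if cell < 8:
            raise ValueError(
                f"grid {self.grid} does not fit image_size {self.image_size} "
                "with usable margins"
            )


def _paint_bar(canvas, mask, center, length, width, theta, color):
    """Rasterize a rotated rectangle; painted pixels are OR-ed into mask."""
    h, w = canvas.shape[:2]
    half = length / 2.0 + 1
    r0, r1 = int(max(center[0] - half, 0)), int(min(center[0] + half + 1, h))
    c0, c1 = int(max(center[1] - half, 0)), int(min(center[1] + half + 1, w))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - center[0]
    dx = cc - center[1]
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    inside = (np.abs(u) <= length / 2.0) & (np.abs(v) <= width / 2.0)
    canvas[r0:r1, c0:c1][inside] = color
    mask[r0:r1, c0:c1] |= inside


def _paint_arc(canvas, mask, center, radius, width, theta, color):
    """A half-circle arc of the same stroke width as a bar."""
    h, w = canvas.shape[:2]
    half = radius + width
    r0, r1 = int(max(center[0] - half, 0)), int(min(center[0] + half + 1, h))
    c0, c1 = int(max(center[1] - half, 0)), int(min(center[1] + half + 1, w))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - center[0]
    dx = cc - center[1]
    dist = np.hypot(dx, dy)
    ang = np.arctan2(dy, dx) - theta
    ang = (ang + np.pi) % (2 * np.pi) - np.pi
    inside = (np.abs(dist - radius) <= width / 2.0) & (np.abs(ang) <= np.pi / 2)
    canvas[r0:r1, c0:c1][inside] = color
    mask[r0:r1, c0:c1] |= inside


def _paint_item(canvas, mask, center, cell, kind, is_target, coin, quarter_turn):
    """Paint one search item.  Bars have 3:1 aspect, length 0.6 of a cell.

    ``coin`` and ``quarter_turn`` are pre-drawn random attributes so the
    RNG stream is identical whether or not the target is rendered as a
    target (needed for render-and-diff controls).
    """

    def bar(center_, theta, color, scale=1.0):
        length = 0.6 * cell * scale
        _paint_bar(canvas, mask, center_, length, length / 3.0, theta, color)

    vertical = np.pi / 2

    if kind == "color_singleton":
        bar(center, vertical, _RED if is_target else _GREEN)
    elif kind == "orientation_singleton":
        bar(center, np.pi / 4 if is_target else vertical, _GREEN)
    elif kind == "conjunction":
        if is_target:  # the unique pairing of the two distractor attributes
            bar(center, np.pi / 4, _RED)
        elif coin < 0.5:
            bar(center, vertical, _RED)
        else:
            bar(center, np.pi / 4, _GREEN)
    elif kind == "curvature":
        if is_target:
            _paint_arc(canvas, mask, center, 0.3 * cell, 0.2 * cell, 0.0, _GREEN)
        else:
            bar(center, vertical, _GREEN)
    elif kind == "intersection":
        bar(center, vertical, _GREEN)
        if is_target:  # a plus junction among plain bars
            bar(center, 0.0, _GREEN)
    elif kind == "symmetry":
        if is_target:  # mirror-symmetric T among asymmetric L's
            bar(center, vertical, _GREEN)
            bar((center[0] - 0.3 * cell, center[1]), 0.0, _GREEN, scale=0.66)
        else:
            rot = quarter_turn * np.pi / 2
            c, s = np.cos(rot), np.sin(rot)
            bar(center, vertical + rot, _GREEN)
            off = (0.3 * cell, 0.2 * cell)
            foot = (center[0] + off[0] * c - off[1] * s,
                    center[1] + off[0] * s + off[1] * c)
            bar(foot, rot, _GREEN, scale=0.4)
    elif kind == "size_singleton":
        bar(center, vertical, _GREEN, scale=1.6 if is_target else 1.0)
    elif kind == "dense_texture":
        reps = 4 if is_target else 2
        span = 0.6 * cell
        offs = (np.arange(reps) + 0.5) / reps * span - span / 2
        for dy in offs:
            for dx in offs:
                _paint_bar(canvas, mask, (center[0] + dy, center[1] + dx),
                           span / reps * 0.7, span / reps * 0.35,
                           np.pi / 2, _GREEN)
    else:
        raise ValueError(kind)


def generate_pattern(
    spec: PatternSpec, paint_target: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Render a pop-out display and its target mask, deterministically.

    With ``paint_target=False`` the target cell is rendered as one more
    distractor (a control display with an identical random stream, useful
    for render-and-diff checks); the mask still marks the target cell.

    Returns
    -------
    image : (S, S, 3) float array in [0, 1]
    mask : (S, S) uint8 array — the target item's bounding region (its
        pixel bounding box united with a cell-sized box at its center)
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid
    size = spec.image_size
    canvas = np.full((size, size, 3), _BG)
    target_pixels = np.zeros((size, size), dtype=bool)
    scratch = np.zeros((size, size), dtype=bool)

    cell_h = size / (rows + 1)
    cell_w = size / (cols + 1)
    cell = min(cell_h, cell_w)
    target_idx = int(rng.integers(rows * cols))
    target_center = None

    for idx in range(rows * cols):
        r, c = divmod(idx, cols)
        center = (
            cell_h * (r + 1) + rng.uniform(-spec.jitter, spec.jitter) * cell,
            cell_w * (c + 1) + rng.uniform(-spec.jitter, spec.jitter) * cell,
        )
        coin = rng.random()
        quarter_turn = int(rng.integers(4))
        is_target = idx == target_idx
        item_mask = target_pixels if is_target else scratch
        _paint_item(canvas, item_mask, center, cell, spec.kind,
                    is_target and paint_target, coin, quarter_turn)
        if is_target:
            target_center = center

    if not target_pixels.any():
        raise RuntimeError("target item rendered no pixels")
    ys, xs = np.nonzero(target_pixels)
    half = cell / 2.0
    r0 = int(max(min(ys.min(), np.floor(target_center[0] - half)), 0))
    r1 = int(min(max(ys.max(), np.ceil(target_center[0] + half)), size - 1))
    c0 = int(max(min(xs.min(), np.floor(target_center[1] - half)), 0))
    c1 = int(min(max(xs.max(), np.ceil(target_center[1] + half)), size - 1))
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[r0:r1 + 1, c0:c1 + 1] = 1
    return np.clip(canvas, 0.0, 1.0), mask


def generate_center_bias_fixations(
    n_images: int,
    n_fix_per_image: int,
    image_size: int,
    bias_sigma_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Identically center-biased fixation clouds for a set of images.

    Fixations are drawn from an isotropic Gaussian at the image center
    with sigma = ``bias_sigma_fraction`` x width, rejection-sampled into
    bounds.  Returns the standard fixation table (image_id, x, y).
    """
    if n_images < 1 or n_fix_per_image < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = bias_sigma_fraction * image_size
    center = (image_size - 1) / 2.0
    frames = []
    for i in range(n_images):
        pts = np.empty((0, 2))
        while pts.shape[0] < n_fix_per_image:
            draw = rng.normal(center, sigma, size=(n_fix_per_image * 2, 2))
            ok = draw[(draw >= 0).all(axis=1) & (draw <= image_size - 1).all(axis=1)]
            pts = np.vstack([pts, ok])
        pts = np.floor(pts[:n_fix_per_image]).astype(int)
        frames.append(
            pd.DataFrame(
                {"image_id": f"img{i:04d}", "x": pts[:, 0], "y": pts[:, 1]}
            )
        )
    return pd.concat(frames, ignore_index=True)


def gaussian_blob_map(
    height: int, width: int, sigma_fraction: float = 0.25
) -> np.ndarray:
    """A centered 2-D Gaussian blob map in [0, 1] — the center-bias baseline."""
    sigma = sigma_fraction * width
    y = np.arange(height) - (height - 1) / 2.0
    x = np.arange(width) - (width - 1) / 2.0
    yy, xx = np.meshgrid(y, x, indexing="ij")
    return np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))


def natural_image(
    height: int, width: int, seed: int = 0, n_disks: int = 120
) -> np.ndarray:
    """A synthetic RGB scene with natural-image statistics (dead leaves).

    Random occluding disks with power-law radii reproduce the hallmarks
    of natural scenes that matter here — scale invariance, sharp
    occlusion edges, and heavy-tailed (kurtotic) filter responses, the
    regime in which ICA patch bases become Gabor-like and codes sparse.
    It has none of the textures, lighting or semantics of photographs.
    """
    rng = np.random.default_rng(seed)
    img = np.empty((height, width, 3))
    img[:] = rng.random(3)
    yy, xx = np.mgrid[0:height, 0:width]
    rmin, rmax = 0.03 * min(height, width), 0.4 * min(height, width)
    exponent = 1.5  # power-law radius distribution, scale-invariant-ish
    for _ in range(n_disks):
        u = rng.random()
        r = rmin / (1.0 - u * (1.0 - (rmin / rmax) ** exponent)) ** (1 / exponent)
        cy, cx = rng.random() * height, rng.random() * width
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        img[disk] = rng.random(3)
    return img
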