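"""Image, saliency-map, fixation and mask I/O.

Fixation tables are CSV files with header ``image_id,x,y`` where ``x`` is
the column index and ``y`` the row index.  Internally everything is
0-based; datasets with 1-based annotations can be read with ``origin=1``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .exceptions import FixationParseError, ImageLoadError

FIXATION_COLUMNS = ("image_id", "x", "y")


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG file as an (H, W, 3) float array in [0, 1].

    Grayscale inputs are replicated across the three channels; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode not in ("RGB", "L"):
                im = im.convert("RGBA" if "A" in im.mode else "RGB")
            if im.mode == "RGBA":
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=float) / 255.0
    except (OSError, UnidentifiedImageError, ValueError) as exc:
        raise ImageLoadError(f"cannot load image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.repeat(arr[..., None], 3, axis=2)
    return arr


def load_mask(path: str | Path) -> np.ndarray:
    """Load a single-channel PNG as a binary (H, W) 0/1 array; nonzero = salient."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im.convert("L"))
    except (OSError, UnidentifiedImageError, ValueError) as exc:
        raise ImageLoadError(f"cannot load mask {path}: {exc}") from exc
    return (arr > 0).astype(np.uint8)


def save_saliency_png(salmap: np.ndarray, path: str | Path) -> None:
    """Write a saliency map as 8-bit grayscale PNG, min-max stretched."""
    salmap = np.asarray(salmap, dtype=float)
    lo, hi = salmap.min(), salmap.max()
    stretched = (salmap - lo) / (hi - lo) if hi > lo else np.zeros_like(salmap)
    Image.fromarray((stretched * 255).round().astype(np.uint8), mode="L").save(path)


def save_saliency_csv(salmap: np.ndarray, path: str | Path) -> None:
    """Write a saliency map as plain-text floats for bit-faithful inspection."""
    np.savetxt(path, np.asarray(salmap, dtype=float), delimiter=",", fmt="%.17g")


def load_saliency_csv(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def read_fixations(path: str | Path | _io.IOBase, origin: int = 0) -> pd.DataFrame:
    """Read a fixation CSV into a DataFrame with columns image_id, x, y.

    Parameters
    ----------
    origin : int
        Coordinate origin of the file; ``origin=1`` shifts 1-based
        annotations to the package's 0-based convention.
    """
    try:
        df = pd.read_csv(path, dtype={"image_id": str})
    except Exception as exc:
        raise FixationParseError(f"cannot parse fixation CSV {path}: {exc}") from exc
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise FixationParseError(
            f"fixation CSV {path} is missing columns {missing}; "
            f"expected header image_id,x,y"
        )
    df = df.loc[:, list(FIXATION_COLUMNS)]
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (coerced != coerced.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FixationParseError(
                f"non-integer value {df[col].iloc[row]!r} in column {col!r} "
                f"at data row {row + 1}"
            )
        df[col] = coerced.astype(int) - origin
    if len(df) and ((df["x"] < 0) | (df["y"] < 0)).any():
        raise FixationParseError("negative fixation coordinate after origin shift")
    return df.reset_index(drop=True)
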