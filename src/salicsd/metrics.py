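"""Fixation and salient-object evaluation metrics.

Shuffled AUC (sAUC) scores a saliency map by how well it ranks the
current image's fixations (positives) above fixations sampled from the
*other* images of the dataset (negatives).  Because positives and
negatives share whatever spatial bias the observers have, a map that
merely encodes center bias scores 0.5 — the chance anchor that makes
sAUC the fair fixation metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .csd import normalize_map, smooth_map
from .exceptions import UndefinedScoreError


def rank_auc(positives: np.ndarray, negatives: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney statistic; ties count one half.

    Equals the fraction of (positive, negative) pairs where the positive
    scores strictly higher, plus half the tied pairs — identical to the
    trapezoidal area under the ROC curve over all thresholds.
    """
    pos = np.asarray(positives, dtype=float).ravel()
    neg = np.asarray(negatives, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise UndefinedScoreError("AUC needs non-empty positives and negatives")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _as_xy(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return points[["x", "y"]].to_numpy(dtype=int)
    arr = np.asarray(points, dtype=int)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("fixations must be an (n, 2) array of (x, y)")
    return arr


def _values_at(salmap: np.ndarray, xy: np.ndarray) -> np.ndarray:
    h, w = salmap.shape
    x = np.clip(xy[:, 0], 0, w - 1)
    y = np.clip(xy[:, 1], 0, h - 1)
    return salmap[y, x]


def shuffled_auc(
    salmap: np.ndarray,
    fix_this_image,
    fix_other_images,
    n_reps: int = 20,
    seed: int = 0,
) -> tuple[float, float]:
    """Shuffled AUC of one map: mean and std over ``n_reps`` resamplings.

    Per repetition, as many negatives as there are positives are sampled
    from the other-image fixation pool (without replacement when the pool
    allows) and a rank AUC is computed on the map values at both point
    sets.  ``salmap`` must already be at the resolution the fixation
    coordinates refer to; lookups are nearest-pixel.
    """
    salmap = np.asarray(salmap, dtype=float)
    pos_xy = _as_xy(fix_this_image)
    pool_xy = _as_xy(fix_other_images)
    if pos_xy.shape[0] == 0 or pool_xy.shape[0] == 0:
        raise UndefinedScoreError("need fixations on the image and in the pool")

    pos_vals = _values_at(salmap, pos_xy)
    rng = np.random.default_rng(seed)
    n_neg = pos_xy.shape[0]
    aucs = np.empty(n_reps)
    for r in range(n_reps):
        replace = pool_xy.shape[0] < n_neg
        idx = rng.choice(pool_xy.shape[0], size=n_neg, replace=replace)
        aucs[r] = rank_auc(pos_vals, _values_at(salmap, pool_xy[idx]))
    return float(aucs.mean()), float(aucs.std())


@dataclass(frozen=True)
class DscCurve:
    """Dice similarity of a thresholded map against a mask, per threshold."""

    thresholds: np.ndarray
    dsc_values: np.ndarray

    @property
    def peak(self) -> float:
        """Peak Dice coefficient (PoDSC) over the threshold lattice."""
        return float(self.dsc_values.max())


def dsc_at_threshold(salmap: np.ndarray, mask: np.ndarray, threshold: float) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of the map binarized at >= t."""
    detected = np.asarray(salmap, dtype=float) >= threshold
    truth = np.asarray(mask).astype(bool)
    denom = detected.sum() + truth.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(detected, truth).sum() / denom)


def dsc_curve(
    salmap: np.ndarray,
    mask: np.ndarray,
    n_thresholds: int = 256,
    thresholds: Sequence[float] | None = None,
) -> DscCurve:
    """Dice coefficient sweep over uniform thresholds in [0, 1]."""
    salmap = np.asarray(salmap, dtype=float)
    mask = np.asarray(mask)
    if salmap.shape != mask.shape:
        raise ValueError(
            f"map shape {salmap.shape} does not match mask shape {mask.shape}"
        )
    if mask.sum() == 0:
        raise ValueError("ground-truth mask is empty")
    ts = (
        np.linspace(0.0, 1.0, n_thresholds)
        if thresholds is None
        else np.asarray(thresholds, dtype=float)
    )
    values = np.array([dsc_at_threshold(salmap, mask, t) for t in ts])
    return DscCurve(thresholds=ts, dsc_values=values)


def sigma_sweep(
    unsmoothed_map: np.ndarray,
    sigma_fractions: Sequence[float],
    evaluate: Callable[[np.ndarray], float],
) -> pd.DataFrame:
    """Re-smooth a map at each sigma (in image widths) and score it.

    ``evaluate`` receives the smoothed, normalized map and returns a
    scalar score (e.g. an sAUC or PoDSC closure).  The returned frame has
    columns ``sigma_fraction`` and ``score``; the argmax sigma is stored
    in ``frame.attrs["best_sigma_fraction"]``.
    """
    sigmas = list(sigma_fractions)
    if not sigmas:
        raise ValueError("need at least one sigma")
    base = np.asarray(unsmoothed_map, dtype=float)
    scores = [
        float(evaluate(normalize_map(smooth_map(base, s)))) for s in sigmas
    ]
    frame = pd.DataFrame({"sigma_fraction": sigmas, "score": scores})
    frame.attrs["best_sigma_fraction"] = float(
        frame.loc[frame["score"].idxmax(), "sigma_fraction"]
    )
    return frame
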