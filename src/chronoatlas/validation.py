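"""Quantitative validation: landmark transfer error, ICC, Dice overlap."""

from __future__ import annotations

import numpy as np

from .grids import LabelMap, LandmarkSet
from .transforms import CompositeTransform, TransformChain, apply_transform_point

__all__ = [
    "landmark_error",
    "transfer_landmarks",
    "icc_two_way_mixed",
    "dice_coefficient",
]


def landmark_error(truth: LandmarkSet, test: LandmarkSet) -> dict[str, object]:
    """Euclidean distance (mm) per landmark plus mean and SD.

    Both sets must contain exactly the same landmark names; a mismatch is
    rejected listing the difference.
    """
    names_t, names_s = set(truth.points), set(test.points)
    if names_t != names_s:
        missing = sorted(names_t ^ names_s)
        raise ValueError(f"landmark name mismatch: {missing}")
    per = {
        name: float(np.linalg.norm(truth[name] - test[name]))
        for name in sorted(names_t)
    }
    vals = np.array(list(per.values()))
    return {
        "per_landmark": per,
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    }


def transfer_landmarks(
    lm: LandmarkSet, T: CompositeTransform | TransformChain
) -> LandmarkSet:
    """Map every landmark through a transform (points in the transform's
    target space; out-of-domain points fall back to the affine part with a
    warning, as in point evaluation)."""
    return LandmarkSet(
        {name: apply_transform_point(T, p) for name, p in lm.points.items()}
    )


def icc_two_way_mixed(ratings: np.ndarray) -> float | None:
    """ICC(3,1): two-way mixed effects, single measures, consistency.

    ``ratings`` is an n-targets x k-raters matrix.  From the two-way ANOVA
    mean squares, ICC = (MS_targets - MS_error) / (MS_targets + (k-1)
    MS_error), clamped to [-1, 1].  Returns None when there is no variance
    to apportion.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 by k>=2 matrix")
    if not np.all(np.isfinite(r)):
        raise ValueError("ratings must be finite")
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((r - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0:
        return None
    return float(np.clip((ms_rows - ms_err) / denom, -1.0, 1.0))


def dice_coefficient(a: LabelMap, b: LabelMap, label: int) -> float | None:
    """Dice overlap 2|A∩B| / (|A|+|B|) of one label; None when both empty."""
    if not a.grid.same_geometry(b.grid):
        raise ValueError("label maps must share a grid")
    am = a.data == label
    bm = b.data == label
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return None
    return 2.0 * int(np.logical_and(am, bm).sum()) / denom
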