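"""EM tissue classification with spatial priors.

Each voxel's class posterior combines a Gaussian intensity likelihood with
a spatial prior probability map (e.g. CSF/GM/WM maps in register with the
image); the M-step re-estimates class means and variances from the
posteriors.  This is a deliberately lean model: no Markov-random-field
regularization and no bias-field estimation inside the loop (inhomogeneity
correction is assumed to have happened upstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import ImageVolume, LabelMap

__all__ = ["TissueModel", "em_tissue_segment", "average_tissue_maps"]


@dataclass
class TissueModel:
    """Per-class Gaussian parameters and spatial prior maps."""

    class_names: list[str]
    means: np.ndarray
    variances: np.ndarray
    priors: list[ImageVolume]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if np.any(self.variances <= 0):
            raise ValueError("variances must be > 0")


def em_tissue_segment(
    image: ImageVolume,
    priors: list[ImageVolume],
    mask: LabelMap | None = None,
    max_iter: int = 50,
    tol: float = 1e-5,
    class_names: list[str] | None = None,
):
    """EM segmentation of ``image`` into len(priors) classes.

    Returns ``(posteriors, hard_labels, model, log_likelihood_trace)``.
    Posteriors sum to 1 at every in-mask voxel; the hard map is the argmax
    with the smallest class index on ties, written as labels 1..K in-mask
    and 0 outside.  The log-likelihood is non-decreasing across iterations;
    the loop stops when its relative change falls below ``tol``.  A
    collapsing class variance is floored at 1e-6 x intensity range (flagged
    with a warning).
    """
    k = len(priors)
    if k < 2:
        raise ValueError("at least two classes required")
    grid = image.grid
    for p in priors:
        if not grid.same_geometry(p.grid):
            raise ValueError("priors must be aligned to the image grid")
    if mask is None:
        mask_arr = np.ones(grid.shape, dtype=bool)
    else:
        if not grid.same_geometry(mask.grid):
            raise ValueError("mask must share the image grid")
        mask_arr = mask.data > 0
    if not mask_arr.any():
        raise ValueError("empty mask")

    y = image.data[mask_arr].astype(float)
    pri = np.stack([p.data[mask_arr] for p in priors], axis=0)
    pri = np.clip(pri, 0.0, None)
    total = pri.sum(axis=0)
    pri = np.where(total > 1e-12, pri / np.maximum(total, 1e-12), 1.0 / k)

    rng_range = float(y.max() - y.min()) or 1.0
    var_floor = (1e-6 * rng_range) ** 2

    # init: prior-weighted intensity averages; flat priors give identical
    # class means, so fall back to intensity quantiles to break the symmetry
    w = pri / pri.sum(axis=1, keepdims=True)
    means = (w * y).sum(axis=1) / w.sum(axis=1)
    if means.max() - means.min() < 1e-6 * rng_range:
        means = np.quantile(y, (np.arange(k) + 0.5) / k)
    variances = np.maximum(
        (w * (y - means[:, None]) ** 2).sum(axis=1) / w.sum(axis=1), var_floor
    )

    ll_trace: list[float] = []
    post = None
    for _ in range(max_iter):
        # E-step
        log_like = (
            -0.5 * np.log(2 * np.pi * variances[:, None])
            - 0.5 * (y - means[:, None]) ** 2 / variances[:, None]
        )
        with np.errstate(divide="ignore"):
            log_num = log_like + np.log(np.maximum(pri, 1e-300))
        m = log_num.max(axis=0)
        num = np.exp(log_num - m)
        denom = num.sum(axis=0)
        post = num / denom
        ll = float(np.sum(np.log(denom) + m))
        ll_trace.append(ll)
        if len(ll_trace) > 1:
            rel = abs(ll_trace[-1] - ll_trace[-2]) / max(abs(ll_trace[-2]), 1e-12)
            if rel <= tol:
                break
        # M-step
        wsum = post.sum(axis=1)
        means = (post * y).sum(axis=1) / np.maximum(wsum, 1e-12)
        variances = (post * (y - means[:, None]) ** 2).sum(axis=1) / np.maximum(
            wsum, 1e-12
        )
        if np.any(variances < var_floor):
            warnings.warn("class variance floored to avoid collapse", stacklevel=2)
            variances = np.maximum(variances, var_floor)

    names = class_names or [f"class{i + 1}" for i in range(k)]
    post_maps = []
    for c in range(k):
        full = np.zeros(grid.shape)
        full[mask_arr] = post[c]
        post_maps.append(ImageVolume(full, grid.spacing, grid.origin))
    hard = np.zeros(grid.shape, dtype=np.int32)
    hard[mask_arr] = np.argmax(post, axis=0) + 1  # argmax takes first max: low index on ties
    hard_map = LabelMap(hard, grid.spacing, grid.origin)
    prior_maps = [
        ImageVolume(np.where(mask_arr, pr, 0.0), grid.spacing, grid.origin)
        for pr in [_expand(pri[c], mask_arr, grid) for c in range(k)]
    ]
    model = TissueModel(names, means, variances, prior_maps)
    return post_maps, hard_map, model, ll_trace


def _expand(vals: np.ndarray, mask_arr: np.ndarray, grid) -> np.ndarray:
    full = np.zeros(grid.shape)
    full[mask_arr] = vals
    return full


def average_tissue_maps(
    per_subject: list[list[ImageVolume]], mask: LabelMap | None = None
) -> list[ImageVolume]:
    """Cohort-average tissue probability maps, renormalized to sum to 1.

    ``per_subject[i]`` holds subject i's per-class posteriors in template
    space, all on one grid.
    """
    if not per_subject:
        raise ValueError("no subjects")
    k = len(per_subject[0])
    grid = per_subject[0][0].grid
    for maps in per_subject:
        if len(maps) != k:
            raise ValueError("inconsistent class count across subjects")
        for m in maps:
            if not grid.same_geometry(m.grid):
                raise ValueError("all maps must share the template grid")
    means = [np.mean([maps[c].data for maps in per_subject], axis=0) for c in range(k)]
    total = np.sum(means, axis=0)
    if mask is not None:
        in_mask = mask.data > 0
    else:
        in_mask = total > 1e-12
    safe = np.where(total > 1e-12, total, 1.0)
    return [
        ImageVolume(
            np.where(in_mask, m / safe, 0.0), grid.spacing, grid.origin
        )
        for m in means
    ]
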