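"""Image similarity metrics: normalized cross-correlation and Studholme NMI."""

from __future__ import annotations

import warnings

import numpy as np

from .grids import ImageVolume

__all__ = ["ncc_metric", "nmi_metric"]


def _as_arrays(a, b) -> tuple[np.ndarray, np.ndarray]:
    da = a.data if isinstance(a, ImageVolume) else np.asarray(a, dtype=float)
    db = b.data if isinstance(b, ImageVolume) else np.asarray(b, dtype=float)
    if da.shape != db.shape:
        raise ValueError(f"images must share a grid; shapes {da.shape} vs {db.shape}")
    return da.ravel(), db.ravel()


def ncc_metric(a, b) -> float:
    """Normalized cross-correlation (Pearson) in [-1, 1].

    Invariant to affine rescaling of either input's intensities.  A
    zero-variance input has no correlation structure; the metric is then
    defined as 0 and a warning is emitted.
    """
    da, db = _as_arrays(a, b)
    da = da - da.mean()
    db = db - db.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0.0:
        warnings.warn("zero-variance input to ncc_metric; returning 0", stacklevel=2)
        return 0.0
    return float(np.clip((da @ db) / denom, -1.0, 1.0))


def nmi_metric(a, b, bins: int = 32) -> float:
    """Studholme normalized mutual information (H(A)+H(B))/H(A,B), in [1, 2].

    Invariant under any bijective relabeling of one input's histogram bins,
    which makes it robust to contrast inversion.  A constant input carries no
    information; the independence limit 1 is returned with a warning.
    """
    da, db = _as_arrays(a, b)
    if da.max() == da.min() or db.max() == db.min():
        warnings.warn("constant input to nmi_metric; returning 1", stacklevel=2)
        return 1.0
    joint, _, _ = np.histogram2d(da, db, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def _entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_joint = _entropy(p.ravel())
    if h_joint == 0.0:
        warnings.warn("degenerate joint histogram in nmi_metric; returning 1", stacklevel=2)
        return 1.0
    return (_entropy(pa) + _entropy(pb)) / h_joint
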