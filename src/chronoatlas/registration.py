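"""Affine and symmetric diffeomorphic registration.

The deformable stage is a symmetric stationary-velocity-field (SVF) demons
scheme: one velocity field ``v`` is optimized; the forward map is ``exp(v)``
and the inverse ``exp(-v)`` (scaling and squaring), so forward and inverse
are mutual inverses by construction.  Demons updates are computed in both
directions and antisymmetrized.  A four-level multi-resolution pyramid runs
each level until the metric stops improving (relative tolerance) or an
iteration cap is reached.

With the NMI metric the demons force is evaluated on a polarity-corrected
copy of the moving image: a joint-histogram conditional-mean transfer maps
moving intensities into the fixed image's intensity range, which turns
cross-contrast alignment (including gray/white inversion) into an
intensity-difference problem while the reported metric trace remains NMI on
the original intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .grids import ImageVolume
from .metrics import ncc_metric, nmi_metric
from .resample import resample_intensity
from .transforms import AffineTransform, CompositeTransform, DisplacementField

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "affine_register",
    "diffeo_register",
]


@dataclass
class RegistrationConfig:
    """Settings shared by the affine and deformable stages.

    ``max_iters_per_level`` runs coarsest level first; the last entry is the
    full-resolution level.  Smoothing sigmas are in voxels: the update
    (fluid-like) smoothing regularizes each demons step, the field
    (diffusion-like) smoothing regularizes the accumulated velocity.
    ``step_size`` caps the per-iteration displacement update, in voxels.
    ``convergence_tol`` is the relative metric change (over a 5-iteration
    window) below which a level stops early.
    """

    levels: int = 4
    max_iters_per_level: Sequence[int] = (100, 100, 100, 20)
    metric: str = "ncc"
    histogram_bins: int = 32
    update_smoothing_sigma: float = 1.0
    field_smoothing_sigma: float = 2.0
    step_size: float = 0.25
    convergence_tol: float = 1e-5

    def __post_init__(self) -> None:
        self.max_iters_per_level = tuple(int(n) for n in self.max_iters_per_level)
        if self.levels != len(self.max_iters_per_level):
            raise ValueError("levels must equal len(max_iters_per_level)")
        if self.update_smoothing_sigma < 0 or self.field_smoothing_sigma < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.metric not in ("ncc", "nmi"):
            raise ValueError(f"metric must be 'ncc' or 'nmi', got {self.metric!r}")


@dataclass
class RegistrationResult:
    """Outcome of a pairwise registration.

    ``forward`` maps fixed-space coordinates to moving-space coordinates
    (pull-back: it resamples the moving image onto the fixed grid);
    ``inverse`` maps the other way.  ``warped_moving`` is the moving image
    resampled onto the fixed grid through ``forward``.
    """

    forward: CompositeTransform
    inverse: CompositeTransform
    metric_trace: list[float] = field(default_factory=list)
    converged: bool = False
    warped_moving: ImageVolume | None = None


# ---------------------------------------------------------------------------
# raw-array field helpers (voxel units, unit grid) — hot path of the demons
# ---------------------------------------------------------------------------


def _identity_coords(shape: tuple[int, ...]) -> np.ndarray:
    axes = [np.arange(n, dtype=float) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)


def _sample_channels(channels: np.ndarray, coords: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample each leading-axis channel of an array at fractional coords."""
    return np.stack(
        [
            ndimage.map_coordinates(c, coords, order=order, mode="nearest")
            for c in channels
        ],
        axis=0,
    )


def _compose_vox(outer: np.ndarray, inner: np.ndarray, ident: np.ndarray) -> np.ndarray:
    """(outer ∘ inner) as displacements, channel-first voxel fields."""
    return inner + _sample_channels(outer, ident + inner)


def _exp_vox(v: np.ndarray, ident: np.ndarray) -> np.ndarray:
    """Scaling-and-squaring exponential of a channel-first voxel SVF."""
    max_disp = float(np.max(np.abs(v))) if v.size else 0.0
    n = int(np.ceil(np.log2(max(max_disp / 0.25, 1.0))))
    phi = v / (2**n)
    for _ in range(n):
        phi = _compose_vox(phi, phi, ident)
    return phi


def _warp_image(img: np.ndarray, disp: np.ndarray, ident: np.ndarray, order: int = 1) -> np.ndarray:
    return ndimage.map_coordinates(img, ident + disp, order=order, mode="nearest")


def _min_jacobian(disp: np.ndarray) -> float:
    """Min Jacobian determinant of (identity + disp), channel-first field."""
    rank = disp.shape[0]
    grads = np.empty(disp.shape[1:] + (rank, rank))
    for i in range(rank):
        gi = np.gradient(disp[i], edge_order=1)
        for j in range(rank):
            grads[..., i, j] = gi[j]
    det = np.linalg.det(grads + np.eye(rank))
    interior = det[tuple(slice(1, -1) for _ in range(rank))]
    return float(interior.min()) if interior.size else float(det.min())


def _smooth_field(f: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return f
    return np.stack([ndimage.gaussian_filter(c, sigma, mode="nearest") for c in f], axis=0)


def _pyramid(img: np.ndarray, levels: int, min_size: int = 16) -> list[np.ndarray]:
    """Coarse-to-fine image pyramid (factor 2, Gaussian anti-aliasing)."""
    out = [img]
    for _ in range(levels - 1):
        cur = out[0]
        if min(cur.shape) < 2 * min_size:
            break
        sm = ndimage.gaussian_filter(cur, 0.85, mode="nearest")
        out.insert(0, sm[tuple(slice(None, None, 2) for _ in range(cur.ndim))])
    return out


def _transfer_lut(
    src: np.ndarray, dst: np.ndarray, bins: int = 128
) -> tuple[float, float, np.ndarray] | None:
    """Conditional-mean intensity transfer src -> dst as a binned LUT.

    Each src-intensity bin maps to the mean dst intensity observed at the
    same voxels.  This polarity-correcting transfer makes cross-contrast
    image pairs comparable by intensity difference; it is the demons-force
    counterpart of driving the alignment with mutual information.  The LUT's
    bin count is finer than the NMI metric's so that narrowly separated
    tissue classes are not merged by the remap.  Returns None for a
    constant src image.
    """
    s = src.ravel()
    d = dst.ravel()
    lo, hi = float(s.min()), float(s.max())
    if hi <= lo:
        return None
    which = np.clip(((s - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    sums = np.bincount(which, weights=d, minlength=bins)
    counts = np.bincount(which, minlength=bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    filled = counts > 0
    if not filled.all():
        idx = np.arange(bins)
        means = np.interp(idx, idx[filled], means[filled])
    means = ndimage.gaussian_filter1d(means, 0.5, mode="nearest")
    return lo, hi, means


def _apply_lut(img: np.ndarray, lut: tuple[float, float, np.ndarray] | None) -> np.ndarray:
    if lut is None:
        return img.copy()
    lo, hi, means = lut
    bins = len(means)
    which = np.clip(((img - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    return means[which]


def _histogram_match(moving: np.ndarray, fixed: np.ndarray, bins: int = 128) -> np.ndarray:
    """Remap ``moving`` into ``fixed``'s intensity range (see _transfer_lut)."""
    return _apply_lut(moving, _transfer_lut(moving, fixed, bins))


def _metric_value(metric: str, a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        if metric == "nmi":
            return nmi_metric(a, b, bins)
        return ncc_metric(a, b)


# ---------------------------------------------------------------------------
# affine registration
# ---------------------------------------------------------------------------


def _affine_from_params(params: np.ndarray, rank: int, center: np.ndarray) -> AffineTransform:
    """translation + rotation + log-scale parameters -> AffineTransform.

    2D: (tx, ty, theta, log_s)           — 4 parameters
    3D: (tx, ty, tz, a, b, c, log_s)     — 7 parameters (Euler angles)
    Rotation/scale act about ``center``.
    """
    if rank == 2:
        t = params[:2]
        theta = params[2]
        s = np.exp(params[3])
        ct, st = np.cos(theta), np.sin(theta)
        m = s * np.array([[ct, -st], [st, ct]])
    else:
        t = params[:3]
        ax, ay, az = params[3:6]
        s = np.exp(params[6])
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        m = s * (rz @ ry @ rx)
    translation = center + t - m @ center
    return AffineTransform(m, translation)


def affine_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    metric: str | None = None,
    config: RegistrationConfig | None = None,
) -> AffineTransform:
    """Recover a similarity transform (translation, rotation, isotropic scale)
    mapping fixed coordinates into moving coordinates.

    Derivative-free (Powell) optimization of the configured metric over a
    coarse-to-fine pyramid.  If no candidate improves on the identity the
    identity is returned.
    """
    config = config or RegistrationConfig()
    metric = metric or config.metric
    rank = fixed.rank
    n_par = 4 if rank == 2 else 7
    center = np.asarray(fixed.grid.index_to_world(
        (np.asarray(fixed.shape, dtype=float) - 1) / 2
    ))

    fix_pyr = _pyramid(fixed.data, config.levels)
    params = np.zeros(n_par)
    spacing = np.asarray(fixed.spacing)
    for li, fix in enumerate(fix_pyr):
        factor = 2 ** (len(fix_pyr) - 1 - li)
        lvl_spacing = spacing * factor
        lvl_grid_img = ImageVolume(fix, tuple(lvl_spacing), fixed.origin)
        pts = lvl_grid_img.grid.voxel_centers().reshape(-1, rank)

        def cost(p: np.ndarray) -> float:
            T = _affine_from_params(p, rank, center)
            idx = moving.grid.world_to_index(T.apply(pts))
            w = ndimage.map_coordinates(
                moving.data, idx.T, order=1, mode="constant", cval=0.0
            )
            return -_metric_value(metric, fix.ravel(), w, config.histogram_bins)

        step_t = float(np.max(lvl_spacing)) * 1.5
        steps = np.concatenate([
            np.full(rank, step_t),
            np.full(n_par - rank - 1, 0.05),
            [0.05],
        ])
        res = optimize.minimize(
            cost,
            params,
            method="Powell",
            options={
                "direc": np.diag(steps),
                "xtol": 1e-3,
                "ftol": 1e-6,
                "maxiter": 40,
            },
        )
        params = res.x

    best = _affine_from_params(params, rank, center)
    # guarantee the contract: never return something worse than identity
    full_pts = fixed.grid.voxel_centers().reshape(-1, rank)

    def full_metric(T: AffineTransform) -> float:
        idx = moving.grid.world_to_index(T.apply(full_pts))
        w = ndimage.map_coordinates(moving.data, idx.T, order=1, mode="constant", cval=0.0)
        return _metric_value(metric, fixed.data.ravel(), w, config.histogram_bins)

    if full_metric(best) < full_metric(AffineTransform.identity(rank)):
        return AffineTransform.identity(rank)
    return best


# ---------------------------------------------------------------------------
# symmetric diffeomorphic (SVF demons) registration
# ---------------------------------------------------------------------------


def _demons_force(target: np.ndarray, warped: np.ndarray) -> np.ndarray:
    """Symmetric-gradient demons update pushing ``warped`` toward ``target``."""
    diff = target - warped
    g_t = np.gradient(target)
    g_w = np.gradient(warped)
    grad = np.stack([(a + b) * 0.5 for a, b in zip(g_t, g_w)], axis=0)
    denom = np.sum(grad**2, axis=0) + diff**2
    with np.errstate(invalid="ignore", divide="ignore"):
        force = grad * (diff / denom)
    return np.where(denom > 1e-12, force, 0.0)


def _upsample_field(v: np.ndarray, target_shape: tuple[int, ...]) -> np.ndarray:
    zoom = [t / s for t, s in zip(target_shape, v.shape[1:])]
    out = np.stack(
        [ndimage.zoom(c, zoom, order=1, mode="nearest", grid_mode=True) for c in v],
        axis=0,
    )
    # displacement magnitudes are in voxels of the finer grid now
    for ax, z in enumerate(zoom):
        out[ax] *= z
    return out


def diffeo_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    config: RegistrationConfig | None = None,
    init: AffineTransform | None = None,
) -> RegistrationResult:
    """Symmetric diffeomorphic registration of ``moving`` onto ``fixed``.

    One stationary velocity field is optimized; forward = exp(v), inverse =
    exp(-v).  Per level the loop runs until the metric's relative change
    over a 5-iteration window drops below ``convergence_tol`` or the level's
    iteration cap is hit.  A negative Jacobian after an update rolls the
    update back at half step; persistent failure aborts with diagnostics.
    """
    config = config or RegistrationConfig()
    rank = fixed.rank
    A = init if init is not None else AffineTransform.identity(rank)

    # moving brought onto the fixed grid through the affine once; the SVF
    # then lives entirely on the fixed grid in voxel units
    if A.is_identity() and fixed.grid.same_geometry(moving.grid):
        M_full = moving.data.astype(float)
    else:
        M_full = resample_intensity(moving, CompositeTransform(A), fixed.grid, order=1).data
    F_full = fixed.data.astype(float)

    fix_pyr = _pyramid(F_full, config.levels)
    mov_pyr = _pyramid(M_full, config.levels)
    n_levels = len(fix_pyr)
    iters = config.max_iters_per_level[-n_levels:]

    v: np.ndarray | None = None
    metric_trace: list[float] = []
    converged = False

    for li in range(n_levels):
        F = fix_pyr[li]
        M = mov_pyr[li]
        ident = _identity_coords(F.shape)
        if v is None:
            v = np.zeros((rank,) + F.shape)
        elif v.shape[1:] != F.shape:
            v = _upsample_field(v, F.shape)

        if config.metric == "nmi":
            M_drive = _histogram_match(M, F)  # moving in fixed's intensity space
            F_drive = _histogram_match(F, M)  # fixed in moving's intensity space
        else:
            M_drive, F_drive = M, F

        step_scale = 1.0
        recent: list[float] = []
        level_converged = False
        prev_v = v
        for it in range(iters[li]):
            phi_f = _exp_vox(v, ident)
            jmin = _min_jacobian(phi_f)
            if jmin <= 0:
                # roll back and retry at half step
                v = prev_v
                step_scale *= 0.5
                if step_scale < 1 / 64:
                    raise RuntimeError(
                        f"diffeo_register: persistent folding (min Jacobian {jmin:.3g})"
                    )
                continue
            phi_b = _exp_vox(-v, ident)
            # forward: moving remapped into fixed intensities, warped to F;
            # backward: fixed remapped into moving intensities, warped to M
            m_w = _warp_image(M_drive, phi_f, ident)
            f_w = _warp_image(F_drive, phi_b, ident)

            if config.metric == "nmi":
                m_w_orig = _warp_image(M, phi_f, ident)
                val = _metric_value("nmi", F, m_w_orig, config.histogram_bins)
            else:
                val = _metric_value("ncc", F, m_w)
            metric_trace.append(val)
            recent.append(val)
            if len(recent) > 5:
                recent.pop(0)
                rel = abs(recent[-1] - recent[0]) / max(abs(recent[0]), 1e-12)
                if rel < config.convergence_tol:
                    level_converged = True
                    break

            u_fwd = _demons_force(F, m_w)
            u_bwd = _demons_force(M, f_w)
            u = 0.5 * (u_fwd - u_bwd)
            u = _smooth_field(u, config.update_smoothing_sigma)
            max_norm = float(np.max(np.sqrt(np.sum(u**2, axis=0))))
            cap = config.step_size * step_scale
            if max_norm > cap:
                u *= cap / max_norm
            prev_v = v
            v = _smooth_field(v + u, config.field_smoothing_sigma)
        if li == n_levels - 1:
            converged = level_converged

    assert v is not None
    ident = _identity_coords(F_full.shape)
    phi_f = _exp_vox(v, ident)
    phi_b = _exp_vox(-v, ident)

    spacing = np.asarray(fixed.spacing)

    def _vox_field_to_mm(phi: np.ndarray) -> np.ndarray:
        # channel-first voxel displacements -> channel-last mm displacements
        out = np.moveaxis(phi, 0, -1).copy()
        out *= spacing
        return out

    phi_f_mm = _vox_field_to_mm(phi_f)
    phi_b_mm = _vox_field_to_mm(phi_b)

    # forward: x -> A(x + phi_f(x)) = A x + t + A_mat @ phi_f(x)
    fwd_local = DisplacementField(
        phi_f_mm @ A.matrix.T, fixed.spacing, fixed.origin
    )
    forward = CompositeTransform(A, fwd_local)

    # inverse: y -> A^-1 y + phi_b(A^-1 y), with the backward field pulled
    # onto the moving grid
    A_inv = A.inverse()
    phi_b_field = DisplacementField(phi_b_mm, fixed.spacing, fixed.origin)
    mov_pts = moving.grid.voxel_centers().reshape(-1, rank)
    inv_vectors = phi_b_field.sample(A_inv.apply(mov_pts), out_of_domain="nearest")
    inv_local = DisplacementField(
        inv_vectors.reshape(moving.grid.shape + (rank,)), moving.spacing, moving.origin
    )
    inverse = CompositeTransform(A_inv, inv_local)

    warped = resample_intensity(moving, forward, fixed.grid, order=3)
    return RegistrationResult(
        forward=forward,
        inverse=inverse,
        metric_trace=metric_trace,
        converged=converged,
        warped_moving=warped,
    )
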