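"""Spatial transforms: affine + dense displacement, composition, inversion.

A transform here follows the pull-back convention: it maps *target*-space
coordinates into *source* space, so that source values can be sampled onto
the target grid.  A composite transform evaluates as

    T(x) = A x + t + D(x)

i.e. the affine part applied to the point plus the local displacement field
interpolated (linearly) at the *target* coordinate x.  Displacement fields
store mm-valued vectors on their own regular grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grids import Grid

__all__ = [
    "AffineTransform",
    "DisplacementField",
    "CompositeTransform",
    "TransformChain",
    "apply_transform_point",
    "concat_chain",
    "invert_displacement",
    "jacobian_determinant",
    "compose_displacements",
    "scaling_and_squaring",
    "DisplacementInversionError",
]


@dataclass
class AffineTransform:
    """Linear map plus translation, y = M x + t (mm)."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        rank = self.translation.shape[0]
        if self.matrix.shape != (rank, rank):
            raise ValueError("matrix and translation ranks disagree")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls, rank: int) -> "AffineTransform":
        return cls(np.eye(rank), np.zeros(rank))

    @property
    def rank(self) -> int:
        return self.translation.shape[0]

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def is_identity(self, atol: float = 1e-12) -> bool:
        return np.allclose(self.matrix, np.eye(self.rank), atol=atol) and np.allclose(
            self.translation, 0.0, atol=atol
        )


@dataclass
class DisplacementField:
    """Dense vector field (mm per component) on a reference grid.

    ``vectors`` has shape ``(*grid_shape, rank)``.
    """

    vectors: np.ndarray
    spacing: tuple[float, ...] = None  # type: ignore[assignment]
    origin: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        rank = self.vectors.ndim - 1
        if rank not in (2, 3) or self.vectors.shape[-1] != rank:
            raise ValueError(
                f"vectors must have shape (*grid, rank); got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field must be finite")
        if self.spacing is None:
            self.spacing = (1.0,) * rank
        elif np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * rank
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
        if self.origin is None:
            self.origin = (0.0,) * rank
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def rank(self) -> int:
        return self.vectors.ndim - 1

    @property
    def grid(self) -> Grid:
        return Grid(self.vectors.shape[:-1], self.spacing, self.origin)

    def sample(self, points: np.ndarray, out_of_domain: str = "zero") -> np.ndarray:
        """Linearly interpolate the field at physical points.

        ``out_of_domain``: "zero" returns a zero displacement outside the
        field's domain (with a warning), "nearest" clamps to the edge.
        """
        points = np.asarray(points, dtype=float)
        single = points.ndim == 1
        pts = np.atleast_2d(points)
        idx = self.grid.world_to_index(pts)
        mode = "nearest"
        out = np.empty_like(idx)
        coords = idx.T
        for c in range(self.rank):
            out[:, c] = ndimage.map_coordinates(
                self.vectors[..., c], coords, order=1, mode=mode
            )
        if out_of_domain == "zero":
            shape = np.asarray(self.grid.shape)
            outside = np.any((idx < 0) | (idx > shape - 1), axis=1)
            if np.any(outside):
                warnings.warn(
                    f"{int(outside.sum())} point(s) outside the displacement-field "
                    "domain; affine-only evaluation used there",
                    stacklevel=2,
                )
                out[outside] = 0.0
        return out[0] if single else out

    def max_norm(self) -> float:
        return float(np.max(np.linalg.norm(self.vectors, axis=-1)))

    @classmethod
    def zeros(cls, grid: Grid) -> "DisplacementField":
        return cls(np.zeros(grid.shape + (grid.rank,)), grid.spacing, grid.origin)


@dataclass
class CompositeTransform:
    """Affine plus optional local displacement: ``T(x) = A x + t + D(x)``.

    Maps target-space coordinates to source-space coordinates.  ``target``
    and ``source`` name the spaces for chain-compatibility checks.
    """

    global_: AffineTransform
    local: DisplacementField | None = None
    target: str = ""
    source: str = ""

    @classmethod
    def identity(cls, rank: int, target: str = "", source: str = "") -> "CompositeTransform":
        return cls(AffineTransform.identity(rank), None, target=target, source=source)

    @classmethod
    def from_displacement(
        cls, f: DisplacementField, target: str = "", source: str = ""
    ) -> "CompositeTransform":
        return cls(AffineTransform.identity(f.rank), f, target=target, source=source)

    @property
    def rank(self) -> int:
        return self.global_.rank

    def apply(self, points: np.ndarray) -> np.ndarray:
        out = self.global_.apply(points)
        if self.local is not None:
            out = out + self.local.sample(points)
        return out


@dataclass
class TransformChain:
    """Ordered concatenation of composite transforms.

    Evaluating the chain at x applies the first link first; link k maps the
    chain's running coordinate from link k's target space into its source
    space, so adjacent links must satisfy ``links[k].source ==
    links[k+1].target`` (when both names are non-empty).
    """

    links: list[CompositeTransform] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.links, self.links[1:]):
            if a.source and b.target and a.source != b.target:
                raise ValueError(
                    f"incompatible adjacent spaces: link source {a.source!r} "
                    f"!= next link target {b.target!r}"
                )

    @property
    def rank(self) -> int:
        return self.links[0].rank

    def apply(self, points: np.ndarray) -> np.ndarray:
        out = np.asarray(points, dtype=float)
        for link in self.links:
            out = link.apply(out)
        return out

    def __len__(self) -> int:
        return len(self.links)


def apply_transform_point(
    T: CompositeTransform | TransformChain, x: np.ndarray
) -> np.ndarray:
    """Map a physical point (mm) through a transform or chain (Eq.-style
    affine-plus-displacement evaluation; outside the local field's domain the
    affine part alone is used and a warning is emitted)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("point must be finite")
    return T.apply(x)


def concat_chain(links: Sequence[CompositeTransform]) -> TransformChain:
    """Concatenate pull-back transforms into a chain (first link first)."""
    return TransformChain(list(links))


def compose_displacements(
    outer: DisplacementField, inner: DisplacementField
) -> DisplacementField:
    """Displacement of applying ``inner`` then ``outer``:

    ``result(x) = inner(x) + outer(x + inner(x))``, on inner's grid.
    Out-of-domain samples of ``outer`` clamp to its edge (fields produced by
    registration decay to ~0 at the boundary).
    """
    grid = inner.grid
    pts = grid.voxel_centers().reshape(-1, grid.rank)
    warped = pts + inner.vectors.reshape(-1, grid.rank)
    outer_at = outer.sample(warped, out_of_domain="nearest")
    total = inner.vectors.reshape(-1, grid.rank) + outer_at
    return DisplacementField(total.reshape(inner.vectors.shape), grid.spacing, grid.origin)


def scaling_and_squaring(
    velocity: DisplacementField, min_steps: int = 0
) -> DisplacementField:
    """Exponentiate a stationary velocity field to a diffeomorphic displacement.

    The number of halvings is chosen so the scaled field moves at most ~0.25
    voxel per step, which keeps each small step trivially invertible; the
    exponential of ``-v`` is then the inverse of the exponential of ``v`` up
    to interpolation error.
    """
    sp = np.asarray(velocity.spacing)
    max_vox = float(np.max(np.abs(velocity.vectors) / sp)) if velocity.vectors.size else 0.0
    n = max(min_steps, int(np.ceil(np.log2(max(max_vox / 0.25, 1.0)))))
    phi = DisplacementField(
        velocity.vectors / (2**n), velocity.spacing, velocity.origin
    )
    for _ in range(n):
        phi = compose_displacements(phi, phi)
    return phi


class DisplacementInversionError(RuntimeError):
    """Fixed-point inversion failed to reach tolerance; carries the residual."""

    def __init__(self, residual: float, tol: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"displacement inversion did not reach tol={tol} mm in "
            f"{max_iter} iterations (achieved residual {residual:.3g} mm)"
        )


def _interior_slice(rank: int, margin: int = 1) -> tuple[slice, ...]:
    return tuple(slice(margin, -margin) for _ in range(rank))


def invert_displacement(
    f: DisplacementField, tol: float = 0.05, max_iter: int = 50
) -> DisplacementField:
    """Invert a displacement field by fixed-point iteration.

    Solves g(x) = -f(x + g(x)); for a field with positive Jacobian the
    iteration contracts.  Convergence is measured as the max norm of the
    composition residual ``f(x + g(x)) + g(x)`` over interior voxels (mm).
    """
    grid = f.grid
    pts = grid.voxel_centers().reshape(-1, grid.rank)
    g = np.zeros_like(f.vectors).reshape(-1, grid.rank)
    interior = np.zeros(grid.shape, dtype=bool)
    interior[_interior_slice(grid.rank)] = True
    interior = interior.reshape(-1)
    residual = np.inf
    for _ in range(max_iter):
        f_at = f.sample(pts + g, out_of_domain="nearest")
        residual = float(np.max(np.linalg.norm((f_at + g)[interior], axis=1)))
        if residual <= tol:
            return DisplacementField(
                g.reshape(f.vectors.shape), f.spacing, f.origin
            )
        g = -f_at
    # final check after the last update
    f_at = f.sample(pts + g, out_of_domain="nearest")
    residual = float(np.max(np.linalg.norm((f_at + g)[interior], axis=1)))
    if residual <= tol:
        return DisplacementField(g.reshape(f.vectors.shape), f.spacing, f.origin)
    raise DisplacementInversionError(residual, tol, max_iter)


def jacobian_determinant(f: DisplacementField):
    """Determinant of the Jacobian of (identity + f), per voxel.

    Central differences in physical units; boundary voxels use one-sided
    differences, interior voxels are the meaningful ones.  Returns an
    ImageVolume on the field's grid.
    """
    from .grids import ImageVolume  # local import to avoid cycle at module load

    rank = f.rank
    grads = np.empty(f.grid.shape + (rank, rank))
    for i in range(rank):
        gi = np.gradient(f.vectors[..., i], *f.spacing, edge_order=1)
        if rank == 2:
            grads[..., i, 0], grads[..., i, 1] = gi
        else:
            grads[..., i, 0], grads[..., i, 1], grads[..., i, 2] = gi
    jac = grads + np.eye(rank)
    det = np.linalg.det(jac)
    return ImageVolume(det, f.spacing, f.origin)
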