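"""Core image containers: scalar volumes, label maps, label schemes, landmarks.

All grids are axis-aligned and regular.  The physical coordinate of voxel
index ``i`` along an axis is ``origin + i * spacing`` (mm); voxel indices are
0-based.  The left-right anatomical axis is by convention the first array
axis.  Arrays may be rank 2 or rank 3 and every algorithm in the package is
written generically over the rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ImageVolume",
    "LabelMap",
    "LabelScheme",
    "SchemeEntry",
    "LandmarkSet",
    "Grid",
]


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular sampling lattice: shape, spacing (mm), origin (mm)."""

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...]

    def __post_init__(self) -> None:
        rank = len(self.shape)
        if rank not in (2, 3):
            raise ValueError(f"rank must be 2 or 3, got {rank}")
        if len(self.spacing) != rank or len(self.origin) != rank:
            raise ValueError("shape, spacing and origin must have equal rank")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"degenerate grid shape {self.shape}")

    @property
    def rank(self) -> int:
        return len(self.shape)

    @property
    def voxel_volume(self) -> float:
        """Physical volume (mm^rank) of one voxel."""
        return float(np.prod(self.spacing))

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) -> fractional voxel indices."""
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices, dtype=float)
        return indices * np.asarray(self.spacing) + np.asarray(self.origin)

    def voxel_centers(self) -> np.ndarray:
        """Physical coordinates of every voxel centre, shape ``(*shape, rank)``."""
        axes = [
            np.arange(n) * sp + og
            for n, sp, og in zip(self.shape, self.spacing, self.origin)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    def same_geometry(self, other: "Grid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def _as_grid_params(rank: int, spacing, origin) -> tuple[tuple[float, ...], tuple[float, ...]]:
    if spacing is None:
        spacing = (1.0,) * rank
    if origin is None:
        origin = (0.0,) * rank
    if np.isscalar(spacing):
        spacing = (float(spacing),) * rank
    return tuple(float(s) for s in spacing), tuple(float(o) for o in origin)


class _GriddedArray:
    """Shared behaviour of ImageVolume and LabelMap."""

    data: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...]

    @property
    def rank(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.spacing, self.origin)


@dataclass
class ImageVolume(_GriddedArray):
    """A scalar intensity volume on a regular 2D/3D grid.

    Parameters
    ----------
    data : ndarray
        Dense rank-2 or rank-3 array of finite real scalars.
    spacing : sequence of float, optional
        Per-axis voxel size in mm (default 1 mm isotropic).
    origin : sequence of float, optional
        Physical coordinate of voxel ``(0, ..., 0)`` in mm (default zeros).
    """

    data: np.ndarray
    spacing: tuple[float, ...] = None  # type: ignore[assignment]
    origin: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"ImageVolume rank must be 2 or 3, got {self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageVolume data must be finite")
        self.spacing, self.origin = _as_grid_params(self.data.ndim, self.spacing, self.origin)
        self.grid  # validates

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same grid, new voxel values."""
        return ImageVolume(np.asarray(data, dtype=float), self.spacing, self.origin)


@dataclass
class LabelMap(_GriddedArray):
    """An integer parcellation on a regular grid; label 0 is background."""

    data: np.ndarray
    spacing: tuple[float, ...] = None  # type: ignore[assignment]
    origin: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(data == np.round(data)):
                raise ValueError("LabelMap data must be integer-valued")
            data = data.astype(np.int32)
        if data.ndim not in (2, 3):
            raise ValueError(f"LabelMap rank must be 2 or 3, got {data.ndim}")
        if data.min(initial=0) < 0:
            raise ValueError("LabelMap values must be non-negative")
        self.data = data
        self.spacing, self.origin = _as_grid_params(data.ndim, self.spacing, self.origin)
        self.grid

    def labels(self, include_background: bool = False) -> np.ndarray:
        ids = np.unique(self.data)
        if not include_background:
            ids = ids[ids != 0]
        return ids

    def with_data(self, data: np.ndarray) -> "LabelMap":
        return LabelMap(data, self.spacing, self.origin)


@dataclass(frozen=True)
class SchemeEntry:
    """One row of a label scheme: name, hemisphere, partner and lobar group."""

    name: str
    hemisphere: str  # "left" | "right" | "none"
    partner_id: int | None = None
    lobe: str | None = None


class LabelScheme:
    """Label ID -> (name, hemisphere, left/right partner, lobar group).

    Pairing is an explicit table rather than parity arithmetic because real
    parcellation schemes break even/odd conventions (e.g. an unpaired midline
    corpus callosum sitting between paired ventricle IDs).  The partner
    relation must be a symmetric involution and partners must lie in opposite
    hemispheres; both are enforced at construction.
    """

    def __init__(self, entries: Mapping[int, SchemeEntry]):
        self.entries: dict[int, SchemeEntry] = dict(entries)
        for lid, e in self.entries.items():
            if e.hemisphere not in ("left", "right", "none"):
                raise ValueError(f"label {lid}: bad hemisphere {e.hemisphere!r}")
            if e.partner_id is not None:
                p = self.entries.get(e.partner_id)
                if p is None:
                    raise ValueError(f"label {lid}: partner {e.partner_id} not in scheme")
                if p.partner_id != lid:
                    raise ValueError(
                        f"partner relation is not an involution: {lid} -> "
                        f"{e.partner_id} -> {p.partner_id}"
                    )
                if {e.hemisphere, p.hemisphere} != {"left", "right"}:
                    raise ValueError(
                        f"partners {lid}/{e.partner_id} must lie in opposite hemispheres"
                    )

    def __contains__(self, label_id: int) -> bool:
        return int(label_id) in self.entries

    def __getitem__(self, label_id: int) -> SchemeEntry:
        return self.entries[int(label_id)]

    def __iter__(self) -> Iterator[int]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def partner(self, label_id: int) -> int | None:
        return self.entries[int(label_id)].partner_id

    def pairs(self) -> list[tuple[int, int]]:
        """All (left_id, right_id) partner pairs, each reported once."""
        out = []
        for lid, e in sorted(self.entries.items()):
            if e.partner_id is not None and e.hemisphere == "left":
                out.append((lid, e.partner_id))
        return out

    def lobes(self) -> dict[str, list[int]]:
        """Lobar group name -> member label IDs."""
        out: dict[str, list[int]] = {}
        for lid, e in sorted(self.entries.items()):
            if e.lobe is not None:
                out.setdefault(e.lobe, []).append(lid)
        return out


@dataclass
class LandmarkSet:
    """Named physical points (mm).  Names are unique by construction (dict)."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            clean[str(name)] = p
        self.points = clean

    def names(self) -> list[str]:
        return sorted(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]
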