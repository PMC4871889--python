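"""Label fusion, left-right flipping, laterality and ROI volumetry.

The asymmetry coefficient of a paired region,

    S = 2 |V_L - V_R| / (V_L + V_R),

is a dimensionless normalized left-right volume difference in [0, 2]; 0
means perfect volumetric symmetry, 2 means one side is absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import LabelMap, LabelScheme

__all__ = [
    "majority_vote",
    "flip_labels_lr",
    "asymmetry_coefficient",
    "region_volumes",
    "icv_proportions",
    "asymmetry_report",
    "AsymmetryReport",
    "VolumeTable",
    "cohort_volume_table",
]

MM3_PER_CM3 = 1000.0


@dataclass
class VolumeTable:
    """Per-label volumes in cm^3 (background excluded unless asked for)."""

    volumes: dict[int, float]
    voxel_volume_mm3: float
    total_volume_cm3: float

    def __getitem__(self, label: int) -> float:
        return self.volumes[label]


@dataclass
class AsymmetryReport:
    """Per-paired-region laterality: rows of (base name, V_L, V_R, S)."""

    rows: list[dict[str, object]]

    def max_s(self) -> float:
        vals = [r["S"] for r in self.rows if r["S"] is not None]
        return max(vals) if vals else float("nan")

    def min_s(self) -> float:
        vals = [r["S"] for r in self.rows if r["S"] is not None]
        return min(vals) if vals else float("nan")


def majority_vote(maps: list[LabelMap]) -> LabelMap:
    """Per-voxel most frequent label; ties go to the smallest label ID."""
    if not maps:
        raise ValueError("at least one label map required")
    grid = maps[0].grid
    for m in maps[1:]:
        if not grid.same_geometry(m.grid):
            raise ValueError("all label maps must share one grid")
    stack = np.stack([m.data for m in maps], axis=0)
    ids = np.unique(stack)
    # counting in ascending-ID order + strict '>' keeps the first (smallest)
    # ID on ties
    best_count = np.zeros(grid.shape, dtype=np.int32)
    winner = np.full(grid.shape, ids[0], dtype=stack.dtype)
    for lid in ids:
        count = np.sum(stack == lid, axis=0, dtype=np.int32)
        take = count > best_count
        winner[take] = lid
        best_count[take] = count[take]
    return LabelMap(winner, maps[0].spacing, maps[0].origin)


def flip_labels_lr(labels: LabelMap, scheme: LabelScheme) -> LabelMap:
    """Mirror along the left-right (first) axis and swap partner IDs.

    Unpaired IDs (midline / tissue classes) survive unchanged.  Applying the
    operation twice restores the input exactly.  A hemispheric ID without a
    partner is an error naming the ID.
    """
    present = np.unique(labels.data)
    lut_size = int(present.max()) + 1 if present.size else 1
    lut = np.arange(lut_size, dtype=labels.data.dtype)
    for lid in present:
        lid = int(lid)
        if lid == 0:
            continue
        if lid not in scheme:
            raise ValueError(f"label ID {lid} missing from the scheme")
        entry = scheme[lid]
        if entry.hemisphere in ("left", "right"):
            if entry.partner_id is None:
                raise ValueError(
                    f"hemispheric label ID {lid} ({entry.name}) has no partner"
                )
            lut[lid] = entry.partner_id
    mirrored = np.flip(labels.data, axis=0)
    return LabelMap(lut[mirrored], labels.spacing, labels.origin)


def asymmetry_coefficient(v_left: float, v_right: float) -> float | None:
    """S = 2 |V_L - V_R| / (V_L + V_R); None (missing) when both are zero."""
    if v_left < 0 or v_right < 0:
        raise ValueError("volumes must be non-negative")
    total = v_left + v_right
    if total == 0:
        return None
    return 2.0 * abs(v_left - v_right) / total


def region_volumes(labels: LabelMap, include_background: bool = False) -> VolumeTable:
    """Per-label volume = voxel count x voxel physical volume, in cm^3."""
    vox = labels.grid.voxel_volume
    ids, counts = np.unique(labels.data, return_counts=True)
    volumes = {
        int(i): float(c) * vox / MM3_PER_CM3
        for i, c in zip(ids, counts)
        if include_background or i != 0
    }
    total = labels.data.size * vox / MM3_PER_CM3
    return VolumeTable(volumes=volumes, voxel_volume_mm3=vox, total_volume_cm3=total)


def icv_proportions(
    labels: LabelMap, mask: LabelMap, scheme: LabelScheme
) -> dict[str, float]:
    """Per-lobar-group volume as a percentage of the (brain-mask) volume.

    The label map is restricted to the mask first; each group's in-mask
    volume is divided by the mask volume.  Unlabeled in-mask voxels are
    allowed, so the percentages sum to at most 100.
    """
    if not labels.grid.same_geometry(mask.grid):
        raise ValueError("labels and mask must share a grid")
    mask_arr = mask.data > 0
    n_mask = int(mask_arr.sum())
    if n_mask == 0:
        raise ValueError("empty mask")
    masked = np.where(mask_arr, labels.data, 0)
    out: dict[str, float] = {}
    for lobe, members in scheme.lobes().items():
        n = int(np.isin(masked, members).sum())
        out[lobe] = 100.0 * n / n_mask
    return out


def asymmetry_report(labels: LabelMap, scheme: LabelScheme) -> AsymmetryReport:
    """S for every left/right partner pair in the scheme, from ROI volumes."""
    table = region_volumes(labels)
    rows = []
    for left_id, right_id in scheme.pairs():
        v_l = table.volumes.get(left_id, 0.0)
        v_r = table.volumes.get(right_id, 0.0)
        base = scheme[left_id].name
        for suffix in (" left", "_left", " l", "-left"):
            if base.lower().endswith(suffix):
                base = base[: -len(suffix)]
                break
        rows.append(
            {
                "region": base,
                "left_id": left_id,
                "right_id": right_id,
                "V_L": v_l,
                "V_R": v_r,
                "S": asymmetry_coefficient(v_l, v_r),
            }
        )
    return AsymmetryReport(rows=rows)


def cohort_volume_table(tables: list[VolumeTable]) -> dict[int, tuple[float, float]]:
    """Cohort mean and SD of per-label volumes (cm^3) across subjects."""
    ids = sorted({i for t in tables for i in t.volumes})
    out = {}
    for i in ids:
        vals = np.array([t.volumes.get(i, 0.0) for t in tables])
        out[i] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return out
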