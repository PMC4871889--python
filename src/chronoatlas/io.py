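"""File I/O: NIfTI volumes, label schemes, landmark CSVs, reports, configs.

NIfTI grids are assumed axis-aligned (RAS-like, left-right along the first
axis): the affine must be diagonal up to a small tolerance; spacing comes
from the header zooms and the origin from the affine translation.  All
round-trips preserve data, spacing and origin to float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .fusion import AsymmetryReport, VolumeTable
from .grids import ImageVolume, LabelMap, LabelScheme, LandmarkSet, SchemeEntry
from .transforms import AffineTransform, CompositeTransform, DisplacementField

__all__ = [
    "read_image",
    "write_image",
    "read_labels",
    "write_labels",
    "read_scheme",
    "write_scheme",
    "read_landmarks",
    "write_landmarks",
    "write_volume_report",
    "read_volume_report",
    "write_asymmetry_report",
    "write_transform",
    "read_transform",
    "load_config",
    "save_config",
]

_AXIS_NAMES = ("x", "y", "z")


def _affine_from_grid(spacing, origin, rank: int) -> np.ndarray:
    aff = np.eye(4)
    for i in range(rank):
        aff[i, i] = spacing[i]
        aff[i, 3] = origin[i]
    return aff


def _grid_from_nifti(img) -> tuple[np.ndarray, tuple, tuple]:
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    rank = data.ndim
    if rank not in (2, 3):
        raise ValueError(f"expected a 2D/3D volume, got rank {rank}")
    aff = img.affine
    lin = aff[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.max(np.abs(off_diag)) > 1e-4 * max(1.0, np.max(np.abs(lin))):
        raise ValueError(
            "oblique orientation not supported: affine has off-diagonal terms "
            f"{off_diag.round(6).tolist()}"
        )
    spacing = tuple(float(abs(aff[i, i])) for i in range(rank))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing in header: {spacing}")
    origin = tuple(float(aff[i, 3]) for i in range(rank))
    return data, spacing, origin


def read_image(path) -> ImageVolume:
    data, spacing, origin = _grid_from_nifti(nib.load(str(path)))
    return ImageVolume(data.astype(float), spacing, origin)


def write_image(img: ImageVolume, path) -> None:
    aff = _affine_from_grid(img.spacing, img.origin, img.rank)
    nib.save(nib.Nifti1Image(img.data.astype(np.float32), aff), str(path))


def read_labels(path) -> LabelMap:
    data, spacing, origin = _grid_from_nifti(nib.load(str(path)))
    return LabelMap(np.rint(data).astype(np.int32), spacing, origin)


def write_labels(labels: LabelMap, path) -> None:
    aff = _affine_from_grid(labels.spacing, labels.origin, labels.rank)
    nib.save(nib.Nifti1Image(labels.data.astype(np.int32), aff), str(path))


def read_scheme(path) -> LabelScheme:
    """Label scheme from TSV (id, name, hemisphere, partner_id, lobe) or JSON."""
    path = Path(path)
    entries: dict[int, SchemeEntry] = {}
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        for key, e in raw.items():
            entries[int(key)] = SchemeEntry(
                e["name"],
                e.get("hemisphere", "none"),
                e.get("partner_id"),
                e.get("lobe"),
            )
    else:
        df = pd.read_csv(path, sep="\t", dtype={"partner_id": "Int64"})
        required = {"id", "name", "hemisphere"}
        if not required.issubset(df.columns):
            raise ValueError(f"scheme file missing columns {sorted(required - set(df.columns))}")
        for _, row in df.iterrows():
            partner = row.get("partner_id")
            lobe = row.get("lobe")
            entries[int(row["id"])] = SchemeEntry(
                str(row["name"]),
                str(row["hemisphere"]),
                None if pd.isna(partner) else int(partner),
                None if (lobe is None or (isinstance(lobe, float) and np.isnan(lobe))) else str(lobe),
            )
    return LabelScheme(entries)


def write_scheme(scheme: LabelScheme, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = {
            str(lid): {
                "name": e.name,
                "hemisphere": e.hemisphere,
                "partner_id": e.partner_id,
                "lobe": e.lobe,
            }
            for lid, e in sorted(scheme.entries.items())
        }
        path.write_text(json.dumps(raw, indent=1))
    else:
        rows = [
            {
                "id": lid,
                "name": e.name,
                "hemisphere": e.hemisphere,
                "partner_id": e.partner_id,
                "lobe": e.lobe,
            }
            for lid, e in sorted(scheme.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path)
    if "name" not in df.columns:
        raise ValueError("landmark CSV needs a 'name' column")
    axes = [a for a in _AXIS_NAMES if a in df.columns]
    if not axes:
        raise ValueError("landmark CSV needs coordinate columns x,y[,z]")
    return LandmarkSet(
        {str(r["name"]): np.array([float(r[a]) for a in axes]) for _, r in df.iterrows()}
    )


def write_landmarks(lm: LandmarkSet, path) -> None:
    rows = []
    for name in lm.names():
        p = lm[name]
        rows.append({"name": name, **{_AXIS_NAMES[i]: p[i] for i in range(len(p))}})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_volume_report(
    table: VolumeTable,
    path,
    scheme: LabelScheme | None = None,
    cohort: dict[int, tuple[float, float]] | None = None,
) -> None:
    """CSV: label,name,volume_cm3 (+ mean,sd columns in cohort mode)."""
    rows = []
    for lid, vol in sorted(table.volumes.items()):
        row = {
            "label": lid,
            "name": scheme[lid].name if scheme and lid in scheme else "",
            "volume_cm3": vol,
        }
        if cohort and lid in cohort:
            row["mean_cm3"], row["sd_cm3"] = cohort[lid]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_volume_report(path) -> VolumeTable:
    df = pd.read_csv(path)
    volumes = {int(r["label"]): float(r["volume_cm3"]) for _, r in df.iterrows()}
    return VolumeTable(volumes=volumes, voxel_volume_mm3=float("nan"), total_volume_cm3=float("nan"))


def write_asymmetry_report(report: AsymmetryReport, path) -> None:
    """CSV: region,V_L,V_R,S."""
    pd.DataFrame(
        [
            {"region": r["region"], "V_L": r["V_L"], "V_R": r["V_R"], "S": r["S"]}
            for r in report.rows
        ]
    ).to_csv(path, index=False)


def write_transform(T: CompositeTransform, prefix) -> None:
    """Affine as a 4x4 text matrix; displacement as a vector NIfTI."""
    prefix = str(prefix)
    aff = _affine_from_grid([1] * 3, [0] * 3, 3)
    full = np.eye(4)
    r = T.rank
    full[:r, :r] = T.global_.matrix
    full[:r, 3] = T.global_.translation
    np.savetxt(prefix + "_affine.txt", full)
    if T.local is not None:
        vec_aff = _affine_from_grid(T.local.spacing, T.local.origin, T.local.rank)
        nib.save(
            nib.Nifti1Image(T.local.vectors.astype(np.float32), vec_aff),
            prefix + "_field.nii.gz",
        )


def read_transform(prefix, rank: int) -> CompositeTransform:
    prefix = str(prefix)
    full = np.loadtxt(prefix + "_affine.txt")
    glob = AffineTransform(full[:rank, :rank], full[:rank, 3])
    local = None
    field_path = Path(prefix + "_field.nii.gz")
    if field_path.exists():
        img = nib.load(str(field_path))
        vectors = np.asanyarray(img.dataobj).astype(float)
        aff = img.affine
        spacing = tuple(float(abs(aff[i, i])) for i in range(rank))
        origin = tuple(float(aff[i, 3]) for i in range(rank))
        local = DisplacementField(vectors, spacing, origin)
    return CompositeTransform(glob, local)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=1, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
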