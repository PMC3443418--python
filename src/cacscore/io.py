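"""Readers and writers for volumes, trajectories, phantom specs and scores.

NIfTI-1 volumes go through nibabel, NRRD through SimpleITK; both are
normalised to the package's ``(x, y, z)`` axis order with z the slice axis.
Trajectories are JSON (``[{"name", "points", "radius"}, ...]``) or 4-column
TSV (``name  x  y  z``, optional 5th ``radius`` column).  Phantoms are JSON
(cylinder geometry or explicit voxel lists) or an integer label-mask volume
with a sidecar label->density map.  Scores are plain CSV.
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ArteryTrajectory,
    CTVolume,
    Cylinder,
    FormatError,
    PhantomInsert,
    PhantomSpec,
    ScoreResult,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_trajectories",
    "write_trajectories",
    "read_phantom",
    "write_phantom",
    "phantom_from_label_mask",
    "read_scores",
    "write_scores",
]

_NIFTI_EXTS = (".nii", ".nii.gz")
_NRRD_EXTS = (".nrrd", ".nhdr")


def _is_nifti(path: str) -> bool:
    return path.endswith(_NIFTI_EXTS)


def read_volume(path: str, scan_id: str = "", participant_id: str = "") -> CTVolume:
    """Read a NIfTI-1 or NRRD scalar volume into a :class:`CTVolume`.

    Spacing is taken from the file metadata; the voxel array is returned in
    ``(x, y, z)`` order.  Non-3D data or non-positive spacing raise
    :class:`FormatError`.
    """
    if not os.path.exists(path):
        raise FormatError(f"volume file not found: {path}")
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected 3D data, got {data.ndim}D")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    elif path.endswith(_NRRD_EXTS):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        if img.GetDimension() != 3:
            raise FormatError(f"{path}: expected 3D data, got {img.GetDimension()}D")
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
    else:
        raise FormatError(f"unsupported volume format: {path}")
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: non-positive spacing {spacing}")
    return CTVolume(
        voxels=np.asarray(data, dtype=float),
        spacing=spacing,
        origin=origin,
        scan_id=scan_id,
        participant_id=participant_id,
    )


def write_volume(volume: CTVolume, path: str) -> None:
    """Write a :class:`CTVolume` to NIfTI-1 (.nii/.nii.gz) or NRRD."""
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.voxels.astype(np.float64), affine), path)
    elif path.endswith(_NRRD_EXTS):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(volume.voxels.transpose(2, 1, 0))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, path)
    else:
        raise FormatError(f"unsupported volume format: {path}")


def read_trajectories(path: str) -> list[ArteryTrajectory]:
    """Read artery trajectories from JSON or TSV.

    A trajectory with no explicit radius gets the conventional 8 mm search
    radius.  Fewer than two points per artery is a format error.
    """
    if not os.path.exists(path):
        raise FormatError(f"trajectory file not found: {path}")
    if path.endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
        if not isinstance(raw, list):
            raise FormatError(f"{path}: expected a JSON list of trajectories")
        return [
            ArteryTrajectory(
                name=str(entry.get("name", f"artery{i}")),
                points=np.asarray(entry["points"], dtype=float),
                search_radius=float(entry.get("radius", 8.0)),
            )
            for i, entry in enumerate(raw)
        ]
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: TSV needs columns {sorted(required)}")
    for col in ("x", "y", "z"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: non-numeric coordinates in column {col}")
    out = []
    for name, grp in df.groupby("name", sort=False):
        radius = 8.0
        if "radius" in grp.columns and np.isfinite(grp["radius"].iloc[0]):
            radius = float(grp["radius"].iloc[0])
        out.append(
            ArteryTrajectory(
                name=str(name),
                points=grp[["x", "y", "z"]].to_numpy(dtype=float),
                search_radius=radius,
            )
        )
    return out


def write_trajectories(trajectories: Sequence[ArteryTrajectory], path: str) -> None:
    """Write trajectories to JSON or TSV (formats mirror read_trajectories)."""
    if path.endswith(".json"):
        payload = [
            {
                "name": t.name,
                "points": t.points.tolist(),
                "radius": t.search_radius,
            }
            for t in trajectories
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    rows = []
    for t in trajectories:
        for p in t.points:
            rows.append(
                {"name": t.name, "x": p[0], "y": p[1], "z": p[2], "radius": t.search_radius}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _insert_from_json(entry: dict) -> PhantomInsert:
    if "cylinder" in entry:
        cyl = entry["cylinder"]
        return PhantomInsert(
            density=float(entry["density"]),
            cylinder=Cylinder(
                center=tuple(cyl["center"]),
                radius=float(cyl["radius"]),
                half_length=float(cyl["half_length"]),
                axis=int(cyl.get("axis", 2)),
            ),
        )
    if "voxels" in entry:
        return PhantomInsert(
            density=float(entry["density"]),
            voxels=np.asarray(entry["voxels"], dtype=int),
        )
    raise FormatError("phantom insert needs a 'cylinder' or 'voxels' field")


def read_phantom(path: str) -> PhantomSpec:
    """Read a geometric phantom specification from JSON."""
    if not os.path.exists(path):
        raise FormatError(f"phantom file not found: {path}")
    with open(path) as fh:
        raw = json.load(fh)
    if "inserts" not in raw:
        raise FormatError(f"{path}: phantom JSON needs an 'inserts' list")
    return PhantomSpec(inserts=[_insert_from_json(e) for e in raw["inserts"]])


def write_phantom(phantom: PhantomSpec, path: str) -> None:
    payload = {"inserts": []}
    for ins in phantom.inserts:
        entry: dict = {"density": ins.density}
        if ins.cylinder is not None:
            entry["cylinder"] = {
                "center": list(ins.cylinder.center),
                "radius": ins.cylinder.radius,
                "half_length": ins.cylinder.half_length,
                "axis": ins.cylinder.axis,
            }
        else:
            entry["voxels"] = ins.voxels.tolist()
        payload["inserts"].append(entry)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def phantom_from_label_mask(labels: np.ndarray, density_map: dict) -> PhantomSpec:
    """Build a PhantomSpec from an integer label volume.

    ``density_map`` maps label value -> known density (mg/mL); keys may be
    strings (JSON sidecar convention) or ints.
    """
    labels = np.asarray(labels)
    inserts = []
    for key, density in density_map.items():
        label = int(key)
        idx = np.argwhere(labels == label)
        if len(idx) == 0:
            raise FormatError(f"label {label} absent from phantom mask")
        inserts.append(PhantomInsert(density=float(density), voxels=idx))
    return PhantomSpec(inserts=inserts)


_SCORE_COLUMNS = ["scan_id", "participant_id", "agatston", "swcs", "n_lesions"]


def write_scores(
    results: Sequence[ScoreResult], path: str, header_comments: Sequence[str] = ()
) -> None:
    """Write scores as CSV with a fixed header and deterministic row order
    (participant_id, scan_id).  Optional '#' comment lines carry the resolved
    configuration."""
    if not results:
        raise FormatError("cannot write an empty score table")
    df = pd.DataFrame(
        [
            {
                "scan_id": r.scan_id,
                "participant_id": r.participant_id,
                "agatston": r.agatston,
                "swcs": r.swcs,
                "n_lesions": r.n_lesions,
            }
            for r in results
        ]
    ).sort_values(["participant_id", "scan_id"], kind="stable")
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, columns=_SCORE_COLUMNS)


def read_scores(path: str) -> pd.DataFrame:
    """Read a score CSV written by :func:`write_scores`."""
    if not os.path.exists(path):
        raise FormatError(f"score file not found: {path}")
    df = pd.read_csv(path, comment="#", dtype={"scan_id": str, "participant_id": str})
    missing = set(_SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing score columns {sorted(missing)}")
    return df
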