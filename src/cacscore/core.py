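"""Core domain types for coronary-artery-calcium scoring.

Coordinate convention
---------------------
Volumes are 3D arrays indexed ``(i, j, k)`` = ``(x, y, z)`` with ``z`` the
slice axis.  Voxel indices are 0-based and the physical position (mm) of the
*center* of voxel ``(i, j, k)`` is ``origin + (i*dx, j*dy, k*dz)``.  No
resampling is ever performed: anisotropic spacing (e.g. 2.5/3.0 mm slices
with sub-millimetre in-plane pixels) is respected by every computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "EmptyRegionError",
    "CTVolume",
    "Cylinder",
    "PhantomInsert",
    "PhantomSpec",
    "ArteryTrajectory",
    "Lesion",
    "ScoreResult",
    "region_of_interest",
]


class FormatError(ValueError):
    """An input file or in-memory object violates its format contract."""


class EmptyRegionError(RuntimeError):
    """A computation received an empty voxel region where one is required."""


@dataclass
class CTVolume:
    """A 3D CT attenuation volume in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Attenuation in HU; must be finite everywhere.
    spacing : (dx, dy, dz)
        Voxel spacing in mm along each axis; all strictly positive.
    origin : (x0, y0, z0)
        Physical position (mm) of the center of voxel (0, 0, 0).
    scan_id, participant_id : str
        Opaque identifiers carried through to score tables.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scan_id: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError(
                f"voxels must be 3D, got {self.voxels.ndim}D data"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive floats, got {self.spacing}")
        if len(self.origin) != 3:
            raise FormatError(f"origin must have 3 components, got {self.origin}")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("voxels contain NaN or Inf attenuation values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) of all voxels along one axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to physical mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass
class Cylinder:
    """Axis-aligned cylinder in physical mm coordinates.

    ``axis`` is the cylinder's long axis (0=x, 1=y, 2=z); ``radius`` is the
    cross-sectional radius and ``half_length`` half the extent along ``axis``.
    """

    center: tuple[float, float, float]
    radius: float
    half_length: float
    axis: int = 2

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)
        if self.radius <= 0 or self.half_length <= 0:
            raise FormatError("cylinder radius and half_length must be positive")
        if self.axis not in (0, 1, 2):
            raise FormatError(f"cylinder axis must be 0, 1 or 2, got {self.axis}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership test for an (n, 3) array of mm coordinates."""
        p = np.atleast_2d(points) - np.asarray(self.center)
        cross = [a for a in range(3) if a != self.axis]
        r2 = p[:, cross[0]] ** 2 + p[:, cross[1]] ** 2
        return (r2 <= self.radius**2) & (np.abs(p[:, self.axis]) <= self.half_length)


@dataclass
class PhantomInsert:
    """One calibration-phantom insert of known calcium-hydroxyapatite density.

    The insert region is given either as explicit voxel indices or as a
    :class:`Cylinder` in physical coordinates (resolved against a volume at
    measurement time).
    """

    density: float  # mg/mL calcium hydroxyapatite
    voxels: np.ndarray | None = None  # (n, 3) int voxel indices
    cylinder: Cylinder | None = None

    def __post_init__(self) -> None:
        self.density = float(self.density)
        if self.density < 0:
            raise FormatError("insert density must be non-negative")
        if (self.voxels is None) == (self.cylinder is None):
            raise FormatError("insert needs exactly one of voxels or cylinder")
        if self.voxels is not None:
            self.voxels = np.asarray(self.voxels, dtype=int)
            if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
                raise FormatError("insert voxels must be an (n, 3) index array")

    def resolve_indices(self, volume: CTVolume) -> np.ndarray:
        """Voxel indices of the insert region inside ``volume``."""
        if self.voxels is not None:
            return self.voxels
        grids = np.meshgrid(
            *(volume.axis_coordinates(a) for a in range(3)), indexing="ij"
        )
        pts = np.stack([g.ravel() for g in grids], axis=1)
        inside = self.cylinder.contains(pts).reshape(volume.shape)
        return np.argwhere(inside)


@dataclass
class PhantomSpec:
    """Calibration phantom: inserts of known density scanned with the patient.

    The reference design has densities {0, 50, 100, 200} mg/mL; at least two
    distinct densities are required to fit a calibration line.
    """

    inserts: list[PhantomInsert]

    def __post_init__(self) -> None:
        if len(self.inserts) < 2:
            raise FormatError("phantom needs at least 2 inserts for calibration")
        densities = [ins.density for ins in self.inserts]
        if len(set(densities)) != len(densities):
            raise FormatError(f"insert densities must be distinct, got {densities}")

    @property
    def densities(self) -> list[float]:
        return [ins.density for ins in self.inserts]


@dataclass
class ArteryTrajectory:
    """Reader-traced coronary-artery centerline.

    Candidate calcium is sought within ``search_radius`` mm (default 8) of
    the polyline through ``points`` (ordered physical mm coordinates).
    """

    name: str
    points: np.ndarray  # (n, 3) mm
    search_radius: float = 8.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise FormatError("trajectory points must be an (n, 3) array")
        if len(self.points) < 2:
            raise FormatError(
                f"trajectory '{self.name}' needs >= 2 points, got {len(self.points)}"
            )
        if not np.all(np.isfinite(self.points)):
            raise FormatError(f"trajectory '{self.name}' has non-numeric coordinates")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise FormatError(f"trajectory '{self.name}' has identical consecutive points")
        self.search_radius = float(self.search_radius)
        if self.search_radius <= 0:
            raise FormatError("search_radius must be positive")


@dataclass(frozen=True)
class Lesion:
    """A detected calcified lesion: a connected supra-threshold component.

    ``voxel_indices`` is a tuple of (i, j, k) tuples sorted lexicographically,
    ``volume`` is in mm^3, ``coefficient`` the attenuation bin (1-4) and
    ``lesion_score`` = volume * coefficient.
    """

    voxel_indices: tuple[tuple[int, int, int], ...]
    volume: float
    max_hu: float
    coefficient: int
    lesion_score: float

    def __post_init__(self) -> None:
        if len(self.voxel_indices) < 4:
            raise FormatError("a lesion requires at least 4 contiguous voxels")
        if self.max_hu < 130:
            raise FormatError("lesion max_hu must be >= 130 HU")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)


@dataclass
class ScoreResult:
    """Per-scan (or per-participant, after averaging) calcium scores."""

    scan_id: str
    participant_id: str
    agatston: float
    swcs: float
    n_lesions: float

    def __post_init__(self) -> None:
        if self.agatston < 0:
            raise FormatError("agatston score must be >= 0")
        if self.swcs < 0:
            raise FormatError("swcs must be positive")


def _segment_distance_grid(
    volume: CTVolume, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Distance from every voxel center to the segment a-b (full 3D grid)."""
    xs = volume.axis_coordinates(0)[:, None, None]
    ys = volume.axis_coordinates(1)[None, :, None]
    zs = volume.axis_coordinates(2)[None, None, :]
    ab = b - a
    denom = float(ab @ ab)
    # consecutive trajectory points are guaranteed distinct
    t = ((xs - a[0]) * ab[0] + (ys - a[1]) * ab[1] + (zs - a[2]) * ab[2]) / denom
    np.clip(t, 0.0, 1.0, out=t)
    d2 = (
        (xs - a[0] - t * ab[0]) ** 2
        + (ys - a[1] - t * ab[1]) ** 2
        + (zs - a[2] - t * ab[2]) ** 2
    )
    return np.sqrt(d2)


def _roi_2d_slicewise(
    volume: CTVolume, traj: ArteryTrajectory, mask: np.ndarray
) -> None:
    """Per-slice variant: in-plane distance to the polyline clipped to each
    slice slab (voxel z-center +/- dz/2)."""
    dz = volume.spacing[2]
    zs = volume.axis_coordinates(2)
    xs = volume.axis_coordinates(0)[:, None]
    ys = volume.axis_coordinates(1)[None, :]
    for k, zc in enumerate(zs):
        zlo, zhi = zc - dz / 2.0, zc + dz / 2.0
        for a, b in zip(traj.points[:-1], traj.points[1:]):
            az, bz = a[2], b[2]
            if az == bz:
                if not (zlo <= az <= zhi):
                    continue
                t0, t1 = 0.0, 1.0
            else:
                ta = (zlo - az) / (bz - az)
                tb = (zhi - az) / (bz - az)
                t0, t1 = max(0.0, min(ta, tb)), min(1.0, max(ta, tb))
                if t0 > t1:
                    continue
            p0 = a[:2] + t0 * (b[:2] - a[:2])
            p1 = a[:2] + t1 * (b[:2] - a[:2])
            seg = p1 - p0
            denom = float(seg @ seg)
            if denom == 0.0:
                d2 = (xs - p0[0]) ** 2 + (ys - p0[1]) ** 2
            else:
                t = ((xs - p0[0]) * seg[0] + (ys - p0[1]) * seg[1]) / denom
                np.clip(t, 0.0, 1.0, out=t)
                d2 = (xs - p0[0] - t * seg[0]) ** 2 + (ys - p0[1] - t * seg[1]) ** 2
            mask[:, :, k] |= d2 <= traj.search_radius**2


def region_of_interest(
    volume: CTVolume,
    trajectories: Sequence[ArteryTrajectory],
    mode: str = "3d",
) -> np.ndarray:
    """Voxels within each trajectory's search radius (default 8 mm).

    Returns a boolean mask over the volume grid; a voxel belongs to the
    region of interest when its *center* lies within ``search_radius`` of
    any polyline (Euclidean point-to-segment distance), unioned over
    arteries.  ``mode="2d"`` restricts the test to in-plane distance per
    slice, emulating reader software that applied the radius slice by slice.

    An empty mask is not an error here; downstream scoring raises
    :class:`EmptyRegionError` where a non-empty region is required.
    """
    if not trajectories:
        raise FormatError("at least one artery trajectory is required")
    if mode not in ("3d", "2d"):
        raise FormatError(f"mode must be '3d' or '2d', got {mode!r}")
    mask = np.zeros(volume.shape, dtype=bool)
    for traj in trajectories:
        if mode == "2d":
            _roi_2d_slicewise(volume, traj, mask)
            continue
        dmin = np.full(volume.shape, np.inf)
        for a, b in zip(traj.points[:-1], traj.points[1:]):
            np.minimum(dmin, _segment_distance_grid(volume, a, b), out=dmin)
        mask |= dmin <= traj.search_radius
    return mask
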