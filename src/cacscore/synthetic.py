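"""Synthetic cardiac-CT cohort generator with known ground truth.

Emulates the two-consecutive-scan acquisition protocol: a soft-tissue
background, a four-insert calcium-hydroxyapatite calibration phantom
(0/50/100/200 mg/mL) beneath the "thorax", a reader-style coronary
centerline polyline, spherical calcified plaques placed within the 8 mm
search radius of that centerline, additive Gaussian scanner noise, and —
between the two replicate scans of a participant — independent noise plus a
small random jitter of the trajectory and plaque positions.

Plaques are solid uniform-density spheres rasterised by voxel-center
sampling (a voxel belongs to a plaque when its center lies inside the
sphere); ground truth therefore stays exactly computable.  Participants
destined for a zero Agatston score carry small *high-density* plaques that
cover fewer than four voxels — the minimum-cluster-size route to an
undetectable lesion, mirroring how real small calcifications fall below
"at least 4 contiguous voxels at >= 130 HU" — so the threshold-free score
still sees them.  Low-density (sub-criterion) plaques are available through
the density-range fields for threshold-contrast experiments.

Everything is driven by per-participant / per-scan RNG substreams of a
single seed, so cohorts are reproducible and extensible.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
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
)

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticPlaque",
    "GroundTruth",
    "ScanBundle",
    "density_to_hu",
    "make_phantom",
    "generate_scan",
    "generate_participant",
    "generate_cohort",
]


@dataclass
class SyntheticCohortConfig:
    """Simulation parameters for a synthetic cohort.

    The density->HU map of the simulated scanner defaults to
    ``HU = 10 + 1.2 * density`` so the conventional 130 HU operating point
    sits at 100 mg/mL — inside the phantom's density range, where the
    auto-selected criterion density lands.  ``fraction_zero_as`` is the
    target fraction of participants whose plaques are kept below the
    4-contiguous-voxel detection minimum (the cohort's zero-score stratum).
    """

    n_participants: int = 200
    n_scans_per_participant: int = 2
    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (0.68, 0.68, 3.0)
    phantom_densities: tuple[float, ...] = (0.0, 50.0, 100.0, 200.0)
    phantom_radius: float = 2.5  # mm, insert cross-section
    hu_intercept: float = 10.0  # HU at zero density
    hu_slope: float = 1.2  # HU per mg/mL
    background_hu: float = 30.0  # soft tissue
    noise_sd: float = 15.0  # HU, additive Gaussian
    jitter_sd: float = 0.25  # mm, per-scan trajectory/plaque jitter
    fraction_zero_as: float = 0.5
    plaques_min: int = 1
    plaques_max: int = 4
    supra_radius_range: tuple[float, float] = (1.2, 4.0)
    supra_density_range: tuple[float, float] = (150.0, 400.0)
    zero_plaques_min: int = 1
    zero_plaques_max: int = 8
    zero_radius_range: tuple[float, float] = (0.65, 1.0)
    zero_density_range: tuple[float, float] = (150.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise FormatError("noise_sd and jitter_sd must be >= 0")
        if not 0.0 <= self.fraction_zero_as <= 1.0:
            raise FormatError("fraction_zero_as must be in [0, 1]")
        if self.n_scans_per_participant not in (1, 2):
            raise FormatError("n_scans_per_participant must be 1 or 2")
        if self.plaques_min < 1 or self.plaques_max < self.plaques_min:
            raise FormatError("need 1 <= plaques_min <= plaques_max")
        if self.zero_plaques_min < 1 or self.zero_plaques_max < self.zero_plaques_min:
            raise FormatError("need 1 <= zero_plaques_min <= zero_plaques_max")

    @property
    def extent(self) -> np.ndarray:
        """Physical field of view (mm) per axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing)


@dataclass
class SyntheticPlaque:
    center: tuple[float, float, float]  # mm
    radius: float  # mm
    density: float  # mg/mL


@dataclass
class GroundTruth:
    """Participant-level truth shared by replicate scans."""

    participant_id: str
    plaques: list[SyntheticPlaque]
    true_volume_mm3: float  # voxelised volume of the base (unjittered) plaques
    supra_threshold: bool  # does any plaque meet the detection criteria
    n_plaques: int


@dataclass
class ScanBundle:
    volume: CTVolume
    phantom: PhantomSpec
    trajectories: list[ArteryTrajectory]
    truth: GroundTruth


def density_to_hu(config: SyntheticCohortConfig, density) -> np.ndarray | float:
    """Simulated scanner's attenuation at a calcium density (noise-free)."""
    return config.hu_intercept + config.hu_slope * np.asarray(density, dtype=float)


def make_phantom(config: SyntheticCohortConfig) -> PhantomSpec:
    """Cylindrical inserts in a row beneath the thorax region (high y),
    long axis along z."""
    ex, ey, ez = config.extent
    n = len(config.phantom_densities)
    xs = np.linspace(0.18 * ex, 0.82 * ex, n)
    inserts = [
        PhantomInsert(
            density=d,
            cylinder=Cylinder(
                center=(float(x), 0.85 * ey, 0.5 * ez),
                radius=config.phantom_radius,
                half_length=0.42 * ez,
                axis=2,
            ),
        )
        for d, x in zip(config.phantom_densities, xs)
    ]
    return PhantomSpec(inserts=inserts)


def _covered_indices(
    config: SyntheticCohortConfig, center: np.ndarray, radius: float
) -> np.ndarray:
    """Voxel indices whose centers lie inside a sphere (origin at 0)."""
    sp = np.asarray(config.spacing)
    shape = np.asarray(config.shape)
    lo = np.maximum(np.ceil((center - radius) / sp).astype(int), 0)
    hi = np.minimum(np.floor((center + radius) / sp).astype(int), shape - 1)
    if np.any(lo > hi):
        return np.empty((0, 3), dtype=int)
    grids = np.meshgrid(
        *(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij"
    )
    idx = np.stack([g.ravel() for g in grids], axis=1)
    d2 = np.sum((idx * sp - center) ** 2, axis=1)
    return idx[d2 <= radius**2]


def _base_trajectory(
    config: SyntheticCohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """A gently bending three-point centerline through the cardiac region."""
    ex, ey, ez = config.extent
    zs = np.array([0.06 * ez, 0.5 * ez, 0.94 * ez])
    xs = 0.45 * ex + rng.uniform(-2.0, 2.0, size=3)
    ys = 0.33 * ey + rng.uniform(-2.0, 2.0, size=3)
    return np.column_stack([xs, ys, zs])


def _point_on_polyline(points: np.ndarray, t: float) -> np.ndarray:
    """Point at arc-length fraction t in [0, 1] along a polyline."""
    seg = np.diff(points, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    s = t * cum[-1]
    i = int(np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1))
    frac = (s - cum[i]) / lengths[i]
    return points[i] + frac * seg[i]


def _sample_plaque_center(
    config: SyntheticCohortConfig,
    traj_points: np.ndarray,
    radius: float,
    rng: np.random.Generator,
    existing: list[SyntheticPlaque],
) -> np.ndarray | None:
    ex, ey, ez = config.extent
    phantom_y = 0.85 * ey
    base = _point_on_polyline(traj_points, rng.uniform(0.05, 0.95))
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    center = base + direction * rng.uniform(0.0, 5.5)
    margin = radius + 1.0
    if np.any(center < margin) or np.any(center > config.extent - margin):
        return None
    if center[1] > phantom_y - config.phantom_radius - radius - 2.0:
        return None  # keep plaques clear of the phantom
    # separation exceeds the 26-neighbourhood physical diagonal
    # (sqrt(dx^2+dy^2+dz^2) ~ 3.2 mm), so voxels of distinct plaques can
    # never be contiguous and small clusters cannot merge past the
    # detection minimum
    for p in existing:
        if np.linalg.norm(center - np.asarray(p.center)) < radius + p.radius + 5.0:
            return None
    return center


def _make_plaques(
    config: SyntheticCohortConfig,
    traj_points: np.ndarray,
    zero_as: bool,
    rng: np.random.Generator,
) -> list[SyntheticPlaque]:
    """Sample this participant's plaques, enforcing the score stratum.

    Zero-stratum plaques must cover 1-3 voxel centers (below the detection
    minimum); supra-stratum participants get at least one plaque covering
    >= 5 voxels so a detectable lesion always exists.
    """
    if zero_as:
        n = int(rng.integers(config.zero_plaques_min, config.zero_plaques_max + 1))
    else:
        n = int(rng.integers(config.plaques_min, config.plaques_max + 1))
    r_lo, r_hi = config.zero_radius_range if zero_as else config.supra_radius_range
    d_lo, d_hi = config.zero_density_range if zero_as else config.supra_density_range
    plaques: list[SyntheticPlaque] = []
    for j in range(n):
        placed = False
        for _ in range(200):
            radius = rng.uniform(r_lo, r_hi)
            center = _sample_plaque_center(config, traj_points, radius, rng, plaques)
            if center is None:
                continue
            count = len(_covered_indices(config, center, radius))
            if zero_as:
                ok = 1 <= count <= 3
            elif j == 0:
                ok = count >= 5
            else:
                ok = count >= 1
            if ok:
                plaques.append(
                    SyntheticPlaque(
                        center=tuple(float(c) for c in center),
                        radius=float(radius),
                        density=float(rng.uniform(d_lo, d_hi)),
                    )
                )
                placed = True
                break
        if not placed and j == 0:
            raise FormatError("plaque placement failed after bounded retries")
    return plaques


def _participant_truth(
    config: SyntheticCohortConfig, participant: int
) -> tuple[GroundTruth, np.ndarray, bool]:
    """Base (scan-independent) ground truth for one participant."""
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, participant, 7))
    )
    zero_as = bool(rng.random() < config.fraction_zero_as)
    traj_points = _base_trajectory(config, rng)
    plaques = _make_plaques(config, traj_points, zero_as, rng)
    # true volume is the voxelised volume of the base geometry: the volume
    # of calcium the scanner's grid actually resolves (plaques are disjoint
    # by construction, so counts add)
    covered = 0
    for p in plaques:
        covered += len(_covered_indices(config, np.asarray(p.center), p.radius))
    truth = GroundTruth(
        participant_id=f"P{participant:04d}",
        plaques=plaques,
        true_volume_mm3=covered * float(np.prod(config.spacing)),
        supra_threshold=not zero_as,
        n_plaques=len(plaques),
    )
    return truth, traj_points, zero_as


def _render_scan(
    config: SyntheticCohortConfig,
    truth: GroundTruth,
    traj_points: np.ndarray,
    zero_as: bool,
    participant: int,
    scan_index: int,
) -> tuple[CTVolume, list[ArteryTrajectory]]:
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, participant, 1000 + scan_index))
    )
    vol = np.full(config.shape, config.background_hu, dtype=float)
    phantom = make_phantom(config)
    tmp = CTVolume(voxels=vol, spacing=config.spacing, origin=(0.0, 0.0, 0.0))
    for ins in phantom.inserts:
        idx = ins.resolve_indices(tmp)
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = density_to_hu(config, ins.density)
    # sub-voxel differences between consecutive acquisitions: independent
    # tracing noise on the reader's centerline points and a small
    # displacement of each plaque relative to the sampling grid
    points = traj_points + rng.normal(0.0, config.jitter_sd, size=traj_points.shape)
    for p in truth.plaques:
        center = np.asarray(p.center) + rng.normal(0.0, config.jitter_sd, size=3)
        radius = p.radius
        idx = _covered_indices(config, center, radius)
        if zero_as:
            # jitter may push a tiny plaque's footprint across the
            # 4-contiguous-voxel detection minimum; redraw its displacement
            # (jitter conditioned on the stratum flag), shrinking only as a
            # last resort
            for _ in range(30):
                if len(idx) <= 3:
                    break
                center = np.asarray(p.center) + rng.normal(
                    0.0, config.jitter_sd, size=3
                )
                idx = _covered_indices(config, center, radius)
            for _ in range(30):
                if len(idx) <= 3:
                    break
                radius *= 0.85
                idx = _covered_indices(config, center, radius)
        if len(idx):
            hu = density_to_hu(config, p.density)
            vol[idx[:, 0], idx[:, 1], idx[:, 2]] = np.maximum(
                vol[idx[:, 0], idx[:, 1], idx[:, 2]], hu
            )
    if config.noise_sd > 0:
        vol += rng.normal(0.0, config.noise_sd, size=vol.shape)
    pid = f"P{participant:04d}"
    volume = CTVolume(
        voxels=vol,
        spacing=config.spacing,
        origin=(0.0, 0.0, 0.0),
        scan_id=f"{pid}_S{scan_index}",
        participant_id=pid,
    )
    trajectories = [
        ArteryTrajectory(name="coronary", points=points, search_radius=8.0)
    ]
    return volume, trajectories


def generate_scan(
    config: SyntheticCohortConfig, participant: int, scan_index: int
) -> ScanBundle:
    """Generate one scan of one participant (deterministic in the config seed).

    Replicate scans (``scan_index`` 1, 2, ...) share the participant's
    plaque ground truth but carry independent noise and sub-voxel jitter.
    """
    truth, traj_points, zero_as = _participant_truth(config, participant)
    volume, trajectories = _render_scan(
        config, truth, traj_points, zero_as, participant, scan_index
    )
    return ScanBundle(
        volume=volume,
        phantom=make_phantom(config),
        trajectories=trajectories,
        truth=truth,
    )


def generate_participant(
    config: SyntheticCohortConfig, participant: int
) -> list[ScanBundle]:
    """All replicate scans of one participant."""
    return [
        generate_scan(config, participant, s + 1)
        for s in range(config.n_scans_per_participant)
    ]


def truth_table(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "n_plaques": t.n_plaques,
                "true_volume_mm3": t.true_volume_mm3,
                "supra_threshold": t.supra_threshold,
            }
            for t in truths
        ]
    )


def generate_cohort(
    config: SyntheticCohortConfig, out_dir: str | None = None
) -> tuple[list[list[ScanBundle]], pd.DataFrame]:
    """Generate the whole cohort; optionally write it to disk.

    Returns the per-participant scan bundles and the ground-truth table.
    With ``out_dir`` set, writes one NIfTI volume and one trajectory JSON
    per scan, a shared phantom JSON, ``ground_truth.csv`` and the resolved
    configuration.
    """
    from . import io as _io

    participants = []
    truths = []
    for p in range(config.n_participants):
        scans = generate_participant(config, p)
        participants.append(scans)
        truths.append(scans[0].truth)
    table = truth_table(truths)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        _io.write_phantom(make_phantom(config), os.path.join(out_dir, "phantom.json"))
        for scans in participants:
            for bundle in scans:
                sid = bundle.volume.scan_id
                _io.write_volume(
                    bundle.volume, os.path.join(out_dir, f"{sid}.nii.gz")
                )
                _io.write_trajectories(
                    bundle.trajectories,
                    os.path.join(out_dir, f"{sid}_trajectories.json"),
                )
        table.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            json.dump(asdict(config), fh, indent=1)
    return participants, table
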