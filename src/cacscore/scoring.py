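"""Agatston and spatially weighted calcium scores for one CT scan.

Agatston score (as used throughout): connected components of voxels at
>= 130 HU inside the coronary search region, kept when they span at least 4
contiguous voxels; each lesion contributes ``volume(mm^3) * coefficient``
with the coefficient set by the lesion's maximum attenuation (130-199 -> 1,
200-299 -> 2, 300-399 -> 3, >= 400 -> 4), and the score is the sum over
lesions.  Note this is the volume-times-coefficient variant; the classic
per-slice area scoring is deliberately out of scope.

Spatially weighted calcium score (SWCS), two steps:

1. every voxel gets a phantom-calibrated weight ``w = Phi((HU - mu_c)/sigma_c)``
   (zero outside the search region);
2. every voxel gets an adjusted score ``s[v] = w[v] * mean(w over the 3x3x3
   neighbourhood of v, including v, truncated at volume borders)``, which
   upweights voxels whose neighbours also show high attenuation and
   suppresses isolated noise.

SWCS = kappa * sum over region voxels of s[v] * voxel_volume.  It is strictly
positive for any non-empty region and strictly increasing in every voxel's
attenuation, so calcium below the 130 HU threshold still moves the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .calibration import (
    CalibrationModel,
    apply_hu_recalibration,
    extract_phantom_stats,
    fit_calibration,
    voxel_weight,
)
from .core import (
    ArteryTrajectory,
    CTVolume,
    EmptyRegionError,
    FormatError,
    Lesion,
    PhantomSpec,
    ScoreResult,
    region_of_interest,
)

__all__ = [
    "find_lesions",
    "agatston_coefficient",
    "agatston_score",
    "weight_field",
    "adjusted_score_field",
    "swcs_score",
    "ScanConfig",
    "score_scan",
    "participant_score",
    "log_transform",
    "calibrate_kappa",
]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise FormatError(f"connectivity must be 6 or 26, got {connectivity}")


def find_lesions(
    volume: CTVolume,
    roi: np.ndarray,
    threshold: float = 130.0,
    min_voxels: int = 4,
    connectivity: int = 26,
    exclusion_mask: np.ndarray | None = None,
) -> list[Lesion]:
    """Detect candidate calcified lesions inside the search region.

    Connected components (6- or 26-connectivity, default 26) of voxels with
    HU >= ``threshold`` within ``roi``; components of fewer than
    ``min_voxels`` voxels are discarded.  ``exclusion_mask`` marks voxels a
    reviewer rejected (the interactive plaque review step replaced by a mask
    input).  Lesions are returned sorted by their lexicographically smallest
    voxel index, so labeling order never affects output.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != volume.shape:
        raise FormatError("roi mask shape does not match volume")
    mask = roi & (volume.voxels >= threshold)
    if exclusion_mask is not None:
        mask &= ~np.asarray(exclusion_mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    lesions = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_voxels:
            continue
        hu = volume.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
        max_hu = float(hu.max())
        vol = len(idx) * volume.voxel_volume
        coef = agatston_coefficient(max_hu)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        voxel_indices = tuple(tuple(int(v) for v in idx[i]) for i in order)
        lesions.append(
            Lesion(
                voxel_indices=voxel_indices,
                volume=vol,
                max_hu=max_hu,
                coefficient=coef,
                lesion_score=vol * coef,
            )
        )
    lesions.sort(key=lambda l: l.voxel_indices[0])
    return lesions


def agatston_coefficient(max_hu: float) -> int:
    """Attenuation coefficient bin: 130-199 -> 1, 200-299 -> 2, 300-399 -> 3,
    >= 400 -> 4.  Below 130 HU no lesion exists, so this is a contract error."""
    if max_hu < 130:
        raise FormatError(f"no coefficient below the 130 HU threshold (got {max_hu})")
    if max_hu < 200:
        return 1
    if max_hu < 300:
        return 2
    if max_hu < 400:
        return 3
    return 4


def agatston_score(lesions: Sequence[Lesion]) -> float:
    """Sum of volume * coefficient over accepted lesions; 0 when none."""
    return float(sum(l.lesion_score for l in lesions))


def weight_field(
    volume: CTVolume, roi: np.ndarray, model: CalibrationModel
) -> np.ndarray:
    """Phantom-calibrated per-voxel weights, exactly zero outside the region."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != volume.shape:
        raise FormatError("roi mask shape does not match volume")
    w = np.zeros(volume.shape, dtype=float)
    w[roi] = voxel_weight(volume.voxels[roi], model)
    return w


def _neighborhood_kernel(neighborhood: int) -> np.ndarray:
    return _structure(neighborhood).astype(float)


def adjusted_score_field(
    w: np.ndarray, neighborhood: int = 26
) -> np.ndarray:
    """Neighbour-adjusted scores s[v] = w[v] * mean(w over N(v) including v).

    The neighbourhood is the full 3x3x3 block (26) or the face-adjacent
    cross (6), truncated at the volume border (no padding): the mean divides
    by the number of in-volume neighbours only.
    """
    kernel = _neighborhood_kernel(neighborhood)
    wsum = ndimage.correlate(w, kernel, mode="constant", cval=0.0)
    counts = ndimage.correlate(np.ones_like(w), kernel, mode="constant", cval=0.0)
    return w * (wsum / counts)


def swcs_score(
    volume: CTVolume,
    roi: np.ndarray,
    model: CalibrationModel,
    neighborhood: int = 26,
    kappa: float = 1.0,
) -> float:
    """Spatially weighted calcium score for one scan.

    Raises :class:`EmptyRegionError` for an empty region — a structurally
    different outcome from a small positive score.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise EmptyRegionError("search region is empty; cannot compute SWCS")
    w = weight_field(volume, roi, model)
    s = adjusted_score_field(w, neighborhood=neighborhood)
    return float(kappa * s[roi].sum() * volume.voxel_volume)


@dataclass
class ScanConfig:
    """Resolved per-scan scoring configuration (all defaults explicit)."""

    threshold: float = 130.0
    min_voxels: int = 4
    connectivity: int = 26
    neighborhood: int = 26
    criterion_density: float | str = "auto"
    sigma_floor: float = 1.0
    kappa: float = 1.0
    roi_mode: str = "3d"
    hu_recalibration: tuple[float, float] | None = None  # (nominal a, b); off

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "min_voxels": self.min_voxels,
            "connectivity": self.connectivity,
            "neighborhood": self.neighborhood,
            "criterion_density": self.criterion_density,
            "sigma_floor": self.sigma_floor,
            "kappa": self.kappa,
            "roi_mode": self.roi_mode,
            "hu_recalibration": self.hu_recalibration,
        }


def score_scan(
    volume: CTVolume,
    trajectories: Sequence[ArteryTrajectory],
    phantom: PhantomSpec,
    config: ScanConfig | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> ScoreResult:
    """Full per-scan pipeline: phantom stats -> calibration -> search region
    -> lesion detection / Agatston -> SWCS.

    Component failures are re-raised with the pipeline stage prepended so a
    batch run reports where a scan broke.
    """
    cfg = config or ScanConfig()
    stage = "phantom statistics"
    try:
        stats = extract_phantom_stats(volume, phantom)
        stage = "calibration fit"
        model = fit_calibration(
            stats,
            criterion_density=cfg.criterion_density,
            sigma_floor=cfg.sigma_floor,
        )
        stage = "HU recalibration"
        scored_volume = volume
        if cfg.hu_recalibration is not None:
            scored_volume = apply_hu_recalibration(
                volume, model, *cfg.hu_recalibration
            )
        stage = "region of interest"
        roi = region_of_interest(scored_volume, trajectories, mode=cfg.roi_mode)
        if not roi.any():
            raise EmptyRegionError(
                "no voxel centers fall inside any trajectory search radius"
            )
        stage = "lesion detection"
        lesions = find_lesions(
            scored_volume,
            roi,
            threshold=cfg.threshold,
            min_voxels=cfg.min_voxels,
            connectivity=cfg.connectivity,
            exclusion_mask=exclusion_mask,
        )
        stage = "SWCS"
        swcs = swcs_score(
            scored_volume, roi, model, neighborhood=cfg.neighborhood, kappa=cfg.kappa
        )
    except (FormatError, EmptyRegionError) as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc
    return ScoreResult(
        scan_id=volume.scan_id,
        participant_id=volume.participant_id,
        agatston=agatston_score(lesions),
        swcs=swcs,
        n_lesions=len(lesions),
    )


def participant_score(results: Sequence[ScoreResult]) -> ScoreResult:
    """Per-participant score: the arithmetic mean over available scans
    (the two-scan protocol averages both; a single scan passes through)."""
    if not 1 <= len(results) <= 2:
        raise FormatError(f"expected 1 or 2 scans per participant, got {len(results)}")
    pids = {r.participant_id for r in results}
    if len(pids) != 1:
        raise FormatError(f"mixed participant ids in one average: {sorted(pids)}")
    return ScoreResult(
        scan_id="+".join(r.scan_id for r in results),
        participant_id=results[0].participant_id,
        agatston=float(np.mean([r.agatston for r in results])),
        swcs=float(np.mean([r.swcs for r in results])),
        n_lesions=float(np.mean([r.n_lesions for r in results])),
    )


def log_transform(score, base=2):
    """log_base(score + 1): base 2 for event models, natural log for the
    risk-factor regressions.  Scores must be non-negative."""
    score = np.asarray(score, dtype=float)
    if np.any(score < 0):
        raise FormatError("log transform requires non-negative scores")
    if base == 2:
        out = np.log2(score + 1.0)
    elif base in ("e", np.e):
        out = np.log1p(score)
    else:
        raise FormatError(f"base must be 2 or 'e', got {base!r}")
    return float(out) if out.ndim == 0 else out


def calibrate_kappa(results: Sequence[ScoreResult]) -> float:
    """Global SWCS scale fitted so kappa*SWCS tracks the Agatston score.

    Through-origin least squares of AS on SWCS over scans with AS > 0 (the
    stratum where the two scores measure the same lesions).  Utility only;
    the default scale is kappa = 1.
    """
    a = np.array([r.agatston for r in results if r.agatston > 0])
    s = np.array([r.swcs for r in results if r.agatston > 0])
    if len(a) == 0:
        raise EmptyRegionError("kappa calibration needs scans with AS > 0")
    return float((a @ s) / (s @ s))
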