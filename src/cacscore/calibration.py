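"""Phantom-based attenuation calibration and the SWCS voxel-weighting function.

Each scan is acquired with a calibration phantom of known calcium-
hydroxyapatite densities (reference design: 0, 50, 100, 200 mg/mL) beneath
the thorax.  Per-insert attenuation statistics parameterise two ordinary
least-squares lines,

    mean HU(d) = a_mu + b_mu * d        sd HU(d) = a_sigma + b_sigma * d,

evaluated at a *criterion density* c to give (mu_c, sigma_c).  A voxel with
attenuation ``hu`` then receives the weight

    w(hu) = Phi((hu - mu_c) / sigma_c),

the probability that a voxel drawn from the phantom-implied attenuation
distribution at the criterion calcium density would show at most the
observed HU.  The weight is smooth, threshold-free, strictly increasing in
HU and strictly positive, so every scored scan receives a positive score
even when no voxel reaches the conventional 130 HU detection threshold.

By default the criterion density is chosen so that its fitted mean
attenuation equals 130 HU (``c = (130 - a_mu)/b_mu``, clipped to the phantom
density range), anchoring the continuous score to the same operating point
as thresholded scoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.special import ndtr

from .core import CTVolume, FormatError, PhantomSpec

__all__ = [
    "PhantomStats",
    "CalibrationModel",
    "extract_phantom_stats",
    "fit_calibration",
    "voxel_weight",
    "apply_hu_recalibration",
    "AGATSTON_THRESHOLD_HU",
    "WEIGHT_FLOOR",
]

logger = logging.getLogger(__name__)

#: Conventional lesion detection threshold anchoring the default criterion.
AGATSTON_THRESHOLD_HU = 130.0

#: Numerical floor on the voxel weight.  Phi underflows to exactly 0 in
#: float64 around z = -38, which would make an all-air region score 0; the
#: floor keeps every finite-HU weight (and its square, which the neighbour
#: adjustment can produce) strictly positive in double precision.
WEIGHT_FLOOR = 1e-150


@dataclass
class PhantomStats:
    """Per-insert attenuation statistics (sample mean/SD, n-1 denominator)."""

    densities: np.ndarray  # mg/mL
    mean_hu: np.ndarray
    sd_hu: np.ndarray
    n_voxels: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.mean_hu = np.asarray(self.mean_hu, dtype=float)
        self.sd_hu = np.asarray(self.sd_hu, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        n = len(self.densities)
        if not (len(self.mean_hu) == len(self.sd_hu) == len(self.n_voxels) == n):
            raise FormatError("phantom stats arrays must have equal length")
        if np.any(self.sd_hu < 0) or np.any(self.n_voxels < 8):
            raise FormatError("phantom stats need sd >= 0 and >= 8 voxels per insert")


@dataclass
class CalibrationModel:
    """Fitted density->attenuation calibration for one scan.

    ``mu_c`` and ``sigma_c`` are the mean/SD lines evaluated at the criterion
    density (``sigma_c`` clamped at ``sigma_floor``); they fully determine
    the voxel-weighting function.
    """

    mean_intercept: float  # a_mu, HU
    mean_slope: float  # b_mu, HU per mg/mL
    sd_intercept: float  # a_sigma, HU
    sd_slope: float  # b_sigma, HU per mg/mL
    criterion_density: float  # c, mg/mL
    sigma_floor: float
    mu_c: float
    sigma_c: float
    mean_residual_rms: float = 0.0
    sd_residual_rms: float = 0.0

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source: str) -> "CalibrationModel":
        try:
            raw = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                raw = json.load(fh)
        return cls(**raw)


def extract_phantom_stats(volume: CTVolume, phantom: PhantomSpec) -> PhantomStats:
    """Sample mean and SD of attenuation over each phantom insert region.

    Raises :class:`FormatError` when a region leaves the volume, holds fewer
    than 8 voxels, or overlaps another insert.
    """
    shape = np.asarray(volume.shape)
    densities, means, sds, counts = [], [], [], []
    seen: set[tuple[int, int, int]] = set()
    for ins in phantom.inserts:
        idx = ins.resolve_indices(volume)
        if len(idx) and (np.any(idx < 0) or np.any(idx >= shape)):
            raise FormatError(
                f"insert at {ins.density} mg/mL extends outside the volume"
            )
        if len(idx) < 8:
            raise FormatError(
                f"insert at {ins.density} mg/mL has {len(idx)} voxels (< 8)"
            )
        keys = set(map(tuple, idx))
        if seen & keys:
            raise FormatError("phantom insert regions overlap")
        seen |= keys
        hu = volume.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
        densities.append(ins.density)
        means.append(float(np.mean(hu)))
        sds.append(float(np.std(hu, ddof=1)))
        counts.append(len(idx))
    return PhantomStats(
        densities=np.array(densities),
        mean_hu=np.array(means),
        sd_hu=np.array(sds),
        n_voxels=np.array(counts),
    )


def fit_calibration(
    stats: PhantomStats,
    criterion_density: float | str = "auto",
    sigma_floor: float = 1.0,
) -> CalibrationModel:
    """OLS fit of mean HU and SD HU on insert density; evaluate at criterion.

    ``criterion_density="auto"`` picks the density whose fitted mean
    attenuation equals 130 HU, clipped to [0, max insert density].  A fitted
    sigma below ``sigma_floor`` is clamped (and logged) so noise-free
    synthetic phantoms do not degenerate to a step-function weight.
    """
    d = stats.densities
    if len(np.unique(d)) < 2:
        raise FormatError("calibration needs >= 2 distinct insert densities")
    if sigma_floor <= 0:
        raise FormatError("sigma_floor must be positive")
    b_mu, a_mu = np.polyfit(d, stats.mean_hu, 1)
    b_sd, a_sd = np.polyfit(d, stats.sd_hu, 1)
    if b_mu <= 0:
        raise FormatError(
            f"attenuation must increase with density (fitted slope {b_mu:.4g})"
        )
    if criterion_density == "auto":
        c = (AGATSTON_THRESHOLD_HU - a_mu) / b_mu
        c = float(np.clip(c, 0.0, d.max()))
    else:
        c = float(criterion_density)
        if not (0.0 <= c <= d.max()):
            raise FormatError(
                f"criterion density {c} outside phantom range [0, {d.max()}]"
            )
    mu_c = a_mu + b_mu * c
    sigma_c = a_sd + b_sd * c
    if sigma_c < sigma_floor:
        logger.warning(
            "fitted sigma at criterion density is %.3g HU; clamping to floor %.3g",
            sigma_c,
            sigma_floor,
        )
        sigma_c = sigma_floor
    mean_resid = stats.mean_hu - (a_mu + b_mu * d)
    sd_resid = stats.sd_hu - (a_sd + b_sd * d)
    return CalibrationModel(
        mean_intercept=float(a_mu),
        mean_slope=float(b_mu),
        sd_intercept=float(a_sd),
        sd_slope=float(b_sd),
        criterion_density=c,
        sigma_floor=float(sigma_floor),
        mu_c=float(mu_c),
        sigma_c=float(sigma_c),
        mean_residual_rms=float(np.sqrt(np.mean(mean_resid**2))),
        sd_residual_rms=float(np.sqrt(np.mean(sd_resid**2))),
    )


def voxel_weight(hu, model: CalibrationModel):
    """Normal-CDF weight Phi((hu - mu_c)/sigma_c), floored away from zero.

    Accepts scalars or arrays; strictly increasing in HU over the CT range
    and in (0, 1) for finite input.
    """
    z = (np.asarray(hu, dtype=float) - model.mu_c) / model.sigma_c
    w = ndtr(z)
    w = np.clip(w, WEIGHT_FLOOR, 1.0 - np.finfo(float).epsneg)
    if np.ndim(hu) == 0:
        return float(w)
    return w


def apply_hu_recalibration(
    volume: CTVolume,
    model: CalibrationModel,
    nominal_intercept: float = 0.0,
    nominal_slope: float = 1.0,
) -> CTVolume:
    """Affine HU recalibration mapping the fitted phantom line onto a nominal
    density->HU line (optional pre-processing; off by default in scoring).

    A voxel at observed HU is assigned the attenuation the nominal line gives
    at its phantom-implied density: hu' = n_a + n_b * (hu - a_mu) / b_mu.
    """
    implied_density = (volume.voxels - model.mean_intercept) / model.mean_slope
    return CTVolume(
        voxels=nominal_intercept + nominal_slope * implied_density,
        spacing=volume.spacing,
        origin=volume.origin,
        scan_id=volume.scan_id,
        participant_id=volume.participant_id,
    )
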