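"""Shared fixtures and independent reference implementations (oracles).

The oracles deliberately re-derive each quantity by the most naive route
possible — per-voxel distance scans, breadth-first flood fill, explicit
double loops — so they share no code path with the library implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cacscore import ArteryTrajectory, CTVolume
from cacscore.calibration import CalibrationModel, voxel_weight

# --------------------------------------------------------------------------
# fixtures


def make_model(mu_c=130.0, sigma_c=10.0, criterion_density=100.0):
    """A calibration model with directly specified weighting parameters."""
    return CalibrationModel(
        mean_intercept=10.0,
        mean_slope=1.2,
        sd_intercept=sigma_c,
        sd_slope=0.0,
        criterion_density=criterion_density,
        sigma_floor=1.0,
        mu_c=mu_c,
        sigma_c=sigma_c,
    )


@pytest.fixture
def model():
    return make_model()


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


def make_volume(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), **kw):
    return CTVolume(voxels=np.asarray(voxels, dtype=float), spacing=spacing,
                    origin=origin, **kw)


def straight_trajectory(start, end, radius=8.0, name="artery"):
    return ArteryTrajectory(
        name=name, points=np.array([start, end], dtype=float), search_radius=radius
    )


# --------------------------------------------------------------------------
# oracles


def point_segment_distance(p, a, b):
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    t = float(np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0))
    return float(np.linalg.norm(a + t * ab - p))


def roi_oracle(volume: CTVolume, trajectories) -> np.ndarray:
    """Brute-force all-voxel distance scan."""
    mask = np.zeros(volume.shape, dtype=bool)
    sp = np.asarray(volume.spacing)
    org = np.asarray(volume.origin)
    for idx in np.ndindex(volume.shape):
        p = org + np.asarray(idx) * sp
        for t in trajectories:
            d = min(
                point_segment_distance(p, t.points[s], t.points[s + 1])
                for s in range(len(t.points) - 1)
            )
            if d <= t.search_radius:
                mask[idx] = True
                break
    return mask


def neighbor_offsets(connectivity: int):
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(di) + abs(dj) + abs(dk) != 1:
                    continue
                offs.append((di, dj, dk))
    return offs


def flood_fill_components(mask: np.ndarray, connectivity: int):
    """Breadth-first connected components of a boolean mask."""
    offs = neighbor_offsets(connectivity)
    seen = np.zeros(mask.shape, dtype=bool)
    components = []
    for start in np.ndindex(mask.shape):
        if not mask[start] or seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            cur = queue.pop()
            comp.append(cur)
            for off in offs:
                nxt = tuple(int(c + o) for c, o in zip(cur, off))
                if any(not 0 <= nxt[a] < mask.shape[a] for a in range(3)):
                    continue
                if mask[nxt] and not seen[nxt]:
                    seen[nxt] = True
                    queue.append(nxt)
        components.append(frozenset(comp))
    return components


def swcs_oracle(volume: CTVolume, roi, model, neighborhood=26, kappa=1.0):
    """Naive double loop over voxels and their truncated neighbourhoods."""
    shape = volume.shape
    w = np.zeros(shape)
    for idx in np.ndindex(shape):
        if roi[idx]:
            w[idx] = voxel_weight(float(volume.voxels[idx]), model)
    offs = [(0, 0, 0)] + neighbor_offsets(neighborhood)
    total = 0.0
    for idx in np.ndindex(shape):
        if not roi[idx]:
            continue
        vals = []
        for off in offs:
            nxt = tuple(int(c + o) for c, o in zip(idx, off))
            if all(0 <= nxt[a] < shape[a] for a in range(3)):
                vals.append(w[nxt])
        total += w[idx] * (sum(vals) / len(vals))
    return kappa * total * volume.voxel_volume


def icc_oracle(pairs, variant="icc1"):
    """Independent ICC via pingouin's ANOVA-table implementation."""
    import pandas as pd
    import pingouin as pg

    pairs = np.asarray(pairs, dtype=float)
    n = len(pairs)
    df = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), 2),
            "rater": np.tile(["scan1", "scan2"], n),
            "score": pairs.ravel(),
        }
    )
    table = pg.intraclass_corr(df, targets="target", raters="rater", ratings="score")
    key = {"icc1": "ICC(1,1)", "icc2": "ICC(A,1)"}[variant]
    return float(table.set_index("Type").loc[key, "ICC"])
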