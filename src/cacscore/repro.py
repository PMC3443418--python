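"""Test-retest reproducibility statistics for paired replicate scans.

The primary reproducibility measure is the percent difference between a
participant's two scan scores,

    pd(x1, x2) = |x1 - x2| / ((x1 + x2)/2) * 100,

which is symmetric, scale-invariant and bounded in [0, 200]; it is
undefined when both scores are zero (such participants are excluded and
counted).  Reproducibility of the two scoring methods is compared on the
*same* participants via the per-participant paired difference
(AS percent difference minus SWCS percent difference), summarised by its
median and mean with seeded bootstrap percentile confidence intervals.

The intraclass correlation coefficient defaults to the one-way
random-effects form ICC(1,1) — scan order within a participant is
exchangeable under a randomised reading protocol — with the two-way random
absolute-agreement form ICC(2,1) available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import FormatError, ScoreResult

__all__ = [
    "percent_difference",
    "icc",
    "ReproSummary",
    "pair_scores",
    "reproducibility_table",
]


def percent_difference(x1: float, x2: float) -> float:
    """Absolute difference between replicate scores relative to their mean,
    in percent.  Undefined (ValueError) when x1 + x2 = 0."""
    if x1 < 0 or x2 < 0:
        raise FormatError("scores must be non-negative")
    s = x1 + x2
    if s == 0:
        raise FormatError("percent difference undefined when both scores are 0")
    return abs(x1 - x2) / (s / 2.0) * 100.0


def icc(pairs: Iterable[tuple[float, float]], variant: str = "icc1") -> float:
    """Intraclass correlation coefficient for paired measurements (k = 2).

    ``variant="icc1"``: one-way random effects, (MSB - MSW)/(MSB + MSW).
    ``variant="icc2"``: two-way random effects, absolute agreement.
    Degenerate data (no between-participant variance) raise FormatError.
    """
    x = np.asarray(list(pairs), dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise FormatError("pairs must be an (n, 2) array-like")
    n = len(x)
    if n < 3:
        raise FormatError("ICC needs at least 3 pairs")
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - row_means[:, None]) ** 2) / (n * (k - 1))
    if variant == "icc1":
        denom = msb + (k - 1) * msw
        if denom == 0:
            raise FormatError("ICC undefined: no variance in the data")
        return float((msb - msw) / denom)
    if variant == "icc2":
        col_means = x.mean(axis=0)
        msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
        sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
        mse = sse / ((n - 1) * (k - 1))
        denom = msb + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            raise FormatError("ICC undefined: no variance in the data")
        return float((msb - mse) / denom)
    raise FormatError(f"unknown ICC variant {variant!r}")


@dataclass
class ReproSummary:
    """Reproducibility comparison of SWCS and AS on one participant subset."""

    subset: str
    n: int
    n_excluded_as: int  # AS percent difference undefined (both scans 0)
    n_excluded_swcs: int
    median_pct_swcs: float
    mean_pct_swcs: float
    median_pct_as: float
    mean_pct_as: float
    median_paired_diff: float  # AS% - SWCS%, per participant
    mean_paired_diff: float
    median_paired_ci: tuple[float, float]
    mean_paired_ci: tuple[float, float]
    icc_swcs: float
    icc_as: float

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["median_paired_ci_lo"], d["median_paired_ci_hi"] = d.pop("median_paired_ci")
        d["mean_paired_ci_lo"], d["mean_paired_ci_hi"] = d.pop("mean_paired_ci")
        return d


def pair_scores(scores: pd.DataFrame | Sequence[ScoreResult]) -> pd.DataFrame:
    """Pivot a long score table (2 rows per participant) into one row per
    participant with as1/as2/swcs1/swcs2 columns; participants without
    exactly two scans are dropped."""
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame(
            [
                {
                    "scan_id": r.scan_id,
                    "participant_id": r.participant_id,
                    "agatston": r.agatston,
                    "swcs": r.swcs,
                }
                for r in scores
            ]
        )
    rows = []
    for pid, grp in scores.sort_values("scan_id").groupby("participant_id"):
        if len(grp) != 2:
            continue
        rows.append(
            {
                "participant_id": pid,
                "as1": grp["agatston"].iloc[0],
                "as2": grp["agatston"].iloc[1],
                "swcs1": grp["swcs"].iloc[0],
                "swcs2": grp["swcs"].iloc[1],
            }
        )
    if not rows:
        raise FormatError("no participants with paired scans")
    return pd.DataFrame(rows)


def _apply_subset(paired: pd.DataFrame, subset: str, max_as: float | None) -> pd.DataFrame:
    if subset == "either":
        out = paired[(paired.as1 > 0) | (paired.as2 > 0)]
    elif subset == "both":
        out = paired[(paired.as1 > 0) & (paired.as2 > 0)]
    elif subset == "all":
        out = paired
    else:
        raise FormatError(f"subset must be 'either', 'both' or 'all', got {subset!r}")
    if max_as is not None:
        out = out[(out.as1 < max_as) & (out.as2 < max_as)]
    if len(out) == 0:
        raise FormatError(f"subset {subset!r} is empty after filtering")
    return out


def reproducibility_table(
    scores: pd.DataFrame | Sequence[ScoreResult],
    subset: str = "either",
    max_as: float | None = None,
    n_bootstrap: int = 2000,
    seed: int = 0,
    exclude_participants: Sequence[str] = (),
) -> ReproSummary:
    """Reproducibility summary on a participant subset.

    ``subset`` filters on the Agatston score: ``"either"`` keeps participants
    with AS > 0 on at least one scan, ``"both"`` requires AS > 0 on both,
    ``"all"`` keeps everyone; ``max_as`` further restricts to AS < max_as on
    both scans (the low-score strata).  ``exclude_participants`` stands in
    for reader-flagged unacceptable-noise scans.

    Percent differences for the two methods and the per-participant paired
    difference (AS% - SWCS%) are computed on identical participant sets;
    participants with an undefined percent difference for either method are
    excluded from the paired comparison and counted.  Confidence intervals
    are 95% bootstrap percentile intervals resampling participants.
    """
    paired = pair_scores(scores)
    if exclude_participants:
        paired = paired[~paired.participant_id.isin(set(exclude_participants))]
    sub = _apply_subset(paired, subset, max_as)

    def _pct(a, b):
        with np.errstate(invalid="ignore", divide="ignore"):
            s = a + b
            out = np.where(s > 0, np.abs(a - b) / (s / 2.0) * 100.0, np.nan)
        return out

    pct_as = _pct(sub.as1.to_numpy(), sub.as2.to_numpy())
    pct_swcs = _pct(sub.swcs1.to_numpy(), sub.swcs2.to_numpy())
    defined = ~np.isnan(pct_as) & ~np.isnan(pct_swcs)
    n_excl_as = int(np.isnan(pct_as).sum())
    n_excl_swcs = int(np.isnan(pct_swcs).sum())
    pct_as, pct_swcs = pct_as[defined], pct_swcs[defined]
    if len(pct_as) == 0:
        raise FormatError("no participant has defined percent differences")
    diff = pct_as - pct_swcs

    rng = np.random.default_rng(seed)
    n = len(diff)
    boot_med = np.empty(n_bootstrap)
    boot_mean = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        take = rng.integers(0, n, size=n)
        boot_med[b] = np.median(diff[take])
        boot_mean[b] = np.mean(diff[take])
    med_ci = tuple(np.percentile(boot_med, [2.5, 97.5]))
    mean_ci = tuple(np.percentile(boot_mean, [2.5, 97.5]))

    d = sub[defined]
    return ReproSummary(
        subset=subset if max_as is None else f"{subset}-lt:{max_as:g}",
        n=int(n),
        n_excluded_as=n_excl_as,
        n_excluded_swcs=n_excl_swcs,
        median_pct_swcs=float(np.median(pct_swcs)),
        mean_pct_swcs=float(np.mean(pct_swcs)),
        median_pct_as=float(np.median(pct_as)),
        mean_pct_as=float(np.mean(pct_as)),
        median_paired_diff=float(np.median(diff)),
        mean_paired_diff=float(np.mean(diff)),
        median_paired_ci=(float(med_ci[0]), float(med_ci[1])),
        mean_paired_ci=(float(mean_ci[0]), float(mean_ci[1])),
        icc_swcs=icc(zip(d.swcs1, d.swcs2)),
        icc_as=icc(zip(d.as1, d.as2)),
    )
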