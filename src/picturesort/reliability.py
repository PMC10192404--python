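"""Test-retest reliability: Bland-Altman agreement analysis.

For each retained index, paired baseline/follow-up values give per-subject
differences (follow-up minus baseline by default) and means.  The limits
of agreement are ``mean difference +/- 1.96 x SD(difference)`` (SD with
the n-1 denominator); the repeatability coefficient is the half-width
``1.96 x SD(difference)``; and the percentage of differences inside the
closed interval between the limits is reported (about 95% is expected for
normally distributed differences).

The reliability coefficient partitions variance: the within-person
variance is estimated as ``SD(difference)^2 / 2`` (each difference is the
sum of two independent occasion errors) and compared with the total
variance of the pooled two-timepoint values:

    R = 1 - sigma_w^2 / sigma_total^2,  floored at 0.

R is the fraction of observed variance attributable to stable
between-person differences (an intraclass-type coefficient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

Z_LIMITS = 1.96

DiffSign = Literal["followup_minus_baseline", "baseline_minus_followup"]


class ReliabilityError(ValueError):
    pass


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    n_excluded: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    repeatability: float
    pct_within: float
    reliability_coefficient: float  # NaN when total variance is 0
    diff_sign: str = "followup_minus_baseline"


@dataclass(frozen=True)
class BlandAltmanPlotData:
    """Per-subject points plus the three reference lines of the plot."""

    points: pd.DataFrame  # columns: subject_id, mean, difference
    lines: dict  # mean_diff, loa_lower, loa_upper


def _paired(baseline: pd.Series, followup: pd.Series):
    b = pd.Series(baseline, dtype=float)
    f = pd.Series(followup, dtype=float)
    common = b.index.intersection(f.index)
    b, f = b.loc[common], f.loc[common]
    ok = b.notna() & f.notna()
    n_excluded = (
        len(set(baseline.index).union(followup.index)) - int(ok.sum())
    )
    return b[ok], f[ok], n_excluded


def bland_altman(
    baseline: pd.Series,
    followup: pd.Series,
    diff_sign: DiffSign = "followup_minus_baseline",
) -> BlandAltmanResult:
    """Bland-Altman agreement between two timepoints, paired by index.

    Subjects missing either timepoint are excluded (count reported); at
    least 3 complete pairs are required.
    """
    b, f, n_excluded = _paired(baseline, followup)
    n = len(b)
    if n < 3:
        raise ReliabilityError(f"need >=3 complete pairs, got {n}")
    if diff_sign == "followup_minus_baseline":
        diffs = (f - b).to_numpy()
    elif diff_sign == "baseline_minus_followup":
        diffs = (b - f).to_numpy()
    else:
        raise ReliabilityError(f"unknown diff_sign {diff_sign!r}")
    mean_diff = float(diffs.mean())
    sd_diff = float(np.std(diffs, ddof=1))
    loa_lower = mean_diff - Z_LIMITS * sd_diff
    loa_upper = mean_diff + Z_LIMITS * sd_diff
    within = (diffs >= loa_lower) & (diffs <= loa_upper)  # closed interval
    pooled = np.concatenate([b.to_numpy(), f.to_numpy()])
    total_var = float(np.var(pooled, ddof=1))
    if total_var > 0:
        rc = max(0.0, 1.0 - (sd_diff**2 / 2.0) / total_var)
    else:
        rc = math.nan
    return BlandAltmanResult(
        n=n,
        n_excluded=n_excluded,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=loa_lower,
        loa_upper=loa_upper,
        repeatability=Z_LIMITS * sd_diff,
        pct_within=100.0 * within.mean(),
        reliability_coefficient=rc,
        diff_sign=diff_sign,
    )


def reliability_coefficient(baseline: pd.Series, followup: pd.Series) -> float:
    """1 - sigma_w^2 / sigma_total^2 with sigma_w^2 = SD(diff)^2 / 2.

    Errors when the pooled two-timepoint variance is zero.
    """
    res = bland_altman(baseline, followup)
    if math.isnan(res.reliability_coefficient):
        raise ReliabilityError("zero total variance: coefficient undefined")
    return res.reliability_coefficient


def export_bland_altman_plotdata(
    result: BlandAltmanResult,
    baseline: pd.Series,
    followup: pd.Series,
) -> BlandAltmanPlotData:
    """Plot-ready table: per-subject (mean, difference) rows and the
    mean-difference / limits-of-agreement reference lines."""
    b, f, _ = _paired(baseline, followup)
    if len(b) == 0:
        raise ReliabilityError("no complete pairs to plot")
    if result.diff_sign == "followup_minus_baseline":
        diffs = f - b
    else:
        diffs = b - f
    points = pd.DataFrame(
        {
            "subject_id": b.index,
            "mean": ((b + f) / 2.0).to_numpy(),
            "difference": diffs.to_numpy(),
        }
    )
    lines = {
        "mean_diff": result.mean_diff,
        "loa_lower": result.loa_lower,
        "loa_upper": result.loa_upper,
    }
    return BlandAltmanPlotData(points=points, lines=lines)


__all__ = [
    "Z_LIMITS",
    "BlandAltmanPlotData",
    "BlandAltmanResult",
    "ReliabilityError",
    "bland_altman",
    "export_bland_altman_plotdata",
    "reliability_coefficient",
]
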