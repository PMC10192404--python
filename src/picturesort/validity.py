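"""Convergent validity: Pearson correlations and the retention rule.

Each picture-sort healthy-eating index is correlated (pairwise-complete
Pearson, two-sided p from the t transform with n-2 df) against the
cohort's reference measures: in children the 5-item self-efficacy for
eating F&V; in adults the abbreviated-FFQ F&V servings (expected positive
sign) and the obesogenic dietary index (expected negative sign).

An index is *retained* for the reliability stage iff it is significantly
correlated (p <= 0.1, strict "p > 0.1 not retained" boundary) with at
least one of its cohort's references, with the correlation in the
expected direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Default retention p-value threshold.
RETENTION_P = 0.1


class ValidityError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class RetentionDecision:
    index: str
    reference: str
    expected_sign: str  # '+' or '-'
    retained: bool
    reason: str


def pearson_with_p(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Pearson r with two-sided p, pairwise-complete.

    p comes from t = r * sqrt((n-2) / (1-r^2)) against t(n-2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidityError("x and y must have the same length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValidityError(f"need >=3 complete pairs, got {n}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidityError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(var_x, var_y, float(res.statistic),
                             float(res.pvalue), int(n))


def significance_flag(p: float) -> str:
    """Footnote flag at the report's significance levels."""
    if p < 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "+"
    return ""


def convergent_validity_matrix(
    index_table: pd.DataFrame,
    reference_table: pd.DataFrame,
) -> pd.DataFrame:
    """All index x reference correlations, pairwise-complete, long format.

    Both tables are wide, indexed (or keyed by a subject_id column) by
    subject; every numeric column of ``index_table`` is correlated with
    every numeric column of ``reference_table``.
    """
    ix = _subject_indexed(index_table)
    ref = _subject_indexed(reference_table)
    common = ix.index.intersection(ref.index)
    if common.empty:
        raise ValidityError("no overlapping subjects between tables")
    ix, ref = ix.loc[common], ref.loc[common]
    rows = []
    for xcol in ix.columns:
        for ycol in ref.columns:
            res = pearson_with_p(ix[xcol], ref[ycol], xcol, ycol)
            rows.append(
                {
                    "var_x": res.var_x,
                    "var_y": res.var_y,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                    "flag": significance_flag(res.p),
                }
            )
    return pd.DataFrame(rows, columns=["var_x", "var_y", "r", "p", "n", "flag"])


def _subject_indexed(table: pd.DataFrame) -> pd.DataFrame:
    if "subject_id" in table.columns:
        table = table.set_index("subject_id")
    return table.select_dtypes(include=[np.number])


def retention_filter(
    results: pd.DataFrame,
    reference_spec: Mapping[str, str],
    indices: Optional[Sequence[str]] = None,
    p_threshold: float = RETENTION_P,
) -> list[RetentionDecision]:
    """Apply the retention rule to a correlation table.

    ``reference_spec`` maps reference-measure column names to expected
    signs ('+'/'-'); an index is retained if, for at least one reference,
    p <= p_threshold and sign(r) matches.  One decision per index per
    reference is returned (plus the rule that any pass retains the index
    is easily recovered with :func:`retained_indices`).
    """
    for ref, sign in reference_spec.items():
        if sign not in ("+", "-"):
            raise ValidityError(f"expected_sign for {ref!r} must be '+' or '-'")
        if ref not in set(results["var_y"]):
            raise ValidityError(f"unknown reference {ref!r} not in results")
    if indices is None:
        indices = list(dict.fromkeys(results["var_x"]))
    decisions = []
    for index in indices:
        for ref, sign in reference_spec.items():
            row = results[(results["var_x"] == index) & (results["var_y"] == ref)]
            if row.empty:
                raise ValidityError(f"no correlation for ({index!r}, {ref!r})")
            r, p = float(row.iloc[0]["r"]), float(row.iloc[0]["p"])
            sign_ok = (r > 0) if sign == "+" else (r < 0)
            sig_ok = p <= p_threshold
            retained = sig_ok and sign_ok
            if retained:
                reason = f"r={r:.2f}, p={p:.3g} <= {p_threshold} with expected sign"
            elif not sig_ok:
                reason = f"p={p:.3g} > {p_threshold}"
            else:
                reason = f"sign of r={r:.2f} opposite to expected {sign}"
            decisions.append(RetentionDecision(index, ref, sign, retained, reason))
    return decisions


def retained_indices(decisions: Sequence[RetentionDecision]) -> list[str]:
    """Indices retained against at least one reference, in first-seen order."""
    out: list[str] = []
    for d in decisions:
        if d.retained and d.index not in out:
            out.append(d.index)
    return out


def decisions_frame(decisions: Sequence[RetentionDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "index": d.index,
                "reference": d.reference,
                "expected_sign": d.expected_sign,
                "retained": d.retained,
                "reason": d.reason,
            }
            for d in decisions
        ]
    )


__all__ = [
    "RETENTION_P",
    "CorrelationResult",
    "RetentionDecision",
    "ValidityError",
    "convergent_validity_matrix",
    "decisions_frame",
    "pearson_with_p",
    "retained_indices",
    "retention_filter",
    "significance_flag",
]
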