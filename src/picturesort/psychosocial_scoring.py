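"""Child psychosocial scales: scoring, rescaling and internal consistency.

Two constructs are measured on 4-point Likert items (1-4, no neutral
midpoint): the tendency to choose fruits and vegetables (F&V) when
eating, and self-efficacy for eating / bringing / cooking F&V.  Scale
scores are arithmetic means of answered items, optionally restricted to a
fruit or vegetable subscale, and can be rescaled to [0, 1] as
(mean - min) / (max - min) so that scales with different theoretical
ranges can be compared via the coefficient of variation.

Internal consistency uses Cronbach's alpha

    alpha = k/(k-1) * (1 - sum(var_i) / var_total)

with sample (n-1) variances on complete cases.  A single item is removed
from a scale when deleting it improves alpha by more than 30% *relative*
to the baseline value (``(alpha_after - alpha) / alpha > 0.30``); at most
one item is ever removed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Relative-improvement threshold for single-item removal.
REMOVAL_THRESHOLD = 0.30

LIKERT_MIN = 1
LIKERT_MAX = 4


class ScaleError(ValueError):
    pass


@dataclass(frozen=True)
class ScaleDefinition:
    """An ordered item set with optional fruit/vegetable subscale tags."""

    scale_id: str
    item_ids: tuple[str, ...]
    subscales: Mapping[str, str] = field(default_factory=dict)
    likert_min: int = LIKERT_MIN
    likert_max: int = LIKERT_MAX

    def __post_init__(self) -> None:
        if len(self.item_ids) < 2:
            raise ScaleError(f"scale {self.scale_id!r} needs >=2 items")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ScaleError(f"scale {self.scale_id!r} has duplicate items")
        n_options = self.likert_max - self.likert_min + 1
        if n_options % 2 == 1:
            raise ScaleError(
                f"scale {self.scale_id!r}: response options must exclude a "
                "neutral midpoint (even number of options)"
            )

    def items_for(self, subscale: Optional[str]) -> tuple[str, ...]:
        if subscale is None:
            return self.item_ids
        return tuple(i for i in self.item_ids if self.subscales.get(i) == subscale)


@dataclass(frozen=True)
class ScaleScore:
    """Mean score for one subject on one scale (or subscale)."""

    scale_id: str
    mean_score: float  # NaN when nothing answered
    rescaled: float
    n_items_answered: int
    subject_id: Optional[str] = None
    timepoint: Optional[str] = None

    @property
    def missing(self) -> bool:
        return math.isnan(self.mean_score)


@dataclass(frozen=True)
class AlphaReport:
    """Cronbach alpha with alpha-if-deleted and the removal decision."""

    scale_id: str
    alpha: float
    loo_alphas: Mapping[str, float]
    removed_item: Optional[str]
    alpha_after: Optional[float]
    n_subjects: int
    flagged_nonpositive_baseline: bool = False


def default_scales() -> dict[str, ScaleDefinition]:
    """Packaged scale definitions (tendency-to-choose; 5- and 8-item
    self-efficacy and their fruit/vegetable subscales)."""
    from .food_registry import _data_path

    with _data_path("scales.json").open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return _scales_from_payload(raw)


def load_scales(path: str | Path) -> dict[str, ScaleDefinition]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return _scales_from_payload(raw)


def _scales_from_payload(raw: Mapping) -> dict[str, ScaleDefinition]:
    out = {}
    for spec in raw["scales"]:
        sd = ScaleDefinition(
            scale_id=spec["scale_id"],
            item_ids=tuple(spec["item_ids"]),
            subscales=dict(spec.get("subscales", {})),
            likert_min=int(spec.get("likert_min", LIKERT_MIN)),
            likert_max=int(spec.get("likert_max", LIKERT_MAX)),
        )
        out[sd.scale_id] = sd
    return out


# ---------------------------------------------------------------------------
# Scale means

def rescale(value: float, likert_min: float = LIKERT_MIN,
            likert_max: float = LIKERT_MAX) -> float:
    """Affine map of a scale value onto [0, 1]: (x - min) / range."""
    return (value - likert_min) / (likert_max - likert_min)


def scale_mean(
    responses: Mapping[str, float],
    definition: ScaleDefinition,
    subscale: Optional[str] = None,
    subject_id: Optional[str] = None,
    timepoint: Optional[str] = None,
) -> ScaleScore:
    """Mean of answered items (optionally one subscale), with rescaling.

    Missing items are simply left out of the mean; with zero answered
    items the score is flagged missing (NaN), never fabricated.
    """
    items = definition.items_for(subscale)
    values = []
    for item in items:
        v = responses.get(item)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if not (definition.likert_min <= v <= definition.likert_max):
            raise ScaleError(
                f"response {v!r} for item {item!r} outside "
                f"[{definition.likert_min}, {definition.likert_max}]"
            )
        values.append(float(v))
    if not values:
        return ScaleScore(definition.scale_id, math.nan, math.nan, 0,
                          subject_id, timepoint)
    mean = float(np.mean(values))
    return ScaleScore(
        scale_id=definition.scale_id,
        mean_score=mean,
        rescaled=rescale(mean, definition.likert_min, definition.likert_max),
        n_items_answered=len(values),
        subject_id=subject_id,
        timepoint=timepoint,
    )


def score_scales(
    likert: pd.DataFrame,
    scales: Optional[Mapping[str, ScaleDefinition]] = None,
) -> pd.DataFrame:
    """Score every subject x timepoint on every scale.

    ``likert`` is long format with columns subject_id, timepoint, item_id,
    response (a scale_id column, if present, is ignored: items are looked
    up by item_id so overlapping scale definitions share responses).
    Returns a wide frame keyed by (subject_id, timepoint) with one
    mean-score column per scale plus ``<scale>__rescaled`` columns.
    """
    scales = scales or default_scales()
    wide = likert.pivot_table(
        index=["subject_id", "timepoint"],
        columns="item_id",
        values="response",
        aggfunc="first",
    )
    out = pd.DataFrame(index=wide.index)
    for scale_id, sd in scales.items():
        present = [i for i in sd.item_ids if i in wide.columns]
        if not present:
            out[scale_id] = np.nan
        else:
            out[scale_id] = wide[present].mean(axis=1)
        out[f"{scale_id}__rescaled"] = (out[scale_id] - sd.likert_min) / (
            sd.likert_max - sd.likert_min
        )
    return out.reset_index()


# ---------------------------------------------------------------------------
# Internal consistency

def _complete_case_matrix(item_matrix) -> np.ndarray:
    arr = np.asarray(item_matrix, dtype=float)
    if arr.ndim != 2:
        raise ScaleError("item matrix must be 2-D (subjects x items)")
    arr = arr[~np.isnan(arr).any(axis=1)]
    return arr


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of a subjects x items matrix (complete cases).

    alpha = k/(k-1) * (1 - sum(item variances) / variance of row totals),
    all variances with the n-1 denominator.
    """
    arr = _complete_case_matrix(item_matrix)
    n, k = arr.shape
    if k < 2:
        raise ScaleError("alpha requires >=2 items")
    if n < 3:
        raise ScaleError("alpha requires >=3 complete cases")
    total_var = np.var(arr.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ScaleError("degenerate scale: zero variance of total score")
    item_vars = np.var(arr, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_vars / total_var))


def removal_improves(alpha: float, alpha_after: float,
                     threshold: float = REMOVAL_THRESHOLD) -> bool:
    """Does deleting an item improve alpha by more than ``threshold``,
    relative to baseline?  With a non-positive baseline the relative
    change is taken against |alpha| (any improvement from alpha <= 0 to a
    positive value qualifies)."""
    if alpha > 0:
        return (alpha_after - alpha) / alpha > threshold
    if alpha == 0:
        return alpha_after > 0
    return (alpha_after - alpha) / abs(alpha) > threshold


def alpha_item_removal(
    item_matrix,
    item_ids: Optional[Sequence[str]] = None,
    scale_id: str = "scale",
    threshold: float = REMOVAL_THRESHOLD,
) -> AlphaReport:
    """Alpha-if-deleted for every item and the single-item removal decision.

    The candidate is the item whose deletion maximises alpha (ties broken
    by scale order); it is removed iff the relative improvement exceeds
    ``threshold``.  At most one item is removed.
    """
    arr = _complete_case_matrix(item_matrix)
    n, k = arr.shape
    if item_ids is None:
        item_ids = [f"item_{j}" for j in range(k)]
    if len(item_ids) != k:
        raise ScaleError("item_ids length must match matrix columns")
    base = cronbach_alpha(arr)
    loo: dict[str, float] = {}
    for j, item in enumerate(item_ids):
        sub = np.delete(arr, j, axis=1)
        if sub.shape[1] < 2:
            loo[item] = math.nan
            continue
        try:
            loo[item] = cronbach_alpha(sub)
        except ScaleError:
            loo[item] = math.nan
    finite = {i: a for i, a in loo.items() if not math.isnan(a)}
    removed = None
    alpha_after = None
    if finite:
        best_item = max(finite, key=lambda i: (finite[i], -item_ids.index(i)))
        # deterministic tie-break: first item in scale order among maxima
        best_val = finite[best_item]
        for i in item_ids:
            if i in finite and finite[i] == best_val:
                best_item = i
                break
        if removal_improves(base, best_val, threshold):
            removed, alpha_after = best_item, best_val
    return AlphaReport(
        scale_id=scale_id,
        alpha=base,
        loo_alphas=loo,
        removed_item=removed,
        alpha_after=alpha_after,
        n_subjects=n,
        flagged_nonpositive_baseline=base <= 0,
    )


def coefficient_of_variation(values) -> float:
    """SD/mean of (typically rescaled) scores; NaN-flagged when mean <= 0."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return math.nan
    mean = arr.mean()
    if mean <= 0:
        return math.nan
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return sd / float(mean)


__all__ = [
    "LIKERT_MAX",
    "LIKERT_MIN",
    "REMOVAL_THRESHOLD",
    "AlphaReport",
    "ScaleDefinition",
    "ScaleError",
    "ScaleScore",
    "alpha_item_removal",
    "coefficient_of_variation",
    "cronbach_alpha",
    "default_scales",
    "load_scales",
    "removal_improves",
    "rescale",
    "scale_mean",
    "score_scales",
]
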