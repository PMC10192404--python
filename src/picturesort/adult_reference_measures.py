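"""Adult reference measures: abbreviated-FFQ F&V servings and the
obesogenic dietary index.

The abbreviated food-frequency questionnaire asks 7 fruit-and-vegetable
questions; their already-converted daily servings are summed into total
F&V servings/day, *excluding French fries but including other potatoes*.
The obesogenic dietary index averages the weekly frequencies of eating
fast food, eating French fries, and drinking soda (any type).  Both serve
as the established reference measures against which the picture-sort
indices are validated in adults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

#: The 7 FFQ items; French fries are asked but excluded from the total.
FFQ_ITEMS: dict[str, dict] = {
    "ffq_juice": {"tag": "fruit", "included": True},
    "ffq_fruit": {"tag": "fruit", "included": True},
    "ffq_salad": {"tag": "vegetable", "included": True},
    "ffq_fries": {"tag": "vegetable", "included": False},
    "ffq_other_potatoes": {"tag": "vegetable", "included": True},
    "ffq_beans": {"tag": "vegetable", "included": True},
    "ffq_other_veg": {"tag": "vegetable", "included": True},
}

OBESOGENIC_ITEMS = ("fast_food", "french_fries", "soda")

#: Multipliers converting raw capture units to weekly frequency.
FREQUENCY_TO_WEEKLY = {"per_week": 1.0, "per_day": 7.0, "per_month": 7.0 / 30.0}


class ReferenceMeasureError(ValueError):
    pass


@dataclass(frozen=True)
class FfqResponse:
    """Per-item daily servings for one subject x timepoint."""

    subject_id: str
    timepoint: str
    daily_servings: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.daily_servings) - set(FFQ_ITEMS)
        if unknown:
            raise ReferenceMeasureError(f"unknown FFQ item(s): {sorted(unknown)}")
        for item, v in self.daily_servings.items():
            if v is not None and not math.isnan(v) and v < 0:
                raise ReferenceMeasureError(f"negative servings for {item!r}")


@dataclass(frozen=True)
class ObesogenicResponse:
    """Weekly frequencies of fast food, French fries and soda."""

    subject_id: str
    timepoint: str
    fast_food: float
    french_fries: float
    soda: float

    def __post_init__(self) -> None:
        for name in OBESOGENIC_ITEMS:
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v < 0:
                raise ReferenceMeasureError(f"negative weekly frequency {name!r}")


def ffq_fv_servings(resp: FfqResponse, tag: Optional[str] = None) -> float:
    """Total daily F&V servings, excluding French fries.

    ``tag`` ('fruit' | 'vegetable') restricts to a subscore.  All items
    missing -> NaN (missing flag), never zero.
    """
    total = 0.0
    answered_any = 0
    for item, meta in FFQ_ITEMS.items():
        v = resp.daily_servings.get(item)
        if v is None or math.isnan(v):
            continue
        answered_any += 1
        if not meta["included"]:
            continue
        if tag is not None and meta["tag"] != tag:
            continue
        total += float(v)
    return total if answered_any else math.nan


def obesogenic_index(resp: ObesogenicResponse) -> float:
    """Mean of the three weekly frequencies; missing if any item missing."""
    values = [getattr(resp, n) for n in OBESOGENIC_ITEMS]
    if any(v is None or math.isnan(v) for v in values):
        return math.nan
    return float(np.mean([float(v) for v in values]))


def to_weekly(value: float, unit: str = "per_week") -> float:
    """Convert a raw frequency capture to weekly frequency."""
    try:
        return value * FREQUENCY_TO_WEEKLY[unit]
    except KeyError:
        raise ReferenceMeasureError(
            f"unknown frequency unit {unit!r}; allowed: "
            f"{sorted(FREQUENCY_TO_WEEKLY)}"
        ) from None


# ---------------------------------------------------------------------------
# Long-table I/O (adult_survey.csv: subject_id,timepoint,measure,item_id,value)

ADULT_SURVEY_COLUMNS = ["subject_id", "timepoint", "measure", "item_id", "value"]


def load_adult_survey(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(ADULT_SURVEY_COLUMNS) - set(frame.columns)
    if missing:
        raise ReferenceMeasureError(
            f"{path}: missing columns {sorted(missing)}"
        )
    bad = set(frame["measure"].unique()) - {"ffq", "obesogenic"}
    if bad:
        raise ReferenceMeasureError(f"{path}: unknown measure(s) {sorted(bad)}")
    return frame


def score_adult_survey(survey: pd.DataFrame) -> pd.DataFrame:
    """Wide per-subject reference measures from the long survey table.

    Columns: ffq_fruits, ffq_vegetables, ffq_fv (servings/day) and
    obesogenic_index (weekly frequency), keyed by subject_id, timepoint.
    """
    ffq = survey[survey["measure"] == "ffq"].pivot_table(
        index=["subject_id", "timepoint"],
        columns="item_id", values="value", aggfunc="first",
    )
    obes = survey[survey["measure"] == "obesogenic"].pivot_table(
        index=["subject_id", "timepoint"],
        columns="item_id", values="value", aggfunc="first",
    )
    idx = ffq.index.union(obes.index)
    out = pd.DataFrame(index=idx)

    def _sum_items(tag: Optional[str]) -> pd.Series:
        cols = [
            i for i, m in FFQ_ITEMS.items()
            if m["included"] and (tag is None or m["tag"] == tag)
            and i in ffq.columns
        ]
        if not cols:
            return pd.Series(np.nan, index=idx)
        s = ffq[cols].sum(axis=1, min_count=1)
        return s.reindex(idx)

    out["ffq_fruits"] = _sum_items("fruit")
    out["ffq_vegetables"] = _sum_items("vegetable")
    out["ffq_fv"] = _sum_items(None)
    obes_cols = [c for c in OBESOGENIC_ITEMS if c in obes.columns]
    if len(obes_cols) == len(OBESOGENIC_ITEMS):
        out["obesogenic_index"] = obes[list(OBESOGENIC_ITEMS)].mean(axis=1).where(
            obes[list(OBESOGENIC_ITEMS)].notna().all(axis=1)
        ).reindex(idx)
    else:
        out["obesogenic_index"] = np.nan
    return out.reset_index()


__all__ = [
    "ADULT_SURVEY_COLUMNS",
    "FFQ_ITEMS",
    "FREQUENCY_TO_WEEKLY",
    "OBESOGENIC_ITEMS",
    "FfqResponse",
    "ObesogenicResponse",
    "ReferenceMeasureError",
    "ffq_fv_servings",
    "load_adult_survey",
    "obesogenic_index",
    "score_adult_survey",
    "to_weekly",
]
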