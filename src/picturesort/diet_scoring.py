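"""Healthy-eating indices from picture-sort frequency responses.

Ordinal frequency labels are first converted to servings/day (0 for
"never" up to 2 for "more than once per day").  Per-subject servings are
then summed into AHEI component totals with the instrument's exclusion
rules applied:

* potatoes never count as vegetables;
* fruit juice counts toward the SSB+juice component, not fruit;
* alcohol is excluded from the total food frequency;
* the healthy frequency sums the four health-positive food groups
  (fruit, vegetables, whole grains, nuts/legumes).

Each of the 6 modified-AHEI components is scored 0-10 by linear
interpolation against a :class:`ComponentStandard` (reverse components —
sugary drinks and red/processed meat — score 10 at zero intake).  The
derived indices are:

=========================  =========  =====================================
modified AHEI total        0-60       sum of the 6 component scores
healthy foods score        0-40       sum of the 4 healthy component scores
F&V score                  0-20       fruit score + vegetable score
ratio healthy-to-total     0-1        healthy freq / total freq
=========================  =========  =====================================

The ratio is intended to dampen per-subject over/under-reporting: a
subject who inflates every frequency inflates numerator and denominator
together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .food_registry import (
    AHEI_COMPONENTS,
    FoodRegistry,
    InstrumentDialect,
    default_dialects,
    default_registry,
)


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ComponentServings:
    """Daily-servings totals for one subject at one timepoint."""

    vegetables: float
    fruit_excl_juice: float
    whole_grains: float
    nuts_legumes: float
    ssb_juice: float
    red_processed_meat: float
    healthy_freq: float
    total_freq: float

    @property
    def fruit(self) -> float:
        # juice items carry ahei_component=ssb_juice, so the fruit component
        # already excludes juice
        return self.fruit_excl_juice

    @property
    def fv_excl_juice(self) -> float:
        return self.fruit_excl_juice + self.vegetables

    def __post_init__(self) -> None:
        for name in (
            "vegetables", "fruit_excl_juice", "whole_grains", "nuts_legumes",
            "ssb_juice", "red_processed_meat", "healthy_freq", "total_freq",
        ):
            if getattr(self, name) < 0:
                raise ScoringError(f"{name} must be non-negative")
        if self.healthy_freq > self.total_freq + 1e-9:
            raise ScoringError("healthy_freq cannot exceed total_freq")


@dataclass(frozen=True)
class ComponentStandard:
    """Linear 0-10 scoring rule for one AHEI component."""

    component: str
    direction: str  # positive | reverse
    zero_score_servings: float
    full_score_servings: float

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "reverse"):
            raise ScoringError(f"unknown direction {self.direction!r}")
        if self.zero_score_servings == self.full_score_servings:
            raise ScoringError("zero- and full-score servings must differ")


@dataclass(frozen=True)
class IndexScores:
    """All healthy-eating indices for one subject x timepoint."""

    modified_ahei_total: float
    healthy_foods_score: float
    fv_score: float
    fruit_score: float
    veg_score: float
    whole_grain_score: float
    nuts_legumes_score: float
    ssb_juice_score: float
    red_meat_score: float
    ratio_healthy_total: float  # NaN when total_freq == 0
    servings: ComponentServings


def default_standards() -> dict[str, ComponentStandard]:
    """Packaged modified-AHEI component standards (see standards.yaml)."""
    from .food_registry import _data_path

    with _data_path("standards.yaml").open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _standards_from_mapping(raw)


def load_standards(path: str | Path) -> dict[str, ComponentStandard]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _standards_from_mapping(raw)


def _standards_from_mapping(raw: Mapping) -> dict[str, ComponentStandard]:
    out = {}
    for comp in AHEI_COMPONENTS:
        if comp not in raw:
            raise ScoringError(f"standards file missing component {comp!r}")
        spec = raw[comp]
        out[comp] = ComponentStandard(
            component=comp,
            direction=spec["direction"],
            zero_score_servings=float(spec["zero_score_servings"]),
            full_score_servings=float(spec["full_score_servings"]),
        )
    return out


# ---------------------------------------------------------------------------
# Frequency conversion and component summation

def frequency_to_servings(response: str, dialect: InstrumentDialect) -> float:
    """Daily servings for one ordinal frequency label."""
    try:
        return float(dialect.servings_per_day[response])
    except KeyError:
        raise ScoringError(
            f"label {response!r} is not a category of the {dialect.name!r} "
            f"dialect (allowed: {list(dialect.categories)})"
        ) from None


def component_servings(
    records: pd.DataFrame,
    registry: FoodRegistry,
    dialect: InstrumentDialect,
    include_salad: bool = True,
) -> ComponentServings:
    """Sum one subject x timepoint's responses into component servings/day.

    ``records`` is a long frame with item_id and response columns, all rows
    from a single subject and timepoint.  ``include_salad=False`` drops
    salad items from the vegetable component (they still count in totals).
    """
    if records.empty:
        raise ScoringError("empty record set: nothing to score")
    if records["item_id"].duplicated().any():
        raise ScoringError("duplicate item_id in record set")
    totals = dict.fromkeys(AHEI_COMPONENTS, 0.0)
    healthy = 0.0
    total = 0.0
    for row in records.itertuples():
        item = registry.get(row.item_id)
        servings = frequency_to_servings(row.response, dialect)
        if not item.is_alcohol:
            total += servings
        component = item.ahei_component
        if component != "none":
            if component == "vegetables" and item.is_salad and not include_salad:
                pass
            else:
                totals[component] += servings
        if item.healthy:
            if not (item.is_salad and not include_salad):
                healthy += servings
    return ComponentServings(
        vegetables=totals["vegetables"],
        fruit_excl_juice=totals["fruit"],
        whole_grains=totals["whole_grains"],
        nuts_legumes=totals["nuts_legumes"],
        ssb_juice=totals["ssb_juice"],
        red_processed_meat=totals["red_processed_meat"],
        healthy_freq=healthy,
        total_freq=total,
    )


def score_component(servings: float, std: ComponentStandard) -> float:
    """Score one component 0-10 by clamped linear interpolation."""
    if servings < 0:
        raise ScoringError("servings must be non-negative")
    span = std.full_score_servings - std.zero_score_servings
    score = 10.0 * (servings - std.zero_score_servings) / span
    return float(min(10.0, max(0.0, score)))


_COMPONENT_FIELD = {
    "vegetables": "vegetables",
    "fruit": "fruit_excl_juice",
    "whole_grains": "whole_grains",
    "nuts_legumes": "nuts_legumes",
    "ssb_juice": "ssb_juice",
    "red_processed_meat": "red_processed_meat",
}


def compute_indices(
    cs: ComponentServings,
    standards: Optional[Mapping[str, ComponentStandard]] = None,
) -> IndexScores:
    """All healthy-eating indices from component servings."""
    standards = standards or default_standards()
    scores = {
        comp: score_component(getattr(cs, field), standards[comp])
        for comp, field in _COMPONENT_FIELD.items()
    }
    ratio = (
        cs.healthy_freq / cs.total_freq if cs.total_freq > 0 else math.nan
    )
    healthy_score = (
        scores["fruit"] + scores["vegetables"] + scores["whole_grains"]
        + scores["nuts_legumes"]
    )
    return IndexScores(
        modified_ahei_total=sum(scores.values()),
        healthy_foods_score=healthy_score,
        fv_score=scores["fruit"] + scores["vegetables"],
        fruit_score=scores["fruit"],
        veg_score=scores["vegetables"],
        whole_grain_score=scores["whole_grains"],
        nuts_legumes_score=scores["nuts_legumes"],
        ssb_juice_score=scores["ssb_juice"],
        red_meat_score=scores["red_processed_meat"],
        ratio_healthy_total=ratio,
        servings=cs,
    )


# ---------------------------------------------------------------------------
# Vectorised cohort scoring

#: Index columns of the wide per-subject table, in report order.
INDEX_COLUMNS = [
    "fruit_score",
    "veg_score",
    "fv_score",
    "healthy_foods_score",
    "modified_ahei_total",
    "ratio_healthy_total",
]

SERVINGS_COLUMNS = [
    "vegetables",
    "fruit_excl_juice",
    "fv_excl_juice",
    "whole_grains",
    "nuts_legumes",
    "ssb_juice",
    "red_processed_meat",
    "healthy_freq",
    "total_freq",
]


def score_cohort(
    responses: pd.DataFrame,
    registry: Optional[FoodRegistry] = None,
    dialects: Optional[Mapping[str, InstrumentDialect]] = None,
    standards: Optional[Mapping[str, ComponentStandard]] = None,
    include_salad: bool = True,
) -> pd.DataFrame:
    """Score every subject x timepoint in a validated long response table.

    Returns a wide frame keyed by (subject_id, role, timepoint) with the
    servings columns and all index columns.  Equivalent to calling
    :func:`component_servings` + :func:`compute_indices` per subject, but
    vectorised for large synthetic cohorts.
    """
    registry = registry or default_registry()
    dialects = dialects or default_dialects()
    standards = standards or default_standards()

    reg = registry.to_frame().set_index("item_id")
    df = responses.merge(
        reg[["ahei_component", "healthy", "is_alcohol", "is_salad"]],
        left_on="item_id",
        right_index=True,
        how="left",
        validate="many_to_one",
    )
    if df["ahei_component"].isna().any():
        bad = sorted(df.loc[df["ahei_component"].isna(), "item_id"].unique())
        raise ScoringError(f"unknown item_id(s) in responses: {bad}")

    servings = np.empty(len(df), dtype=float)
    servings.fill(np.nan)
    for role, dialect in dialects.items():
        mask = (df["role"] == role).to_numpy()
        if mask.any():
            mapped = df.loc[mask, "response"].map(dialect.servings_per_day)
            if mapped.isna().any():
                bad = sorted(df.loc[mask, "response"][mapped.isna()].unique())
                raise ScoringError(
                    f"labels not in {role!r} dialect: {bad}"
                )
            servings[mask] = mapped.to_numpy(dtype=float)
    df = df.assign(servings=servings)

    veg_ok = (df["ahei_component"] == "vegetables") & (
        include_salad | ~df["is_salad"]
    )
    healthy_ok = df["healthy"] & (include_salad | ~df["is_salad"])
    contributions = pd.DataFrame(
        {
            "vegetables": df["servings"].where(veg_ok, 0.0),
            "fruit_excl_juice": df["servings"].where(
                df["ahei_component"] == "fruit", 0.0
            ),
            "whole_grains": df["servings"].where(
                df["ahei_component"] == "whole_grains", 0.0
            ),
            "nuts_legumes": df["servings"].where(
                df["ahei_component"] == "nuts_legumes", 0.0
            ),
            "ssb_juice": df["servings"].where(
                df["ahei_component"] == "ssb_juice", 0.0
            ),
            "red_processed_meat": df["servings"].where(
                df["ahei_component"] == "red_processed_meat", 0.0
            ),
            "healthy_freq": df["servings"].where(healthy_ok, 0.0),
            "total_freq": df["servings"].where(~df["is_alcohol"], 0.0),
        }
    )
    keys = df[["subject_id", "role", "timepoint"]]
    wide = (
        pd.concat([keys, contributions], axis=1)
        .groupby(["subject_id", "role", "timepoint"], sort=True)
        .sum()
        .reset_index()
    )
    wide["fv_excl_juice"] = wide["fruit_excl_juice"] + wide["vegetables"]

    def _score(col: str, comp: str) -> pd.Series:
        std = standards[comp]
        span = std.full_score_servings - std.zero_score_servings
        raw = 10.0 * (wide[col] - std.zero_score_servings) / span
        return raw.clip(0.0, 10.0)

    wide["fruit_score"] = _score("fruit_excl_juice", "fruit")
    wide["veg_score"] = _score("vegetables", "vegetables")
    wg = _score("whole_grains", "whole_grains")
    nl = _score("nuts_legumes", "nuts_legumes")
    ssb = _score("ssb_juice", "ssb_juice")
    meat = _score("red_processed_meat", "red_processed_meat")
    wide["fv_score"] = wide["fruit_score"] + wide["veg_score"]
    wide["healthy_foods_score"] = wide["fv_score"] + wg + nl
    wide["modified_ahei_total"] = wide["healthy_foods_score"] + ssb + meat
    wide["ratio_healthy_total"] = np.where(
        wide["total_freq"] > 0,
        wide["healthy_freq"] / wide["total_freq"].replace(0, np.nan),
        np.nan,
    )
    return wide[["subject_id", "role", "timepoint"] + SERVINGS_COLUMNS + INDEX_COLUMNS]


def write_indices(indices: pd.DataFrame, path: str | Path) -> None:
    indices.to_csv(path, index=False)


__all__ = [
    "INDEX_COLUMNS",
    "SERVINGS_COLUMNS",
    "ComponentServings",
    "ComponentStandard",
    "IndexScores",
    "ScoringError",
    "component_servings",
    "compute_indices",
    "default_standards",
    "frequency_to_servings",
    "load_standards",
    "score_cohort",
    "score_component",
    "write_indices",
]
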