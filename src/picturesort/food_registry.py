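"""Food-item registry, response dialects and tabular input validation.

The picture-sort instrument presents photograph cards of foods commonly
eaten in the contemporary Navajo diet, organised into 10 food groupings.
Each card (a :class:`FoodItem`) is mapped to at most one component of the
modified Alternative Healthy Eating Index (AHEI) and carries the exclusion
flags the scoring rules need (potatoes are not vegetables; fruit juice is
not fruit; alcohol is excluded from totals).

Respondents answer with an ordinal frequency label; children choose from
4 scored categories and adults from 5 (an :class:`InstrumentDialect`).
Long-format response tables are validated here before any scoring happens:
a record set that passes :func:`load_response_table` with no errors is
scoreable downstream without further checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd
import yaml

GROUPINGS: tuple[str, ...] = (
    "breads",
    "vegetables and salad",
    "fruits",
    "beverages",
    "soups or stews",
    "cereals",
    "dairy and eggs",
    "rice, pasta, etc.",
    "meat, chicken, or fish",
    "desserts and snacks",
)

AHEI_COMPONENTS: tuple[str, ...] = (
    "vegetables",
    "fruit",
    "whole_grains",
    "nuts_legumes",
    "ssb_juice",
    "red_processed_meat",
)

#: Components whose items count toward the healthy-foods frequency/score.
HEALTHY_COMPONENTS: frozenset[str] = frozenset(
    {"vegetables", "fruit", "whole_grains", "nuts_legumes"}
)

ROLES: tuple[str, ...] = ("child", "adult")
TIMEPOINTS: tuple[str, ...] = ("baseline", "followup")

RESPONSE_COLUMNS = ["subject_id", "role", "timepoint", "item_id", "response"]


class RegistryError(ValueError):
    """A registry file or item violates a structural rule."""


class ResponseTableError(ValueError):
    """A response table cannot be parsed at all (I/O / empty / bad header)."""


@dataclass(frozen=True)
class FoodItem:
    """One picture card: a food mapped to its grouping and AHEI role."""

    item_id: str
    label: str
    grouping: str
    ahei_component: str = "none"
    healthy: bool = False
    is_potato: bool = False
    is_fruit_juice: bool = False
    is_alcohol: bool = False
    is_salad: bool = False

    def __post_init__(self) -> None:
        if self.grouping not in GROUPINGS:
            raise RegistryError(
                f"item {self.item_id!r}: unknown grouping {self.grouping!r}; "
                f"allowed groupings are {list(GROUPINGS)}"
            )
        if self.ahei_component not in AHEI_COMPONENTS + ("none",):
            raise RegistryError(
                f"item {self.item_id!r}: unknown ahei_component "
                f"{self.ahei_component!r}"
            )
        if self.is_potato and self.ahei_component == "vegetables":
            raise RegistryError(
                f"item {self.item_id!r}: potatoes are excluded from the "
                "vegetable component regardless of preparation "
                "(set ahei_component to 'none')"
            )
        expected_healthy = self.ahei_component in HEALTHY_COMPONENTS
        if self.healthy != expected_healthy:
            raise RegistryError(
                f"item {self.item_id!r}: healthy must be {expected_healthy} "
                f"for ahei_component {self.ahei_component!r} (healthy food "
                "groups are fruit, vegetables, whole grains, nuts/legumes)"
            )


@dataclass(frozen=True)
class FoodRegistry:
    """Immutable collection of :class:`FoodItem` keyed by ``item_id``."""

    items: tuple[FoodItem, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for it in self.items:
            if it.item_id in seen:
                raise RegistryError(f"duplicate item_id {it.item_id!r}")
            seen.add(it.item_id)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self.items)

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    def get(self, item_id: str) -> FoodItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def groupings(self) -> set[str]:
        return {it.grouping for it in self.items}

    def ahei_components(self) -> set[str]:
        """Distinct AHEI components represented, excluding 'none'."""
        return {it.ahei_component for it in self.items} - {"none"}

    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def to_frame(self) -> pd.DataFrame:
        """Registry as a DataFrame (one row per item, scoring flags as columns)."""
        return pd.DataFrame([vars(it) for it in self.items])


@dataclass(frozen=True)
class InstrumentDialect:
    """Ordered frequency categories and their daily-servings values."""

    name: str
    categories: tuple[str, ...]
    servings_per_day: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.categories) != set(self.servings_per_day):
            raise ValueError(
                f"dialect {self.name!r}: categories and servings_per_day "
                "must cover the same labels"
            )
        vals = [self.servings_per_day[c] for c in self.categories]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError(
                f"dialect {self.name!r}: servings_per_day must be monotone "
                "in reported frequency"
            )
        if vals and (min(vals) < 0 or max(vals) > 2):
            raise ValueError(
                f"dialect {self.name!r}: servings values must lie in [0, 2]"
            )
        if self.name == "child" and len(self.categories) != 4:
            raise ValueError("child dialect must have exactly 4 categories")
        if self.name == "adult" and len(self.categories) != 5:
            raise ValueError("adult dialect must have exactly 5 categories")


@dataclass
class ValidationReport:
    """Errors and warnings accumulated while reading a response table."""

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add_error(self, locator: str, rule: str) -> None:
        self.errors.append((locator, rule))


# ---------------------------------------------------------------------------
# Packaged defaults

def _data_path(name: str):
    return resources.files("picturesort.data").joinpath(name)


def default_registry() -> FoodRegistry:
    """The packaged default registry.

    The study's actual card list is unpublished; this fixture covers all 10
    groupings (>=3 items each) and all 6 AHEI components, including potato,
    fruit-juice, sugar-sweetened-beverage, processed-meat and alcohol items,
    so every scoring rule is exercisable.  Override via
    :func:`load_food_registry`.
    """
    with _data_path("registry.json").open("r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return _registry_from_records(payload["items"], source="<packaged registry>")


def default_dialects() -> dict[str, InstrumentDialect]:
    """Packaged child (4-category) and adult (5-category) dialects."""
    with _data_path("dialects.yaml").open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return {
        name: InstrumentDialect(
            name=name,
            categories=tuple(spec["categories"]),
            servings_per_day=dict(spec["servings_per_day"]),
        )
        for name, spec in raw.items()
    }


def load_dialects(path: str | Path) -> dict[str, InstrumentDialect]:
    """Load dialects from a YAML file in the packaged format."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return {
        name: InstrumentDialect(
            name=name,
            categories=tuple(spec["categories"]),
            servings_per_day={k: float(v) for k, v in spec["servings_per_day"].items()},
        )
        for name, spec in raw.items()
    }


# ---------------------------------------------------------------------------
# Registry I/O

_BOOL_FIELDS = ("healthy", "is_potato", "is_fruit_juice", "is_alcohol", "is_salad")


def _coerce_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str):
        low = value.strip().lower()
        if low in {"true", "1", "yes"}:
            return True
        if low in {"false", "0", "no", ""}:
            return False
    raise RegistryError(f"cannot interpret {value!r} as a boolean flag")


def _registry_from_records(records: Iterable[Mapping], source: str) -> FoodRegistry:
    items: list[FoodItem] = []
    valid_fields = {f.name for f in fields(FoodItem)}
    for i, rec in enumerate(records):
        row = {k: v for k, v in dict(rec).items() if k in valid_fields}
        for b in _BOOL_FIELDS:
            if b in row and row[b] is not None and not (
                isinstance(row[b], float) and pd.isna(row[b])
            ):
                row[b] = _coerce_bool(row[b])
            else:
                row.pop(b, None)
        try:
            items.append(FoodItem(**row))
        except (RegistryError, TypeError) as exc:
            raise RegistryError(f"{source}, row {i}: {exc}") from exc
    try:
        return FoodRegistry(tuple(items))
    except RegistryError as exc:
        raise RegistryError(f"{source}: {exc}") from exc


def load_food_registry(path: str | Path) -> FoodRegistry:
    """Read a registry from JSON (canonical) or CSV; all invariants enforced.

    JSON format: either a bare list of item objects or ``{"items": [...]}``.
    CSV requires a header with at least item_id,label,grouping.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path, dtype=str)
        required = {"item_id", "label", "grouping"}
        missing = required - set(frame.columns)
        if missing:
            raise RegistryError(f"{path}: missing columns {sorted(missing)}")
        records = frame.to_dict(orient="records")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        records = payload["items"] if isinstance(payload, dict) else payload
    return _registry_from_records(records, source=str(path))


def write_registry(registry: FoodRegistry, path: str | Path) -> None:
    """Write a registry to JSON or CSV (by suffix); round-trips losslessly."""
    path = Path(path)
    records = [vars(it) for it in registry.items]
    if path.suffix.lower() == ".csv":
        pd.DataFrame(records).to_csv(path, index=False)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"items": records}, fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Response tables

def validate_response_frame(
    frame: pd.DataFrame,
    registry: FoodRegistry,
    dialects: Optional[Mapping[str, InstrumentDialect]] = None,
) -> ValidationReport:
    """Validate a long-format response frame against registry and dialects."""
    dialects = dialects or default_dialects()
    report = ValidationReport()
    known_items = set(registry.item_ids())
    for row in frame.itertuples():
        loc = f"row {row.Index} (subject={row.subject_id}, item={row.item_id})"
        if row.role not in dialects:
            report.add_error(loc, f"unknown role {row.role!r}")
            continue
        if row.timepoint not in TIMEPOINTS:
            report.add_error(loc, f"unknown timepoint {row.timepoint!r}")
        if row.item_id not in known_items:
            report.add_error(loc, f"unknown item_id {row.item_id!r}")
        dialect = dialects[row.role]
        if row.response not in dialect.servings_per_day:
            report.add_error(
                loc,
                f"response {row.response!r} not valid for the "
                f"{dialect.name!r} dialect (allowed: {list(dialect.categories)})",
            )
    dup = frame.duplicated(subset=["subject_id", "timepoint", "item_id"], keep=False)
    if dup.any():
        for idx in frame.index[dup]:
            row = frame.loc[idx]
            report.add_error(
                f"row {idx} (subject={row['subject_id']}, item={row['item_id']})",
                "duplicate (subject_id, timepoint, item_id)",
            )
    return report


def load_response_table(
    path: str | Path,
    dialect: Optional[InstrumentDialect] = None,
    registry: Optional[FoodRegistry] = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a long-format picture-sort response CSV and validate it.

    The header must be exactly ``subject_id,role,timepoint,item_id,response``.
    If ``dialect`` is given it is applied to every row; otherwise each row's
    ``role`` selects the packaged dialect.  Returns the parsed frame together
    with a :class:`ValidationReport`; an empty table raises
    :class:`ResponseTableError` (distinct from validation failure).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ResponseTableError(f"{path}: empty response table") from exc
    if list(frame.columns) != RESPONSE_COLUMNS:
        raise ResponseTableError(
            f"{path}: header must be exactly {','.join(RESPONSE_COLUMNS)}"
        )
    if frame.empty:
        raise ResponseTableError(f"{path}: response table has no records")
    registry = registry or default_registry()
    dialects = (
        {r: dialect for r in ROLES} if dialect is not None else default_dialects()
    )
    report = validate_response_frame(frame, registry, dialects)
    return frame, report


__all__ = [
    "AHEI_COMPONENTS",
    "GROUPINGS",
    "HEALTHY_COMPONENTS",
    "RESPONSE_COLUMNS",
    "ROLES",
    "TIMEPOINTS",
    "FoodItem",
    "FoodRegistry",
    "InstrumentDialect",
    "RegistryError",
    "ResponseTableError",
    "ValidationReport",
    "default_dialects",
    "default_registry",
    "load_dialects",
    "load_food_registry",
    "load_response_table",
    "validate_response_frame",
    "write_registry",
]
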