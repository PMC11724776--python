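"""Derivation of MED4CHILD item indicators from semi-quantitative FFQ data.

The reference instrument reports food-group intakes in grams per day (and
optionally eating occasions per week).  To apply the screener's criteria,
gram intakes are converted to servings with per-group serving sizes; items
the screener phrases as "times a week" use the FFQ frequency columns when
present and fall back to gram-based servings otherwise.  Item 11 (sofrito)
cannot be estimated from group-level FFQ data and is reported as not
derivable; the reference score therefore spans 17 of the 18 items.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, MissingAnswerError
from .scoring import (
    DEFAULT_DICHOTOMY_CUTOFF,
    DEFAULT_QUARTILE_CUTPOINTS,
    ItemCriterion,
    ScoreResult,
    assign_quartile,
    dichotomize,
    load_registry,
    registry_index,
    score_item,
)

CANONICAL_GROUPS = (
    "vegetables",
    "fruits",
    "olive_oil",
    "butter_cream",
    "refined_cereals",
    "whole_grains",
    "fish_seafood",
    "red_processed_meat",
    "white_meat",
    "nuts",
    "legumes",
    "fermented_dairy",
    "dairy_desserts",
    "sugared_beverages",
    "sweets_snacks",
    "pastries",
    "precooked",
)


class _NotDerivable:
    """Sentinel: the item cannot be estimated from FFQ data."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_DERIVABLE"


NOT_DERIVABLE = _NotDerivable()


@dataclass(frozen=True)
class ServingDefinition:
    """Grams per serving for one food group."""

    group: str
    grams_per_serving: float
    source_interval: tuple[float, float] | None = None

    def __post_init__(self):
        if self.grams_per_serving <= 0:
            raise ConfigurationError(
                f"grams_per_serving must be positive ({self.group})"
            )
        if self.source_interval is not None:
            lo, hi = self.source_interval
            if not lo <= self.grams_per_serving <= hi:
                raise ConfigurationError(
                    f"serving size {self.grams_per_serving} outside its "
                    f"source interval [{lo}, {hi}] ({self.group})"
                )


@dataclass(frozen=True)
class FFQRecord:
    """One child's FFQ summary: g/day per food group, optional weekly
    frequencies, daily energy and nutrient intakes."""

    child_id: str
    group_intakes: Mapping[str, float]
    frequencies: Mapping[str, float] = field(default_factory=dict)
    energy_kcal_day: float | None = None
    nutrient_intakes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for group, value in self.group_intakes.items():
            if value is not None and not math.isnan(value) and value < 0:
                raise ConfigurationError(f"negative intake for {group}")
        if self.energy_kcal_day is not None and self.energy_kcal_day <= 0:
            raise ConfigurationError("energy_kcal_day must be positive")

    def intake(self, group: str) -> float:
        value = self.group_intakes.get(group)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise MissingAnswerError(f"missing intake for food group {group!r}")
        return float(value)

    def frequency(self, group: str) -> float | None:
        value = self.frequencies.get(group)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return float(value)


@dataclass(frozen=True)
class FFQMapping:
    """Item -> food-group mapping plus serving definitions."""

    servings: Mapping[str, ServingDefinition]
    item_rules: Mapping[int, dict]

    def serving(self, group: str) -> ServingDefinition:
        if group not in self.servings:
            raise ConfigurationError(f"no serving definition for group {group!r}")
        return self.servings[group]


def load_mapping(path: str | Path | None = None) -> FFQMapping:
    """Load the FFQ mapping config (packaged default or user YAML)."""
    if path is None:
        text = resources.files("med4child.data").joinpath("ffq_mapping.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    servings = {
        group: ServingDefinition(
            group=group,
            grams_per_serving=float(spec["grams"]),
            source_interval=(
                tuple(float(x) for x in spec["source_interval"])
                if spec.get("source_interval")
                else None
            ),
        )
        for group, spec in raw["servings"].items()
    }
    item_rules = {int(k): dict(v) for k, v in raw["items"].items()}
    return FFQMapping(servings=servings, item_rules=item_rules)


def intake_to_servings(
    grams_per_day: float, serving: ServingDefinition, period: str = "day"
) -> float:
    """Convert a g/day intake to servings per day or per week."""
    if grams_per_day < 0:
        raise ConfigurationError("grams_per_day must be >= 0")
    if period not in ("day", "week"):
        raise ConfigurationError(f"period must be 'day' or 'week', got {period!r}")
    servings = grams_per_day / serving.grams_per_serving
    return servings * 7.0 if period == "week" else servings


def _criterion_period(criterion: ItemCriterion) -> str:
    return "day" if criterion.unit.endswith("_day") else "week"


def derive_item_from_ffq(
    item_id: int,
    record: FFQRecord,
    registry: Sequence[ItemCriterion] | None = None,
    mapping: FFQMapping | None = None,
):
    """Apply one screener criterion to FFQ-derived servings.

    Returns 0/1, or :data:`NOT_DERIVABLE` for items with no FFQ
    counterpart (item 11 by default).  Raises
    :class:`MissingAnswerError` when a needed food group is absent.
    """
    if registry is None:
        registry = load_registry()
    if mapping is None:
        mapping = load_mapping()
    criterion = registry_index(registry)[item_id]
    rule = mapping.item_rules.get(item_id)
    if rule is None:
        raise ConfigurationError(f"no FFQ mapping for item {item_id}")

    kind = rule["rule"]
    if kind == "not_derivable":
        return NOT_DERIVABLE

    if kind == "main_fat":
        olive = record.intake("olive_oil")
        butter = record.intake("butter_cream")
        return int(olive > 0 and olive > butter)

    if kind == "white_vs_red":
        white = record.frequency("white_meat")
        red = record.frequency("red_processed_meat")
        if white is None or red is None:
            # gram-based fallback on daily intakes
            white = record.intake("white_meat")
            red = record.intake("red_processed_meat")
        return int(white > red)

    (group,) = rule["groups"]
    period = _criterion_period(criterion)
    if kind == "frequency":
        value = record.frequency(group)
        if value is None:
            value = intake_to_servings(
                record.intake(group), mapping.serving(group), period
            )
    elif kind == "servings":
        value = intake_to_servings(record.intake(group), mapping.serving(group), period)
    else:
        raise ConfigurationError(f"unknown FFQ rule {kind!r} for item {item_id}")
    # item 3's raw/salad sub-condition is not separable in group-level FFQ
    # data; the main threshold alone decides (mapping limitation).
    return score_item(criterion, value)


def derivable_items(mapping: FFQMapping | None = None) -> list[int]:
    if mapping is None:
        mapping = load_mapping()
    return sorted(
        i for i, rule in mapping.item_rules.items() if rule["rule"] != "not_derivable"
    )


def derive_score_from_ffq(
    record: FFQRecord,
    registry: Sequence[ItemCriterion] | None = None,
    mapping: FFQMapping | None = None,
    dichotomy_cutoff: int = DEFAULT_DICHOTOMY_CUTOFF,
    quartile_cutpoints: Sequence[int] = DEFAULT_QUARTILE_CUTPOINTS,
) -> ScoreResult:
    """Reference score over the 17 FFQ-derivable items for one child."""
    if registry is None:
        registry = load_registry()
    if mapping is None:
        mapping = load_mapping()
    points: dict[int, int] = {}
    for item_id in derivable_items(mapping):
        point = derive_item_from_ffq(item_id, record, registry, mapping)
        points[item_id] = int(point)
    total = int(sum(points.values()))
    return ScoreResult(
        child_id=record.child_id,
        item_points=points,
        total=total,
        quartile=assign_quartile(total, quartile_cutpoints),
        adherence_class=dichotomize(total, dichotomy_cutoff),
        items_used=frozenset(points),
    )


def records_from_table(
    df: pd.DataFrame, column_dictionary: Mapping[str, str] | None = None
) -> list[FFQRecord]:
    """Build FFQ records from a wide table (one row per child).

    Columns named by canonical food group hold g/day; optional
    ``freq_<group>`` columns hold eating occasions per week;
    ``energy_kcal_day`` is passed through.  ``column_dictionary`` maps
    user column names to canonical ones.
    """
    if column_dictionary:
        df = df.rename(columns=dict(column_dictionary))
    ids = df["child_id"] if "child_id" in df.columns else df.index
    records = []
    group_cols = [g for g in CANONICAL_GROUPS if g in df.columns]
    freq_cols = {
        g: f"freq_{g}" for g in CANONICAL_GROUPS if f"freq_{g}" in df.columns
    }
    for (_, row), child_id in zip(df.iterrows(), ids):
        records.append(
            FFQRecord(
                child_id=str(child_id),
                group_intakes={g: row[g] for g in group_cols},
                frequencies={g: row[c] for g, c in freq_cols.items()},
                energy_kcal_day=(
                    float(row["energy_kcal_day"])
                    if "energy_kcal_day" in df.columns
                    and not math.isnan(float(row["energy_kcal_day"]))
                    else None
                ),
            )
        )
    return records


def derive_table(
    df: pd.DataFrame,
    registry: Sequence[ItemCriterion] | None = None,
    mapping: FFQMapping | None = None,
    dichotomy_cutoff: int = DEFAULT_DICHOTOMY_CUTOFF,
) -> pd.DataFrame:
    """Derive the 17-item reference score for a whole FFQ table.

    Returns per-item points ``pt01..pt18`` (item 11 absent), ``total`` and
    ``adherence_class``; children with a missing needed food group are
    dropped and counted in ``attrs["n_excluded"]``.
    """
    if registry is None:
        registry = load_registry()
    if mapping is None:
        mapping = load_mapping()
    rows = []
    n_excluded = 0
    for record in records_from_table(df):
        try:
            res = derive_score_from_ffq(
                record, registry, mapping, dichotomy_cutoff=dichotomy_cutoff
            )
        except MissingAnswerError:
            n_excluded += 1
            continue
        row: dict = {"child_id": res.child_id}
        row.update({f"pt{i:02d}": res.item_points[i] for i in sorted(res.items_used)})
        row["total"] = res.total
        row["adherence_class"] = res.adherence_class
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out
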