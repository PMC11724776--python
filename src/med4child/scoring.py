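"""Scoring engine for the 18-item MED4CHILD Mediterranean-diet screener.

The screener awards one point per satisfied item criterion (0-18 total).
Items are defined by a direction (``at_least`` / ``less_than`` for
quantitative items, ``yes`` for binary preference items), a threshold in
the item's own unit, and optionally a sub-condition (item 3 additionally
asks for at least one raw/salad vegetable serving per week).

Answers are stored as quantities, not pre-computed yes/no, and thresholds
are applied by this engine; binary items accept 0/1 directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DomainError,
    IncompleteRecordError,
    MissingAnswerError,
)

VALID_UNITS = frozenset(
    {
        "servings_per_day",
        "servings_per_week",
        "times_per_week",
        "tablespoons_per_day",
        "binary_preference",
    }
)
VALID_DIRECTIONS = frozenset({"at_least", "less_than", "yes"})

#: Quartile cut points of the study cohort's score distribution:
#: Q1 0-8, Q2 9-11, Q3 12-13, Q4 14-18.
DEFAULT_QUARTILE_CUTPOINTS: tuple[int, int, int] = (8, 11, 13)

#: Total-score cutoff separating low (< 10) from high (>= 10) adherence.
DEFAULT_DICHOTOMY_CUTOFF: int = 10

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class ExtraCondition:
    """A sub-criterion that must also hold for the item's point."""

    label: str
    unit: str
    direction: str
    threshold: float

    def is_satisfied(self, value: float) -> bool:
        if self.direction == "at_least":
            return value >= self.threshold
        return value < self.threshold


@dataclass(frozen=True)
class ItemCriterion:
    """Machine-readable scoring rule for one MED4CHILD item."""

    item_id: int
    label: str
    unit: str
    direction: str
    threshold: float
    serving_grams: tuple[float, float] | None = None
    extra_condition: ExtraCondition | None = None

    def __post_init__(self):
        if not 1 <= self.item_id <= 18:
            raise ConfigurationError(f"item_id must be 1-18, got {self.item_id}")
        if self.unit not in VALID_UNITS:
            raise ConfigurationError(f"unknown unit {self.unit!r} (item {self.item_id})")
        if self.direction not in VALID_DIRECTIONS:
            raise ConfigurationError(
                f"unknown direction {self.direction!r} (item {self.item_id})"
            )
        if self.threshold < 0:
            raise ConfigurationError(f"threshold must be >= 0 (item {self.item_id})")
        if self.serving_grams is not None:
            lo, hi = self.serving_grams
            if not 0 < lo <= hi:
                raise ConfigurationError(
                    f"serving_grams interval must satisfy 0 < lower <= upper "
                    f"(item {self.item_id})"
                )


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One child's answers to the administered screener.

    ``answers`` maps item_id to the reported quantity in the item's unit
    (binary items: 0/1).  ``extras`` carries sub-condition answers, keyed
    by item_id (currently only item 3's weekly raw/salad servings).
    A ``None``/NaN or absent answer is treated as missing.
    """

    child_id: str
    answers: Mapping[int, float | None]
    extras: Mapping[int, float | None] = field(default_factory=dict)

    def answer(self, item_id: int) -> float | None:
        value = self.answers.get(item_id)
        return None if _is_missing(value) else float(value)

    def extra(self, item_id: int) -> float | None:
        value = self.extras.get(item_id)
        return None if _is_missing(value) else float(value)


@dataclass(frozen=True)
class ScoreResult:
    """Per-item indicators plus derived summaries for one child."""

    child_id: str
    item_points: Mapping[int, int]
    total: int
    quartile: str
    adherence_class: str
    items_used: frozenset[int]


def load_registry(path: str | Path | None = None) -> list[ItemCriterion]:
    """Load the item registry (the packaged default, or a user YAML file).

    The default registry mirrors the published criteria table; exactly 18
    items with distinct ids are required.
    """
    if path is None:
        text = resources.files("med4child.data").joinpath("items.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    criteria = []
    for entry in raw["items"]:
        extra = entry.get("extra_condition")
        criteria.append(
            ItemCriterion(
                item_id=int(entry["item_id"]),
                label=str(entry["label"]),
                unit=str(entry["unit"]),
                direction=str(entry["direction"]),
                threshold=float(entry["threshold"]),
                serving_grams=(
                    tuple(float(g) for g in entry["serving_grams"])
                    if entry.get("serving_grams")
                    else None
                ),
                extra_condition=(
                    ExtraCondition(
                        label=str(extra["label"]),
                        unit=str(extra["unit"]),
                        direction=str(extra["direction"]),
                        threshold=float(extra["threshold"]),
                    )
                    if extra
                    else None
                ),
            )
        )
    ids = [c.item_id for c in criteria]
    if len(ids) != 18 or len(set(ids)) != 18:
        raise ConfigurationError(
            f"registry must define exactly 18 items with distinct ids, got {sorted(ids)}"
        )
    return criteria


def registry_index(registry: Sequence[ItemCriterion]) -> dict[int, ItemCriterion]:
    return {c.item_id: c for c in registry}


def score_item(
    criterion: ItemCriterion,
    answer: float | None,
    extra_answer: float | None = None,
) -> int:
    """Score one item: 1 if the answer satisfies the criterion, else 0.

    Raises :class:`MissingAnswerError` for a missing answer rather than
    returning 0, so the missing-data policy can act.  When the criterion
    carries a sub-condition and an ``extra_answer`` is provided, both must
    hold; with no ``extra_answer`` the main threshold alone decides (this
    mirrors the FFQ-side mapping, where the sub-condition is not separable).
    """
    if _is_missing(answer):
        raise MissingAnswerError(f"missing answer for item {criterion.item_id}")
    answer = float(answer)
    if answer < 0:
        raise DomainError(f"negative answer {answer} for item {criterion.item_id}")

    if criterion.direction == "yes":
        if answer not in (0.0, 1.0):
            raise DomainError(
                f"binary item {criterion.item_id} expects 0/1, got {answer}"
            )
        return int(answer == 1.0)

    if criterion.direction == "at_least":
        point = answer >= criterion.threshold
    else:  # less_than
        point = answer < criterion.threshold

    if point and criterion.extra_condition is not None and extra_answer is not None:
        point = criterion.extra_condition.is_satisfied(float(extra_answer))
    return int(point)


def score_total(
    response: QuestionnaireResponse,
    registry: Sequence[ItemCriterion] | None = None,
    items_used: Iterable[int] | None = None,
    policy: str = "complete_case",
    dichotomy_cutoff: int = DEFAULT_DICHOTOMY_CUTOFF,
    quartile_cutpoints: Sequence[int] = DEFAULT_QUARTILE_CUTPOINTS,
) -> ScoreResult:
    """Score all requested items for one child and summarise.

    policy
        ``complete_case`` (default): any missing item raises
        :class:`IncompleteRecordError`, signalling record exclusion.
        ``score_zero``: a missing item contributes 0 points.
    """
    if registry is None:
        registry = load_registry()
    index = registry_index(registry)
    used = frozenset(items_used) if items_used is not None else frozenset(index)
    unknown = used - set(index)
    if unknown:
        raise ConfigurationError(f"items {sorted(unknown)} not in registry")
    unknown_answers = {k for k in response.answers if k not in index}
    if unknown_answers:
        raise ConfigurationError(
            f"answers contain unknown item ids {sorted(unknown_answers)}"
        )
    if policy not in ("complete_case", "score_zero"):
        raise ConfigurationError(f"unknown missing-data policy {policy!r}")

    points: dict[int, int] = {}
    for item_id in sorted(used):
        criterion = index[item_id]
        answer = response.answer(item_id)
        try:
            points[item_id] = score_item(criterion, answer, response.extra(item_id))
        except MissingAnswerError:
            if policy == "complete_case":
                raise IncompleteRecordError(
                    f"child {response.child_id}: missing item {item_id} "
                    f"under complete-case policy"
                )
            points[item_id] = 0

    total = int(sum(points.values()))
    return ScoreResult(
        child_id=response.child_id,
        item_points=points,
        total=total,
        quartile=assign_quartile(total, quartile_cutpoints),
        adherence_class=dichotomize(total, dichotomy_cutoff),
        items_used=used,
    )


def assign_quartile(
    total: int,
    cutpoints: Sequence[int] | str = DEFAULT_QUARTILE_CUTPOINTS,
    cohort_totals: Sequence[int] | None = None,
) -> str:
    """Map a total score to its quartile band.

    With fixed ``cutpoints`` (c1, c2, c3) the bands are [0, c1], (c1, c2],
    (c2, c3], (c3, 18].  With ``cutpoints="empirical"`` the 25/50/75th
    percentiles of ``cohort_totals`` are used instead.
    """
    if not 0 <= total <= 18:
        raise DomainError(f"score {total} outside 0-18")
    if isinstance(cutpoints, str):
        if cutpoints != "empirical":
            raise ConfigurationError(f"unknown quartile mode {cutpoints!r}")
        if cohort_totals is None or len(cohort_totals) == 0:
            raise ConfigurationError("empirical quartiles require cohort_totals")
        cuts = np.quantile(np.asarray(cohort_totals, dtype=float), [0.25, 0.5, 0.75])
    else:
        cuts = [float(c) for c in cutpoints]
        if len(cuts) != 3 or sorted(cuts) != cuts:
            raise ConfigurationError("need 3 ascending cut points")
    for label, cut in zip(QUARTILE_LABELS[:3], cuts):
        if total <= cut:
            return label
    return "Q4"


def dichotomize(total: int, cutoff: int = DEFAULT_DICHOTOMY_CUTOFF) -> str:
    """Classify adherence as ``high`` (total >= cutoff) or ``low``."""
    if not 0 <= total <= 18:
        raise DomainError(f"score {total} outside 0-18")
    return "high" if total >= cutoff else "low"


def responses_from_table(df: pd.DataFrame) -> list[QuestionnaireResponse]:
    """Build responses from a wide table with columns q01..q18 (+ q03_raw).

    Missing cells (NaN) become missing answers.  ``child_id`` is taken from
    a ``child_id`` column, else from the index.
    """
    expected = [f"q{i:02d}" for i in range(1, 19)]
    out = []
    ids = df["child_id"] if "child_id" in df.columns else df.index
    for (_, row), child_id in zip(df.iterrows(), ids):
        answers = {
            i: row[col] for i, col in enumerate(expected, start=1) if col in df.columns
        }
        extras = {3: row["q03_raw"]} if "q03_raw" in df.columns else {}
        out.append(QuestionnaireResponse(str(child_id), answers, extras))
    return out


def score_table(
    df: pd.DataFrame,
    registry: Sequence[ItemCriterion] | None = None,
    items_used: Iterable[int] | None = None,
    policy: str = "complete_case",
    dichotomy_cutoff: int = DEFAULT_DICHOTOMY_CUTOFF,
    quartile_cutpoints: Sequence[int] | str = DEFAULT_QUARTILE_CUTPOINTS,
) -> pd.DataFrame:
    """Score a whole questionnaire table.

    Returns one row per scored child with per-item point columns
    ``pt01..pt18`` (restricted to ``items_used``), ``total``, ``quartile``
    and ``adherence_class``.  Under the complete-case policy, children with
    missing items are dropped (they are recorded by the pipeline's
    exclusion accounting, not silently lost here: the return value's
    ``attrs["n_excluded"]`` carries the count).
    """
    if registry is None:
        registry = load_registry()
    results = []
    n_excluded = 0
    for response in responses_from_table(df):
        try:
            results.append(
                score_total(
                    response,
                    registry,
                    items_used=items_used,
                    policy=policy,
                    dichotomy_cutoff=dichotomy_cutoff,
                    quartile_cutpoints=(
                        quartile_cutpoints
                        if not isinstance(quartile_cutpoints, str)
                        else DEFAULT_QUARTILE_CUTPOINTS
                    ),
                )
            )
        except IncompleteRecordError:
            n_excluded += 1
    rows = []
    for res in results:
        row: dict = {"child_id": res.child_id}
        row.update({f"pt{i:02d}": res.item_points[i] for i in sorted(res.items_used)})
        row["total"] = res.total
        row["adherence_class"] = res.adherence_class
        rows.append(row)
    out = pd.DataFrame(rows)
    if isinstance(quartile_cutpoints, str):  # empirical: needs the cohort totals
        totals = out["total"].tolist() if len(out) else []
        out["quartile"] = [
            assign_quartile(t, quartile_cutpoints, totals) for t in out["total"]
        ]
    elif len(out):
        out["quartile"] = [
            assign_quartile(t, quartile_cutpoints) for t in out["total"]
        ]
    out.attrs["n_excluded"] = n_excluded
    return out
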