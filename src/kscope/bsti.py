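"""Baumann questionnaire scoring and 16-type classification.

The Baumann Skin Type Indicator (BSTI) is a self-administered instrument of
60 items answered on a 1-4 scale.  Items belong to four categories —
dryness/oiliness (O, 11 items), sensitivity/resistance (S, 18 items),
pigmentation/non-pigmentation (P, 10 items) and wrinkles/elasticity
(W, 20 items) — and each category total is compared against a published
threshold to call one letter per axis.  The four letters concatenate to one
of 16 types (e.g. ``DRNT``).

Scoring rules implemented here:

* unanswered items contribute 2.5 points;
* O total >= 27 -> oily (``O``), else dry (``D``);
* S total >= 30 -> sensitive (``S``), with +4 bonus points if the subject
  reports one of the listed skin conditions, else resistant (``R``);
* P total >= 31 -> pigmented (``P``), with +5 bonus if sunlight aggravates
  the subject's moles, else non-pigmented (``N``);
* W total >= 41 -> wrinkly (``W``), with +5 bonus if aged over 65, else
  tight/elastic (``T``).

The published category counts sum to 59, one short of the 60-item
instrument; the scorer therefore accepts an optional unscored item tagged
``X`` which never contributes points (see the synthetic generator).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CATEGORY_ITEM_COUNTS",
    "AXIS_THRESHOLDS",
    "HIGH_LETTER",
    "LOW_LETTER",
    "ALL_TYPES",
    "MISSING_ITEM_POINTS",
    "QuestionnaireResponse",
    "BaumannScores",
    "default_category_map",
    "score_category",
    "classify_axis",
    "score_response",
    "classify_bsti",
    "type_distribution",
]

#: items per category for the 60-item instrument (59 scored + 1 unscored).
CATEGORY_ITEM_COUNTS: Mapping[str, int] = {"O": 11, "S": 18, "P": 10, "W": 20}

#: category total at or above which the "high" letter is called.
AXIS_THRESHOLDS: Mapping[str, int] = {"O": 27, "S": 30, "P": 31, "W": 41}

HIGH_LETTER: Mapping[str, str] = {"O": "O", "S": "S", "P": "P", "W": "W"}
LOW_LETTER: Mapping[str, str] = {"O": "D", "S": "R", "P": "N", "W": "T"}

#: points credited for an unanswered item.
MISSING_ITEM_POINTS: float = 2.5

#: bonus points added before the threshold comparison.
_SENSITIVITY_CONDITION_BONUS = 4.0
_MOLE_SUN_BONUS = 5.0
_AGE_BONUS = 5.0
_AGE_BONUS_OVER = 65  # strict: bonus applies to age > 65

_CATEGORY_ORDER = ("O", "S", "P", "W")

#: the 16 reachable four-letter labels, in axis order O/D, S/R, P/N, W/T.
ALL_TYPES: tuple[str, ...] = tuple(
    "".join(letters)
    for letters in itertools.product(
        ("D", "O"), ("R", "S"), ("N", "P"), ("T", "W")
    )
)


def default_category_map(n_items: int = 60) -> list[str]:
    """Item-order category tags for the default instrument layout.

    The first 11 items are O, the next 18 S, then 10 P, then 20 W; any
    remaining items are tagged ``X`` (unscored).  A custom instrument can
    supply its own tag list to :class:`QuestionnaireResponse`.
    """
    tags: list[str] = []
    for cat in _CATEGORY_ORDER:
        tags.extend(cat * 1 for _ in range(CATEGORY_ITEM_COUNTS[cat]))
    tags = [t for t in tags]
    if n_items < len(tags):
        raise ValueError(f"instrument needs at least {len(tags)} items")
    tags.extend("X" for _ in range(n_items - len(tags)))
    return tags


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return True


@dataclass
class QuestionnaireResponse:
    """One subject's questionnaire answers plus scoring flags.

    Parameters
    ----------
    subject_id:
        Identifier carried through to outputs.
    items:
        Ordered item values; each is 1-4 or missing (``None``/NaN).
    categories:
        Category tag per item (``O``/``S``/``P``/``W``/``X``); defaults to
        the standard layout for the given item count.
    has_listed_skin_condition:
        Caller-supplied flag driving the sensitivity bonus.
    sun_aggravates_moles:
        Caller-supplied flag driving the pigmentation bonus.
    age:
        Age in years; drives the wrinkle-axis bonus.
    """

    subject_id: str
    items: Sequence[float | None]
    categories: Sequence[str] | None = None
    has_listed_skin_condition: bool = False
    sun_aggravates_moles: bool = False
    age: float = 0.0
    _tags: tuple[str, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        tags = (
            tuple(self.categories)
            if self.categories is not None
            else tuple(default_category_map(len(self.items)))
        )
        if len(tags) != len(self.items):
            raise ValueError("items and categories differ in length")
        counts = {c: sum(1 for t in tags if t == c) for c in _CATEGORY_ORDER}
        if counts != dict(CATEGORY_ITEM_COUNTS):
            raise ValueError(
                f"category item counts {counts} != required {dict(CATEGORY_ITEM_COUNTS)}"
            )
        for v in self.items:
            if not _is_missing(v) and float(v) not in (1.0, 2.0, 3.0, 4.0):
                raise ValueError(f"item value {v!r} not in {{1,2,3,4}} or missing")
        self._tags = tags

    def category_values(self, category: str) -> list[float | None]:
        if category not in _CATEGORY_ORDER:
            raise KeyError(f"unknown category {category!r}")
        return [v for v, t in zip(self.items, self._tags) if t == category]


@dataclass(frozen=True)
class BaumannScores:
    """Raw and bonus-adjusted category totals plus the four axis calls."""

    subject_id: str
    raw: Mapping[str, float]
    adjusted: Mapping[str, float]
    axis_calls: Mapping[str, str]

    @property
    def label(self) -> str:
        return "".join(self.axis_calls[c] for c in _CATEGORY_ORDER)


def score_category(response: QuestionnaireResponse, category: str) -> float:
    """Total points for one category: item values plus 2.5 per missing item."""
    values = response.category_values(category)
    return float(
        sum(MISSING_ITEM_POINTS if _is_missing(v) else float(v) for v in values)
    )


def _bonus(category: str, *, has_listed_skin_condition: bool,
           sun_aggravates_moles: bool, age: float) -> float:
    if category == "S" and has_listed_skin_condition:
        return _SENSITIVITY_CONDITION_BONUS
    if category == "P" and sun_aggravates_moles:
        return _MOLE_SUN_BONUS
    if category == "W" and age > _AGE_BONUS_OVER:
        return _AGE_BONUS
    return 0.0


def classify_axis(
    total: float,
    category: str,
    *,
    has_listed_skin_condition: bool = False,
    sun_aggravates_moles: bool = False,
    age: float = 0.0,
) -> str:
    """Call one axis letter from a category total.

    The applicable bonus is added to ``total`` before comparison with the
    published threshold; values strictly below the threshold (including
    half-point totals from missing items) take the "low" letter.
    """
    if category not in _CATEGORY_ORDER:
        raise KeyError(f"unknown category {category!r}")
    if not math.isfinite(float(total)):
        raise ValueError("category total must be finite")
    adjusted = float(total) + _bonus(
        category,
        has_listed_skin_condition=has_listed_skin_condition,
        sun_aggravates_moles=sun_aggravates_moles,
        age=age,
    )
    high = adjusted >= AXIS_THRESHOLDS[category]
    return HIGH_LETTER[category] if high else LOW_LETTER[category]


def score_response(response: QuestionnaireResponse) -> BaumannScores:
    """Score all four categories and call the four axes for one subject."""
    raw = {c: score_category(response, c) for c in _CATEGORY_ORDER}
    adjusted = {
        c: raw[c]
        + _bonus(
            c,
            has_listed_skin_condition=response.has_listed_skin_condition,
            sun_aggravates_moles=response.sun_aggravates_moles,
            age=response.age,
        )
        for c in _CATEGORY_ORDER
    }
    calls = {
        c: classify_axis(
            raw[c],
            c,
            has_listed_skin_condition=response.has_listed_skin_condition,
            sun_aggravates_moles=response.sun_aggravates_moles,
            age=response.age,
        )
        for c in _CATEGORY_ORDER
    }
    return BaumannScores(response.subject_id, raw, adjusted, calls)


def classify_bsti(response: QuestionnaireResponse) -> str:
    """Four-letter Baumann type for one subject (e.g. ``DRNT``)."""
    return score_response(response).label


def type_distribution(types: Iterable[str]) -> pd.DataFrame:
    """Counts and percentages per label over all 16 types (zero-filled).

    Returns a frame indexed by label with ``count`` and ``percent`` columns;
    percentages sum to 100.
    """
    labels = list(types)
    if not labels:
        raise ValueError("type_distribution needs at least one label")
    bad = sorted(set(labels) - set(ALL_TYPES))
    if bad:
        raise ValueError(f"unknown type labels: {bad}")
    counts = pd.Series(labels).value_counts().reindex(ALL_TYPES, fill_value=0)
    out = pd.DataFrame(
        {"count": counts.astype(int), "percent": 100.0 * counts / len(labels)}
    )
    out.index.name = "type"
    return out


def score_table(
    responses: pd.DataFrame,
    categories: Sequence[str] | None = None,
    item_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score a questionnaire table (one row per subject).

    ``responses`` must carry item columns (default: every ``q``-prefixed
    column, in order) and may carry ``has_listed_skin_condition``,
    ``sun_aggravates_moles`` and ``age`` columns.
    """
    if item_columns is None:
        item_columns = [c for c in responses.columns if c.startswith("q")]
    rows = []
    for sid, row in responses.iterrows():
        resp = QuestionnaireResponse(
            subject_id=str(sid),
            items=[row[c] for c in item_columns],
            categories=categories,
            has_listed_skin_condition=bool(row.get("has_listed_skin_condition", False)),
            sun_aggravates_moles=bool(row.get("sun_aggravates_moles", False)),
            age=float(row.get("age", 0.0)),
        )
        scores = score_response(resp)
        rows.append(
            {
                "subject_id": scores.subject_id,
                **{f"raw_{c}": scores.raw[c] for c in _CATEGORY_ORDER},
                **{f"adjusted_{c}": scores.adjusted[c] for c in _CATEGORY_ORDER},
                "bsti": scores.label,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")
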