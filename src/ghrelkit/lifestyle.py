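"""Lifestyle covariates: dietary habits index and physical-activity indices.

Two questionnaire-derived covariates enter the adjusted reliability model:

* a dietary habits score from a 37-item qualitative food-frequency list
  (frequency categories from 'almost daily' down to 'never'), summed over
  items so that a maximum of 127 points corresponds to a healthy diet; and
* physical-activity summaries from a standardized activity questionnaire
  covering daily, leisure and athletic activity — total hours per week, and
  an energy-consumption index based on MET (metabolic equivalent of task)
  values per activity.

The original survey instrument does not publish per-item weights, so the
packaged default :class:`ScoringScheme` is an explicit modeling choice (37
items whose maxima sum to exactly 127, direction per the healthy/unhealthy
food-group description); any user-supplied scheme file with consistent
totals can replace it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "FREQUENCY_CATEGORIES",
    "ScoringScheme",
    "load_scheme",
    "default_scheme",
    "dietary_habits_score",
    "ActivityRecord",
    "total_activity_hours",
    "met_energy",
]

#: The six consumption-frequency categories, healthiest-for-frequent first.
FREQUENCY_CATEGORIES: tuple[str, ...] = (
    "almost daily",
    "several times per week",
    "about once a week",
    "several times per month",
    "once a month or less",
    "never",
)

_ACTIVITY_CATEGORIES = ("daily", "leisure", "athletic")


def _canon(token: str) -> str:
    """Canonicalise a category token: case-insensitive, whitespace-collapsed."""
    return " ".join(str(token).strip().lower().replace("_", " ").split())


@dataclass(frozen=True)
class ScoringScheme:
    """Per-item point maps for the food-frequency score.

    ``items`` maps item id -> {frequency category -> points}; ``directions``
    maps item id -> 'healthy_frequent' | 'healthy_rare'. The declared
    ``max_total`` must equal the sum of per-item maxima (self-check at load
    time; loading fails otherwise).
    """

    name: str
    max_total: int
    items: Mapping[str, Mapping[str, float]]
    directions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(max(pts.values()) for pts in self.items.values())
        if total != self.max_total:
            raise ValueError(
                f"scoring scheme {self.name!r} declares max_total={self.max_total} "
                f"but per-item maxima sum to {total}"
            )
        for item, pts in self.items.items():
            if any(p < 0 for p in pts.values()):
                raise ValueError(f"negative points configured for item {item!r}")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.items)

    def item_maximum(self, item: str) -> float:
        return max(self.items[item].values())

    def healthiest_category(self, item: str) -> str:
        """The category earning the most points for *item* (first on ties)."""
        pts = self.items[item]
        return max(pts, key=pts.__getitem__)  # first category on ties


def _scheme_from_dict(raw: dict) -> ScoringScheme:
    items: dict[str, dict[str, float]] = {}
    directions: dict[str, str] = {}
    for entry in raw["items"]:
        item_id = entry["id"]
        if item_id in items:
            raise ValueError(f"duplicate item {item_id!r} in scoring scheme")
        items[item_id] = {_canon(c): float(p) for c, p in entry["points"].items()}
        directions[item_id] = entry.get("direction", "healthy_frequent")
    return ScoringScheme(
        name=raw.get("name", "unnamed"),
        max_total=int(raw["max_total"]),
        items=items,
        directions=directions,
    )


def load_scheme(path: Union[str, Path]) -> ScoringScheme:
    """Load and validate a scoring scheme from a JSON file."""
    with open(path) as fh:
        return _scheme_from_dict(json.load(fh))


def default_scheme() -> ScoringScheme:
    """The packaged 37-item scheme with a 127-point healthy-diet maximum."""
    raw = json.loads(
        resources.files("ghrelkit.data").joinpath("diet_scheme.json").read_text()
    )
    scheme = _scheme_from_dict(raw)
    if len(scheme.items) != 37 or scheme.max_total != 127:
        raise ValueError("packaged diet scheme failed its 37-item / 127-point self-check")
    return scheme


def dietary_habits_score(
    response: Mapping[str, str], scheme: Optional[ScoringScheme] = None
) -> float:
    """Score a food-frequency response against a scheme.

    Parameters
    ----------
    response
        Mapping of item id -> frequency category. Must cover every scheme
        item; categories are matched case-insensitively.
    scheme
        Scoring scheme; the packaged default when omitted.

    Returns
    -------
    float
        Sum of per-item points, between the scheme minimum and
        ``scheme.max_total`` (127 for the default scheme).

    Raises
    ------
    KeyError
        If an item is missing from the response, or the response names an
        item unknown to the scheme.
    ValueError
        If a frequency category is not one of the scheme's categories.
    """
    scheme = scheme or default_scheme()
    unknown = set(response) - set(scheme.items)
    if unknown:
        raise KeyError(f"response contains items unknown to the scheme: {sorted(unknown)}")
    score = 0.0
    for item, pts in scheme.items.items():
        if item not in response:
            raise KeyError(f"response is missing item {item!r}")
        cat = _canon(response[item])
        if cat not in pts:
            raise ValueError(
                f"unknown frequency category {response[item]!r} for item {item!r}; "
                f"expected one of {sorted(pts)}"
            )
        score += pts[cat]
    return score


@dataclass(frozen=True)
class ActivityRecord:
    """One reported activity: name, category, weekly hours and MET value."""

    activity: str
    category: str
    hours_per_week: float
    met: float

    def __post_init__(self) -> None:
        if _canon(self.category) not in _ACTIVITY_CATEGORIES:
            raise ValueError(
                f"activity category must be one of {_ACTIVITY_CATEGORIES}, got {self.category!r}"
            )
        if self.hours_per_week < 0:
            raise ValueError("hours_per_week must be >= 0")
        if self.met <= 0:
            raise ValueError("met must be > 0")


def total_activity_hours(records: Iterable[ActivityRecord]) -> float:
    """Total physical activity index in h/week: hours summed over all
    activities in all categories (daily + leisure + athletic)."""
    return float(sum(r.hours_per_week for r in records))


def met_energy(
    records: Sequence[ActivityRecord],
    weight: float,
    mode: str = "paper_literal",
) -> float:
    """Weekly activity energy-consumption index from MET values.

    ``standard`` mode returns Sum(MET x hours x weight) in kcal/week, using
    the convention 1 MET = 1 kcal per kg body weight per hour.
    ``paper_literal`` mode (default) returns Sum(MET x hours) / weight**2,
    the alternative weight-normalised index in MET.h/(week.kg^2); the two
    conventions disagree on units, so both are exposed and the pipeline
    reports both.
    """
    if weight <= 0:
        raise ValueError("weight must be > 0 kg")
    met_hours = sum(r.met * r.hours_per_week for r in records)
    if mode == "standard":
        return float(met_hours * weight)
    if mode == "paper_literal":
        return float(met_hours / weight**2)
    raise ValueError(f"mode must be 'standard' or 'paper_literal', got {mode!r}")
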