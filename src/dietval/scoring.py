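"""Scoring of the 24-item diet-habits questionnaire (DHQ).

Each item offers an ordered ladder of categorical responses mapped to 1–5
points; discretionary items (take-away foods, pastries, processed meat, fried
food) are reverse-scored so that more frequent consumption earns fewer points.
Twenty of the 24 items are scored and grouped into eight sub-scores (cereal,
fruit/vegetables, take-away, fiber, fat, omega-3, food choices, food
preparation); a sub-score is the mean of its items' points (1–5) and the total
is the sum over the 20 scored items (20–100, higher = better diet quality).

The item definitions — ladders, points, reversal flags and sub-score map —
are data, not code: the bundled JSON schema can be replaced by the true
scoring proforma without touching the scorer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

SUB_SCORES = (
    "cereal",
    "fruit_veg",
    "takeaway",
    "fiber",
    "fat",
    "omega3",
    "food_choices",
    "food_preparation",
)

TOTAL_MIN, TOTAL_MAX = 20, 100


@dataclass(frozen=True)
class DhqItem:
    item_id: str
    prompt_class: str
    categories: tuple[str, ...]
    points: tuple[int, ...]
    reversed: bool
    sub_score: str | None
    scored: bool

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.points):
            raise ValueError(f"{self.item_id}: categories/points length mismatch")
        if not all(1 <= p <= 5 for p in self.points):
            raise ValueError(f"{self.item_id}: points must lie in 1..5")
        if min(self.points) != 1 or max(self.points) != 5:
            raise ValueError(f"{self.item_id}: points must attain both 1 and 5")
        if self.scored and self.sub_score not in SUB_SCORES:
            raise ValueError(f"{self.item_id}: unknown sub-score {self.sub_score!r}")


class DhqSchema:
    """Ordered collection of the 24 item definitions."""

    N_ITEMS = 24
    N_SCORED = 20

    def __init__(self, items: list[DhqItem]):
        if len(items) != self.N_ITEMS:
            raise ValueError(f"schema must define {self.N_ITEMS} items, got {len(items)}")
        n_scored = sum(it.scored for it in items)
        if n_scored != self.N_SCORED:
            raise ValueError(f"schema must score {self.N_SCORED} items, got {n_scored}")
        covered = {it.sub_score for it in items if it.scored}
        if covered != set(SUB_SCORES):
            raise ValueError(f"scored items must cover all sub-scores, got {covered}")
        self.items = list(items)
        self._by_id = {it.item_id: it for it in items}

    def __getitem__(self, item_id: str) -> DhqItem:
        return self._by_id[item_id]

    @property
    def scored_items(self) -> list[DhqItem]:
        return [it for it in self.items if it.scored]

    def sub_score_items(self, name: str) -> list[DhqItem]:
        return [it for it in self.items if it.scored and it.sub_score == name]

    @classmethod
    def from_json(cls, source) -> "DhqSchema":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif isinstance(source, (dict, list)):
            doc = source
        else:
            with open(source, encoding="utf-8") as fh:
                doc = json.load(fh)
        items = [
            DhqItem(
                item_id=d["item_id"],
                prompt_class=d["prompt_class"],
                categories=tuple(d["categories"]),
                points=tuple(int(p) for p in d["points"]),
                reversed=bool(d.get("reversed", False)),
                sub_score=d.get("sub_score"),
                scored=bool(d.get("scored", True)),
            )
            for d in doc["items"]
        ]
        return cls(items)

    @classmethod
    def default(cls) -> "DhqSchema":
        with resources.files("dietval.data").joinpath("dhq_schema.json").open(
            encoding="utf-8"
        ) as fh:
            return cls.from_json(fh)


@dataclass
class DhqScore:
    participant_id: str
    item_points: dict[str, int]
    sub_scores: dict[str, float]
    total: float
    quartile: int | None = None


def score_item(item: DhqItem, category: str) -> int:
    """Points (1–5) for one categorical answer; reversed items score 6 − p."""
    try:
        idx = item.categories.index(category)
    except ValueError:
        raise ValueError(
            f"{item.item_id}: unknown category {category!r}; "
            f"valid: {list(item.categories)}"
        ) from None
    pts = item.points[idx]
    return 6 - pts if item.reversed else pts


def score_participant(
    schema: DhqSchema,
    participant_id: str,
    answers: dict[str, str],
    missing: str = "reject",
) -> DhqScore:
    """Score one participant's answers into sub-scores and a 20–100 total.

    ``missing`` policy: ``"reject"`` raises on any unanswered scored item;
    ``"prorate"`` scales the total by 20/answered and averages sub-scores over
    answered items only (a sub-score with no answered item raises).
    """
    if missing not in ("reject", "prorate"):
        raise ValueError(f"unknown missing policy {missing!r}")
    item_points: dict[str, int] = {}
    for it in schema.scored_items:
        if it.item_id in answers:
            item_points[it.item_id] = score_item(it, answers[it.item_id])
        elif missing == "reject":
            raise ValueError(f"{participant_id}: missing answer for {it.item_id}")
    if not item_points:
        raise ValueError(f"{participant_id}: no scored items answered")

    sub_scores: dict[str, float] = {}
    for name in SUB_SCORES:
        pts = [
            item_points[it.item_id]
            for it in schema.sub_score_items(name)
            if it.item_id in item_points
        ]
        if not pts:
            raise ValueError(f"{participant_id}: sub-score {name} has no answered items")
        sub_scores[name] = float(np.mean(pts))

    total = float(sum(item_points.values()))
    if missing == "prorate" and len(item_points) < schema.N_SCORED:
        total *= schema.N_SCORED / len(item_points)
    return DhqScore(participant_id, item_points, sub_scores, total)


def assign_quartiles(totals: np.ndarray | list[float]) -> np.ndarray:
    """Cohort-relative quartiles 1..4 of total scores.

    Cut points are the linear-interpolation 25/50/75 sample percentiles;
    values tied with a cut point fall in the lower quartile (Q1 = lowest
    diet quality).
    """
    totals = np.asarray(totals, dtype=float)
    if totals.size < 4:
        raise ValueError("quartile assignment requires at least 4 participants")
    q1, q2, q3 = np.percentile(totals, [25, 50, 75])
    return (1 + (totals > q1).astype(int) + (totals > q2) + (totals > q3)).astype(int)


def score_cohort(
    schema: DhqSchema, responses: pd.DataFrame, missing: str = "reject"
) -> pd.DataFrame:
    """Score a long-format response table (participant_id, item_id, category).

    Returns one row per participant: total, quartile, and ``sub_<name>``
    columns, ordered by first appearance.
    """
    rows = []
    for pid, sub in responses.groupby("participant_id", sort=False):
        answers = dict(zip(sub["item_id"].astype(str), sub["category"].astype(str)))
        s = score_participant(schema, str(pid), answers, missing=missing)
        row = {"participant_id": s.participant_id, "total": s.total}
        row.update({f"sub_{k}": v for k, v in s.sub_scores.items()})
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["quartile"] = assign_quartiles(frame["total"].to_numpy())
    return frame
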