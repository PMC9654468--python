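"""Food composition: recall records to daily nutrient totals and guideline serves.

A composition table maps each food code to energy/nutrient densities (per
100 g), guideline-group serve weights (grams of each of the five core food
groups contributed per 100 g of food), a hierarchical major-group code, and a
discretionary flag.  Composite foods (mixed dishes) carry a recipe — a list of
(component code, mass fraction) — and are recursively deconstructed before
nutrients and serves are accumulated, so that e.g. a casserole contributes to
the vegetable and meat groups through its ingredients.

All densities and serve weights share a single per-100-g linear basis, so day
totals are plain weighted sums and scale linearly with grams consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GUIDELINE_GROUPS = ("vegetables", "fruits", "grains", "milk_alt", "meat_alt")

#: kJ defining one serve of a discretionary food.
KJ_PER_DISCRETIONARY_SERVE = 600.0
#: grams of ethanol defining one serve of an alcoholic beverage.
ALCOHOL_G_PER_SERVE = 10.0


class UnknownFoodError(KeyError):
    """A recall record or recipe references a food code absent from the table."""


class RecipeCycleError(ValueError):
    """Composite deconstruction encountered a cyclic recipe graph."""


@dataclass(frozen=True)
class FoodEntry:
    food_code: str
    description: str = ""
    major_group_code: str = "00"
    energy_kj_per_100g: float = 0.0
    nutrient_densities: dict[str, float] = field(default_factory=dict)
    serve_weights: dict[str, float] = field(default_factory=dict)
    discretionary: bool = False
    components: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.energy_kj_per_100g < 0:
            raise ValueError(f"{self.food_code}: negative energy density")
        for name, dens in self.nutrient_densities.items():
            if dens < 0:
                raise ValueError(f"{self.food_code}: negative density for {name!r}")
        if self.components:
            total = sum(frac for _, frac in self.components)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.food_code}: component mass fractions sum to {total!r}, not 1"
                )


@dataclass(frozen=True)
class RecallRecord:
    participant_id: str
    day_index: int
    food_code: str
    grams: float
    day_type: str = "week"

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise ValueError(
                f"{self.participant_id} day {self.day_index}: negative grams"
            )


@dataclass
class DayIntake:
    participant_id: str
    day_index: int
    energy_kj: float
    nutrients: dict[str, float]
    group_serves: dict[str, float]
    discretionary_serves: float
    group_grams: dict[str, float]


class CompositionTable:
    """Lookup of :class:`FoodEntry` by food code, with recipe resolution."""

    def __init__(self, entries: list[FoodEntry]):
        self._entries = {e.food_code: e for e in entries}
        for entry in entries:
            for code, _ in entry.components:
                if code not in self._entries:
                    raise UnknownFoodError(
                        f"component {code!r} of {entry.food_code!r} not in table"
                    )

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, code: str) -> FoodEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise UnknownFoodError(f"unknown food code {code!r}") from None

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_frames(
        cls, foods: pd.DataFrame, components: pd.DataFrame | None = None
    ) -> "CompositionTable":
        """Build a table from a foods frame and optional recipe frame.

        ``foods`` columns: food_code, description, major_group_code,
        energy_kj_per_100g, discretionary, one ``nutrient_<name>`` column per
        nutrient density and one ``serve_<group>`` column per guideline group.
        ``components`` columns: parent_code, component_code, fraction.
        """
        nut_cols = [c for c in foods.columns if c.startswith("nutrient_")]
        serve_cols = [c for c in foods.columns if c.startswith("serve_")]
        recipes: dict[str, list[tuple[str, float]]] = {}
        if components is not None and len(components):
            for parent, sub in components.groupby("parent_code", sort=False):
                recipes[str(parent)] = [
                    (str(r.component_code), float(r.fraction))
                    for r in sub.itertuples()
                ]
        entries = []
        for row in foods.itertuples():
            code = str(row.food_code)
            entries.append(
                FoodEntry(
                    food_code=code,
                    description=str(getattr(row, "description", "")),
                    major_group_code=str(row.major_group_code),
                    energy_kj_per_100g=float(row.energy_kj_per_100g),
                    nutrient_densities={
                        c[len("nutrient_"):]: float(getattr(row, c)) for c in nut_cols
                    },
                    serve_weights={
                        c[len("serve_"):]: float(getattr(row, c)) for c in serve_cols
                    },
                    discretionary=bool(row.discretionary),
                    components=tuple(recipes.get(code, ())),
                )
            )
        return cls(entries)

    @classmethod
    def from_csv(cls, foods_path, components_path=None) -> "CompositionTable":
        foods = pd.read_csv(foods_path, dtype={"food_code": str, "major_group_code": str})
        comps = None
        if components_path is not None:
            comps = pd.read_csv(
                components_path, dtype={"parent_code": str, "component_code": str}
            )
        return cls.from_frames(foods, comps)


def deconstruct(
    entry: FoodEntry, grams: float, table: CompositionTable
) -> list[tuple[str, float]]:
    """Recursively expand a composite food into (terminal code, grams) parts.

    Mass is conserved: the returned grams sum to the input grams.  Foods
    without a recipe return themselves unchanged.
    """
    out: list[tuple[str, float]] = []

    def _expand(code: str, g: float, stack: tuple[str, ...]) -> None:
        if code in stack:
            raise RecipeCycleError(
                f"cyclic recipe: {' -> '.join(stack + (code,))}"
            )
        e = table.get(code)
        if not e.components:
            out.append((code, g))
            return
        for sub_code, frac in e.components:
            _expand(sub_code, g * frac, stack + (code,))

    _expand(entry.food_code, grams, ())
    return out


def day_intake(
    records: list[RecallRecord],
    table: CompositionTable,
    include_alcohol_serves: bool = True,
    alcohol_nutrient: str = "alcohol",
) -> DayIntake:
    """Aggregate one participant-day of recall records into a :class:`DayIntake`.

    Nutrients, energy, guideline-group serves and discretionary serves are
    accumulated over *deconstructed* (terminal) foods; major-group gram totals
    use each food as reported, without deconstruction, since data-driven
    pattern analysis operates on foods as consumed.
    """
    pid = records[0].participant_id if records else ""
    day = records[0].day_index if records else 0
    energy = 0.0
    nutrients: dict[str, float] = {}
    serves = {g: 0.0 for g in GUIDELINE_GROUPS}
    group_grams: dict[str, float] = {}
    disc_kj = 0.0
    alcohol_g = 0.0

    for rec in records:
        if rec.participant_id != pid or rec.day_index != day:
            raise ValueError("day_intake expects records from a single participant-day")
        if rec.grams < 0:
            raise ValueError("negative grams")
        as_reported = table.get(rec.food_code)
        group_grams[as_reported.major_group_code] = (
            group_grams.get(as_reported.major_group_code, 0.0) + rec.grams
        )
        for code, g in deconstruct(as_reported, rec.grams, table):
            e = table.get(code)
            energy += g * e.energy_kj_per_100g / 100.0
            for name, dens in e.nutrient_densities.items():
                nutrients[name] = nutrients.get(name, 0.0) + g * dens / 100.0
            for grp, w in e.serve_weights.items():
                if grp in serves:
                    serves[grp] += g * w / 100.0
            contains_alcohol = e.nutrient_densities.get(alcohol_nutrient, 0.0) > 0
            if e.discretionary and not (contains_alcohol and include_alcohol_serves):
                # alcoholic drinks count through their alcohol mass, not
                # their energy: one serve is 600 kJ OR 10 g alcohol
                disc_kj += g * e.energy_kj_per_100g / 100.0
            alcohol_g += g * e.nutrient_densities.get(alcohol_nutrient, 0.0) / 100.0

    disc_serves = disc_kj / KJ_PER_DISCRETIONARY_SERVE
    if include_alcohol_serves:
        disc_serves += alcohol_g / ALCOHOL_G_PER_SERVE
    return DayIntake(
        participant_id=pid,
        day_index=day,
        energy_kj=energy,
        nutrients=nutrients,
        group_serves=serves,
        discretionary_serves=disc_serves,
        group_grams=group_grams,
    )


def discretionary_serves(
    disc_kj: float, alcohol_g: float, include_alcohol: bool = True
) -> float:
    """Serves of discretionary food: 600 kJ of discretionary-flagged energy or
    10 g of ethanol per serve."""
    if disc_kj < 0 or alcohol_g < 0:
        raise ValueError("discretionary energy and alcohol mass must be >= 0")
    serves = disc_kj / KJ_PER_DISCRETIONARY_SERVE
    if include_alcohol:
        serves += alcohol_g / ALCOHOL_G_PER_SERVE
    return serves


def recalls_from_frame(frame: pd.DataFrame) -> dict[tuple[str, int], list[RecallRecord]]:
    """Group a recall table (participant_id, day_index, day_type, food_code,
    grams) into per participant-day record lists, insertion-ordered."""
    out: dict[tuple[str, int], list[RecallRecord]] = {}
    for row in frame.itertuples():
        rec = RecallRecord(
            participant_id=str(row.participant_id),
            day_index=int(row.day_index),
            food_code=str(row.food_code),
            grams=float(row.grams),
            day_type=str(getattr(row, "day_type", "week")),
        )
        out.setdefault((rec.participant_id, rec.day_index), []).append(rec)
    return out


def day_intake_frame(
    recalls: pd.DataFrame,
    table: CompositionTable,
    include_alcohol_serves: bool = True,
) -> pd.DataFrame:
    """Compute a tidy per participant-day intake table.

    Columns: participant_id, day_index, day_type, energy_kj,
    ``nutrient_<name>``, ``serves_<group>``, serves_discretionary, and
    ``grams_<major_group_code>``.  Missing nutrients/groups are zero.
    """
    grouped = recalls_from_frame(recalls)
    rows = []
    for (pid, day), records in grouped.items():
        di = day_intake(records, table, include_alcohol_serves=include_alcohol_serves)
        row: dict[str, object] = {
            "participant_id": pid,
            "day_index": day,
            "day_type": records[0].day_type,
            "energy_kj": di.energy_kj,
        }
        row.update({f"nutrient_{k}": v for k, v in di.nutrients.items()})
        row.update({f"serves_{k}": v for k, v in di.group_serves.items()})
        row["serves_discretionary"] = di.discretionary_serves
        row.update({f"grams_{k}": v for k, v in di.group_grams.items()})
        rows.append(row)
    frame = pd.DataFrame(rows).fillna(0.0)
    if len(frame):
        lead = ["participant_id", "day_index", "day_type", "energy_kj"]
        rest = sorted(c for c in frame.columns if c not in lead)
        frame = frame[lead + rest]
    return frame
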