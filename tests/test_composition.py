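"""Recall records → daily nutrients, serves and gram totals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietval.composition import (
    CompositionTable,
    FoodEntry,
    RecallRecord,
    RecipeCycleError,
    UnknownFoodError,
    day_intake,
    day_intake_frame,
    deconstruct,
    discretionary_serves,
)


def _table(entries):
    return CompositionTable(entries)


@pytest.fixture()
def basic_table():
    veg = FoodEntry("veg", major_group_code="24", energy_kj_per_100g=150,
                    nutrient_densities={"fiber": 3.5},
                    serve_weights={"vegetables": 4 / 3})
    cereal = FoodEntry("cereal", major_group_code="12", energy_kj_per_100g=1200,
                       nutrient_densities={"fiber": 8.0},
                       serve_weights={"grains": 2.5})
    comp = FoodEntry("dish", major_group_code="13",
                     components=(("veg", 0.5), ("cereal", 0.5)))
    return _table([veg, cereal, comp])


class TestDeconstruct:
    def test_mass_fraction_split(self, basic_table):
        parts = dict(deconstruct(basic_table.get("dish"), 200.0, basic_table))
        assert parts == {"veg": 100.0, "cereal": 100.0}

    def test_identity_for_terminal_food(self, basic_table):
        assert deconstruct(basic_table.get("veg"), 100.0, basic_table) == [("veg", 100.0)]

    def test_nested_expansion_by_hand(self):
        # A = 50% B + 50% E;  B = 50% C + 50% D;  80 g A → E 40, C 20, D 20
        entries = [
            FoodEntry("C"), FoodEntry("D"), FoodEntry("E"),
            FoodEntry("B", components=(("C", 0.5), ("D", 0.5))),
            FoodEntry("A", components=(("B", 0.5), ("E", 0.5))),
        ]
        table = _table(entries)
        parts = dict(deconstruct(table.get("A"), 80.0, table))
        assert parts == pytest.approx({"C": 20.0, "D": 20.0, "E": 40.0})
        assert sum(parts.values()) == pytest.approx(80.0)

    def test_cycle_detection(self):
        entries = [
            FoodEntry("x", components=(("y", 1.0),)),
            FoodEntry("y", components=(("x", 1.0),)),
        ]
        table = _table(entries)
        with pytest.raises(RecipeCycleError):
            deconstruct(table.get("x"), 10.0, table)

    def test_missing_component_named_in_error(self):
        with pytest.raises(UnknownFoodError, match="ghost"):
            _table([FoodEntry("a", components=(("ghost", 1.0),))])

    @given(
        fractions=st.lists(
            st.floats(min_value=0.05, max_value=1.0), min_size=2, max_size=5
        ),
        grams=st.floats(min_value=0.1, max_value=5000),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_conservation_randomized(self, fractions, grams):
        fr = np.asarray(fractions)
        fr = fr / fr.sum()
        terminals = [FoodEntry(f"t{i}") for i in range(len(fr))]
        parent = FoodEntry(
            "p", components=tuple((f"t{i}", float(f)) for i, f in enumerate(fr))
        )
        table = _table(terminals + [parent])
        parts = deconstruct(table.get("p"), grams, table)
        assert sum(g for _, g in parts) == pytest.approx(grams, rel=1e-9)


class TestDayIntake:
    def _records(self, *pairs):
        return [RecallRecord("p1", 1, code, g) for code, g in pairs]

    def test_vegetable_serves_150g_at_75g_per_serve(self, basic_table):
        di = day_intake(self._records(("veg", 150.0)), basic_table)
        assert di.group_serves["vegetables"] == pytest.approx(2.0)

    def test_empty_day_is_all_zero(self, basic_table):
        di = day_intake([], basic_table)
        assert di.energy_kj == 0.0
        assert all(v == 0.0 for v in di.group_serves.values())
        assert di.discretionary_serves == 0.0

    def test_nutrients_add_linearly(self, basic_table):
        di = day_intake(self._records(("veg", 100.0), ("cereal", 100.0)), basic_table)
        assert di.nutrients["fiber"] == pytest.approx(3.5 + 8.0)

    def test_composite_contributes_through_components(self, basic_table):
        di = day_intake(self._records(("dish", 200.0)), basic_table)
        # 100 g veg + 100 g cereal after deconstruction
        assert di.energy_kj == pytest.approx(150.0 + 1200.0)
        assert di.group_serves["vegetables"] == pytest.approx(4 / 3)
        assert di.group_serves["grains"] == pytest.approx(2.5)
        # gram totals stay with the as-consumed dish's major group
        assert di.group_grams == {"13": 200.0}

    def test_doubling_grams_doubles_everything(self, basic_table):
        one = day_intake(self._records(("dish", 120.0), ("veg", 80.0)), basic_table)
        two = day_intake(self._records(("dish", 240.0), ("veg", 160.0)), basic_table)
        assert two.energy_kj == pytest.approx(2 * one.energy_kj)
        for k in one.nutrients:
            assert two.nutrients[k] == pytest.approx(2 * one.nutrients[k])
        for k in one.group_serves:
            assert two.group_serves[k] == pytest.approx(2 * one.group_serves[k])

    def test_unknown_food_code(self, basic_table):
        with pytest.raises(UnknownFoodError):
            day_intake(self._records(("nope", 10.0)), basic_table)

    def test_negative_grams_rejected(self):
        with pytest.raises(ValueError):
            RecallRecord("p1", 1, "veg", -5.0)


class TestDiscretionary:
    def test_energy_only(self):
        assert discretionary_serves(1500.0, 0.0) == pytest.approx(2.5)

    def test_alcohol_only(self):
        assert discretionary_serves(0.0, 25.0) == pytest.approx(2.5)

    def test_combined(self):
        assert discretionary_serves(600.0, 10.0) == pytest.approx(2.0)

    def test_alcohol_excluded_when_configured(self):
        assert discretionary_serves(600.0, 10.0, include_alcohol=False) == pytest.approx(1.0)

    def test_component_inherits_own_discretionary_flag(self):
        # a non-discretionary dish with a discretionary ingredient still
        # accrues discretionary energy from that ingredient
        sweet = FoodEntry("sweet", energy_kj_per_100g=2000, discretionary=True)
        plain = FoodEntry("plain", energy_kj_per_100g=400)
        dish = FoodEntry("dish", components=(("sweet", 0.25), ("plain", 0.75)))
        table = _table([sweet, plain, dish])
        di = day_intake([RecallRecord("p", 1, "dish", 100.0)], table)
        assert di.discretionary_serves == pytest.approx(25 * 20.0 / 600.0)


def test_day_intake_frame_tidy_columns(small_cohort, small_table):
    frame = day_intake_frame(small_cohort.recalls, small_table)
    assert {"participant_id", "day_index", "day_type", "energy_kj"} <= set(frame.columns)
    assert (frame.select_dtypes("number") >= 0).all().all()
    # one row per participant-day present in the recalls
    expect = small_cohort.recalls.groupby(["participant_id", "day_index"]).ngroups
    assert len(frame) == expect
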