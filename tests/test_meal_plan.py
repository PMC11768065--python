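"""Meal plans: validation, JSON dialect, aggregation arithmetic and scaling."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dqii import (
    FoodLookupError,
    MealItem,
    MealPlan,
    ValidationError,
    aggregate_intake,
    read_meal_plans,
    write_meal_plans,
)


def make_plan(items, plan_id="p1", sex="female", kcal=1500.0, source="test"):
    return MealPlan(
        plan_id=plan_id, source=source, sex=sex, age_years=35,
        requested_kcal=kcal, items=tuple(items),
    )


class TestValidation:
    def test_zero_portion_rejected(self):
        with pytest.raises(ValidationError, match="portion_g"):
            MealItem(food_id="apple_raw", portion_g=0.0, meal_slot="lunch")

    def test_unknown_slot_and_sex_rejected(self):
        with pytest.raises(ValidationError, match="meal_slot"):
            MealItem(food_id="apple_raw", portion_g=10, meal_slot="brunch")
        with pytest.raises(ValidationError, match="sex"):
            make_plan([MealItem("apple_raw", 10, "lunch")], sex="unknown")

    def test_nonpositive_kcal_rejected(self):
        with pytest.raises(ValidationError, match="requested_kcal"):
            make_plan([MealItem("apple_raw", 10, "lunch")], kcal=0)


class TestJsonDialect:
    def test_round_trip_preserves_order_and_fields(self, tmp_path):
        plans = [
            make_plan([MealItem("apple_raw", 150, "breakfast")], plan_id="a"),
            make_plan([MealItem("cod_cooked", 90, "dinner"),
                       MealItem("spinach_raw", 80, "dinner")], plan_id="b", sex="male"),
        ]
        path = write_meal_plans(plans, tmp_path / "plans.json", study_meta={"note": "x"})
        again = read_meal_plans(path)
        assert again == plans

    def test_single_plan_file(self, tmp_path):
        path = write_meal_plans([make_plan([MealItem("apple_raw", 1, "snack1")])],
                                tmp_path / "one.json")
        assert len(read_meal_plans(path)) == 1

    def test_invalid_portion_in_file_rejected(self, tmp_path):
        doc = {"plans": [{"plan_id": "x", "source": "s", "sex": "female",
                          "age_years": 35, "requested_kcal": 1400,
                          "items": [{"food_id": "apple_raw", "portion_g": 0,
                                     "meal_slot": "lunch"}]}]}
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="portion_g"):
            read_meal_plans(p)


class TestAggregation:
    def test_identity_and_linear_scaling(self, food_table):
        # apple_raw energy per 100 g is its Atwater value: 48.6 kcal
        one = aggregate_intake(make_plan([MealItem("apple_raw", 100, "lunch")]), food_table)
        assert one.energy_kcal_generated == pytest.approx(48.6)
        one_and_half = aggregate_intake(
            make_plan([MealItem("apple_raw", 150, "lunch")]), food_table
        )
        assert one_and_half.energy_kcal_generated == pytest.approx(48.6 * 1.5)

    def test_three_item_plan_matches_hand_summed_totals(self, food_table):
        # hand-summed from the packaged CSV rows:
        # 120 g chicken: P 37.2, F 4.32; 200 g rice: P 5.2, C 42.4, F 1.8, fib 3.6
        # 150 g broccoli: P 4.2, C 6.0, F 0.6, fib 3.9, vitC 133.8
        plan = make_plan([
            MealItem("chicken_breast_grilled", 120, "lunch"),
            MealItem("brown_rice_cooked", 200, "lunch"),
            MealItem("broccoli_raw", 150, "dinner"),
        ])
        intake = aggregate_intake(plan, food_table)
        assert intake.totals.protein_g == pytest.approx(37.2 + 5.2 + 4.2)
        assert intake.totals.carbohydrate_g == pytest.approx(0.0 + 42.4 + 6.0)
        assert intake.totals.total_fat_g == pytest.approx(4.32 + 1.8 + 0.6)
        assert intake.totals.fibre_g == pytest.approx(3.6 + 3.9)
        assert intake.totals.vitamin_c_mg == pytest.approx(133.8)
        assert intake.servings["grains"] == pytest.approx(200 / 80)
        assert intake.servings["vegetables"] == pytest.approx(150 / 80)
        assert intake.groups_present == {"meat_poultry_fish_egg", "grains", "vegetables"}
        assert intake.protein_sources_present == {"poultry"}

    def test_macro_energy_shares_sum_to_100(self, food_table):
        plan = make_plan([MealItem("salmon_atlantic_cooked", 120, "dinner"),
                          MealItem("quinoa_cooked", 180, "dinner")])
        intake = aggregate_intake(plan, food_table)
        total = intake.pct_energy_carb + intake.pct_energy_protein + intake.pct_energy_fat
        assert total == pytest.approx(100.0, abs=1e-6)
        assert intake.pct_energy_sfa <= intake.pct_energy_fat

    def test_ratios_absent_when_no_saturated_fat(self, food_table):
        intake = aggregate_intake(make_plan([MealItem("water_still", 500, "snack1")]),
                                  food_table)
        assert intake.pufa_to_sfa is None and intake.mufa_to_sfa is None
        assert intake.pct_energy_carb == 0.0  # zero-energy day, defined as 0

    def test_unresolvable_food_names_plan_and_food(self, food_table):
        plan = make_plan([MealItem("dragonfruit", 50, "lunch")], plan_id="px")
        with pytest.raises(FoodLookupError, match="px.*dragonfruit"):
            aggregate_intake(plan, food_table)

    def test_additivity_over_plan_union(self, food_table):
        a = make_plan([MealItem("apple_raw", 130, "lunch")])
        b = make_plan([MealItem("lentils_cooked", 210, "dinner")])
        ab = make_plan(list(a.items) + list(b.items))
        ia, ib, iab = (aggregate_intake(p, food_table) for p in (a, b, ab))
        assert iab.totals.protein_g == pytest.approx(ia.totals.protein_g + ib.totals.protein_g)
        assert iab.totals.energy_kcal == pytest.approx(
            ia.totals.energy_kcal + ib.totals.energy_kcal
        )
        assert iab.groups_present == ia.groups_present | ib.groups_present

    @settings(deadline=None, max_examples=30)
    @given(k=st.floats(min_value=0.1, max_value=10.0, allow_nan=False))
    def test_portion_scaling_preserves_shares_and_sets(self, food_table, k):
        base_items = [MealItem("salmon_atlantic_cooked", 100, "dinner"),
                      MealItem("brown_rice_cooked", 150, "dinner"),
                      MealItem("spinach_raw", 80, "lunch")]
        base = aggregate_intake(make_plan(base_items), food_table)
        scaled = aggregate_intake(
            make_plan([MealItem(i.food_id, i.portion_g * k, i.meal_slot) for i in base_items]),
            food_table,
        )
        assert scaled.totals.energy_kcal == pytest.approx(base.totals.energy_kcal * k)
        assert scaled.pct_energy_carb == pytest.approx(base.pct_energy_carb)
        assert scaled.pct_energy_sfa == pytest.approx(base.pct_energy_sfa)
        assert scaled.pufa_to_sfa == pytest.approx(base.pufa_to_sfa)
        assert scaled.groups_present == base.groups_present
        assert scaled.protein_sources_present == base.protein_sources_present
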