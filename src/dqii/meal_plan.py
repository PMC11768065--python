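"""Structured daily meal plans and their aggregation into a daily intake.

A :class:`MealPlan` is one day's plan as a chatbot (or the synthetic
generator) would emit it after structuring: request metadata (source label,
sex, age, requested kcal) plus an ordered list of items, each a food-table
reference with a portion in grams and a meal slot.

:func:`aggregate_intake` turns a plan into a :class:`DailyIntake`: absolute
nutrient totals, macronutrient energy shares, fatty-acid ratios, servings per
variety group and the presence sets that drive the DQI-I variety scores.

Energy-share convention
-----------------------
Percentages of energy use the Atwater-computed energy (4·protein + 4·carb +
9·fat kcal) as the denominator, so carbohydrate + protein + fat shares sum to
exactly 100.  The composition table's ``energy_kcal`` is used only for the
caloric-accuracy audit, where the question is what a label would say.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FoodLookupError, ValidationError
from .food_composition import (
    SCORED_GROUPS,
    FoodTable,
    NutrientProfile,
)

__all__ = [
    "MEAL_SLOTS",
    "SEXES",
    "MealItem",
    "MealPlan",
    "DailyIntake",
    "aggregate_intake",
    "read_meal_plans",
    "write_meal_plans",
]

MEAL_SLOTS = ("breakfast", "lunch", "dinner", "snack1", "snack2", "snack3")
SEXES = ("female", "male")


@dataclass(frozen=True)
class MealItem:
    """One plan line: a food, a portion in grams, and a meal slot."""

    food_id: str
    portion_g: float
    meal_slot: str

    def __post_init__(self) -> None:
        if not self.portion_g > 0:
            raise ValidationError(
                f"portion_g must be > 0, got {self.portion_g!r} for {self.food_id!r}"
            )
        if self.meal_slot not in MEAL_SLOTS:
            raise ValidationError(
                f"unknown meal_slot {self.meal_slot!r} (expected one of {MEAL_SLOTS})"
            )


@dataclass(frozen=True)
class MealPlan:
    """One day's structured plan plus the request that produced it."""

    plan_id: str
    source: str
    sex: str
    age_years: int
    requested_kcal: float
    items: tuple[MealItem, ...]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"{self.plan_id}: unknown sex {self.sex!r}")
        if not self.requested_kcal > 0:
            raise ValidationError(
                f"{self.plan_id}: requested_kcal must be > 0, got {self.requested_kcal}"
            )
        object.__setattr__(self, "items", tuple(self.items))

    def to_dict(self) -> dict:
        return {
            "plan_id": self.plan_id,
            "source": self.source,
            "sex": self.sex,
            "age_years": self.age_years,
            "requested_kcal": self.requested_kcal,
            "items": [
                {"food_id": it.food_id, "portion_g": it.portion_g, "meal_slot": it.meal_slot}
                for it in self.items
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MealPlan":
        try:
            items = tuple(
                MealItem(
                    food_id=str(it["food_id"]),
                    portion_g=float(it["portion_g"]),
                    meal_slot=str(it["meal_slot"]),
                )
                for it in d["items"]
            )
            return cls(
                plan_id=str(d["plan_id"]),
                source=str(d["source"]),
                sex=str(d["sex"]),
                age_years=int(d["age_years"]),
                requested_kcal=float(d["requested_kcal"]),
                items=items,
            )
        except KeyError as exc:
            raise ValidationError(f"meal plan missing field {exc}") from None


@dataclass(frozen=True)
class DailyIntake:
    """Aggregated one-day intake: totals, energy shares, ratios, presence sets.

    ``pufa_to_sfa`` / ``mufa_to_sfa`` are ``None`` (absent, never infinite)
    when the day contains no saturated fat; a zero-energy day reports all
    energy shares as 0.
    """

    totals: NutrientProfile
    energy_kcal_generated: float
    atwater_kcal: float
    pct_energy_carb: float
    pct_energy_protein: float
    pct_energy_fat: float
    pct_energy_sfa: float
    pct_energy_empty: float
    pufa_to_sfa: float | None
    mufa_to_sfa: float | None
    servings: Mapping[str, float] = field(default_factory=dict)
    groups_present: frozenset[str] = frozenset()
    protein_sources_present: frozenset[str] = frozenset()


def aggregate_intake(plan: MealPlan, table: FoodTable) -> DailyIntake:
    """Aggregate a plan's items into a :class:`DailyIntake`.

    Each total is Σ portion_g/100 × per-100 g value; servings per variety
    group are Σ portion_g / serving_size_g over that group's items.  A food
    group or protein source counts as present as soon as any item with
    positive portion belongs to it.
    """
    totals = NutrientProfile.zero()
    empty_atwater = 0.0
    servings: dict[str, float] = {g: 0.0 for g in SCORED_GROUPS}
    groups: set[str] = set()
    sources: set[str] = set()

    for item in plan.items:
        try:
            rec = table.lookup(item.food_id)
        except FoodLookupError:
            raise FoodLookupError(
                f"plan {plan.plan_id!r}: unknown food_id {item.food_id!r}"
            ) from None
        factor = item.portion_g / 100.0
        contrib = rec.nutrients.scaled(factor)
        totals = totals + contrib
        if rec.empty_calorie:
            empty_atwater += contrib.atwater_kcal()
        groups.add(rec.variety_group)
        if rec.protein_source != "none":
            sources.add(rec.protein_source)
        if rec.variety_group in servings:
            servings[rec.variety_group] += item.portion_g / rec.serving_size_g

    atwater = totals.atwater_kcal()
    if atwater > 0:
        pct_carb = 100.0 * 4.0 * totals.carbohydrate_g / atwater
        pct_protein = 100.0 * 4.0 * totals.protein_g / atwater
        pct_fat = 100.0 * 9.0 * totals.total_fat_g / atwater
        pct_sfa = 100.0 * 9.0 * totals.saturated_fat_g / atwater
        pct_empty = 100.0 * empty_atwater / atwater
    else:
        pct_carb = pct_protein = pct_fat = pct_sfa = pct_empty = 0.0

    sfa = totals.saturated_fat_g
    pufa_to_sfa = totals.pufa_g / sfa if sfa > 0 else None
    mufa_to_sfa = totals.mufa_g / sfa if sfa > 0 else None

    return DailyIntake(
        totals=totals,
        energy_kcal_generated=totals.energy_kcal,
        atwater_kcal=atwater,
        pct_energy_carb=pct_carb,
        pct_energy_protein=pct_protein,
        pct_energy_fat=pct_fat,
        pct_energy_sfa=pct_sfa,
        pct_energy_empty=pct_empty,
        pufa_to_sfa=pufa_to_sfa,
        mufa_to_sfa=mufa_to_sfa,
        servings=servings,
        groups_present=frozenset(groups),
        protein_sources_present=frozenset(sources),
    )


def read_meal_plans(path: str | Path) -> list[MealPlan]:
    """Read the meal-plan JSON dialect: ``{"study": {...}, "plans": [...]}``.

    The top-level ``study`` block is optional free-form metadata; ``plans``
    is an ordered array.  Plan ordering is preserved.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if isinstance(doc, list):  # bare array accepted
        raw_plans: Sequence[Mapping] = doc
    else:
        if "plans" not in doc:
            raise ValidationError(f"{path.name}: document has no 'plans' array")
        raw_plans = doc["plans"]
    return [MealPlan.from_dict(d) for d in raw_plans]


def write_meal_plans(
    plans: Iterable[MealPlan], path: str | Path, study_meta: Mapping | None = None
) -> Path:
    """Write plans in the JSON dialect (round-trips with read_meal_plans)."""
    path = Path(path)
    doc = {"study": dict(study_meta or {}), "plans": [p.to_dict() for p in plans]}
    with path.open("w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, ensure_ascii=False)
        fh.write("\n")
    return path
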