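"""Synthetic meal-plan generator with prescribed statistical properties.

The study this package analyses scored one-day weight-loss plans produced by
three chatbots over a 3 sources × 5 calorie levels (1400–1800 kcal, step
100) × 2 sexes grid; the raw plans themselves are unpublished.  This module
generates structured plans with *controllable* properties — caloric
deviation, food-group coverage, protein-source count, per-component adequacy
fractions, macronutrient energy shares, fatty-acid ratios and moderation
bands — so that every pipeline stage can be exercised and its parameter
recovery verified against generator ground truth.

Construction
------------
Each plan is assembled from the packaged reference food table in closed
form:

1. pick one representative food per requested variety group and protein
   source (seeded RNG; a deterministic "lean" fallback retries with
   low-carbohydrate / low-saturated-fat representatives if the random pick
   is infeasible);
2. set vegetable/fruit/grain portions from the prescribed adequacy
   fractions (portion = fraction × target servings × serving size);
3. top up fibre, iron, calcium, vitamin C, sodium and cholesterol with
   zero-energy supplement foods to the prescribed fractions / moderation
   band representatives;
4. solve the remaining protein, fatty-acid and carbohydrate masses exactly
   using a protein isolate, three oils of linearly independent fatty-acid
   composition (a 3×3 solve), sugar (the empty-calorie carrier) and a
   carbohydrate powder, so that the Atwater energy equals
   ``requested_kcal × (1 + deviation/100)`` and the macronutrient shares hit
   the target.

Any binding constraint that cannot be satisfied raises
:class:`~dqii.errors.FeasibilityError` naming the constraint.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .caloric_accuracy import classify_deviation
from .errors import FeasibilityError, ValidationError
from .food_composition import SCORED_GROUPS, FoodRecord, FoodTable
from .meal_plan import MEAL_SLOTS, MealItem, MealPlan, aggregate_intake
from .scoring_config import ScoringConfig, default_config
from .dqi_scorer import (
    score_balance,
    score_variety_food_groups,
    score_variety_protein_sources,
)

__all__ = [
    "MODERATION_BANDS",
    "PlanSpec",
    "StudySpec",
    "StudyResult",
    "generate_plan",
    "generate_plan_with_truth",
    "generate_study",
    "default_study_spec",
    "derive_cell_seed",
]

#: Names of the moderation bands a PlanSpec may request, best to worst.
MODERATION_BANDS = ("strict", "mid", "high")

#: Representative value targeted inside each band (units of the component).
_BAND_REPS = {
    "saturated_fat": (5.5, 8.5, 12.0),  # %E
    "cholesterol": (220.0, 350.0, 480.0),  # mg/day
    "sodium": (1800.0, 2900.0, 3900.0),  # mg/day
    "empty_calorie": (2.0, 6.0, 12.0),  # %E
}

_PROTEIN_GROUPS = ("meat_poultry_fish_egg", "dairy_beans")
_SERVING_GROUPS = ("vegetables", "fruits", "grains")

#: Adequacy components whose delivered fraction the generator controls
#: directly (protein follows from the macronutrient target instead).
CONTROLLED_ADEQUACY = (
    "vegetables",
    "fruit",
    "grains",
    "fibre",
    "iron",
    "calcium",
    "vitamin_c",
)

_GROUP_TO_COMPONENT = {"vegetables": "vegetables", "fruits": "fruit", "grains": "grains"}

# adjuster foods in the reference table
_OILS = ("coconut_oil", "olive_oil", "sunflower_oil")
_SUPPLEMENTS = {
    "fibre": "inulin_fibre",
    "iron": "iron_premix",
    "calcium": "calcium_premix",
    "vitamin_c": "vitamin_c_powder",
}
_SUPPLEMENT_FIELD = {
    "fibre": "fibre_g",
    "iron": "iron_mg",
    "calcium": "calcium_mg",
    "vitamin_c": "vitamin_c_mg",
}


def _normalise_fractions(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        frac = {k: float(v) for k, v in value.items() if k in CONTROLLED_ADEQUACY}
        missing = set(CONTROLLED_ADEQUACY) - set(frac)
        if missing:
            raise ValidationError(f"adequacy_fraction missing components {sorted(missing)}")
    else:
        frac = {k: float(value) for k in CONTROLLED_ADEQUACY}
    for k, v in frac.items():
        if v < 0:
            raise ValidationError(f"adequacy_fraction[{k!r}] must be >= 0")
    return frac


@dataclass(frozen=True)
class PlanSpec:
    """Prescription for one synthetic plan.

    ``adequacy_fraction`` may be a scalar applied to every controllable
    component or a per-component mapping; the protein component is governed
    by ``macro_target`` (its energy share times the Atwater energy), not by
    a fraction.  ``moderation_profile`` names the intended band per
    component among {"strict", "mid", "high"}; the total-fat band follows
    from the fat share of ``macro_target``, and when ``fatty_acid_target``
    is given the saturated-fat share follows from the fat budget and the
    ratios.
    """

    source: str
    sex: str
    age_years: int = 35
    requested_kcal: float = 1600.0
    target_deviation_pct: float = 0.0
    groups_to_cover: frozenset[str] = frozenset(SCORED_GROUPS)
    n_protein_sources: int = 3
    adequacy_fraction: Mapping[str, float] | float = 1.0
    macro_target: tuple[float, float, float] = (55.0, 15.0, 30.0)
    fatty_acid_target: tuple[float, float] | None = None
    moderation_profile: Mapping[str, str] = field(
        default_factory=lambda: {
            "saturated_fat": "strict",
            "cholesterol": "strict",
            "sodium": "strict",
            "empty_calorie": "strict",
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.requested_kcal > 0:
            raise ValidationError("requested_kcal must be > 0")
        if abs(sum(self.macro_target) - 100.0) > 1e-6:
            raise ValidationError(
                f"macro_target must sum to 100, got {sum(self.macro_target)}"
            )
        unknown = set(self.groups_to_cover) - set(SCORED_GROUPS)
        if unknown:
            raise ValidationError(f"unknown groups_to_cover {sorted(unknown)}")
        if not (0 <= self.n_protein_sources <= 6):
            raise ValidationError("n_protein_sources must be within 0-6")
        for comp, band in self.moderation_profile.items():
            if comp not in _BAND_REPS:
                raise ValidationError(f"unknown moderation component {comp!r}")
            if band not in MODERATION_BANDS:
                raise ValidationError(f"unknown moderation band {band!r}")
        object.__setattr__(self, "groups_to_cover", frozenset(self.groups_to_cover))
        object.__setattr__(
            self, "adequacy_fraction", _normalise_fractions(self.adequacy_fraction)
        )
        object.__setattr__(self, "moderation_profile", dict(self.moderation_profile))


def _band_interval(rule_thresholds, band: str) -> tuple[float, float]:
    """(low, high] interval of a named band under a 2-threshold rule."""
    t1, t2 = rule_thresholds[0][0], rule_thresholds[1][0]
    return {"strict": (0.0, t1), "mid": (t1, t2), "high": (t2, float("inf"))}[band]


class _Builder:
    """Accumulates items and nutrient totals during plan construction."""

    def __init__(self, table: FoodTable):
        self.table = table
        self.portions: dict[str, float] = {}

    def add(self, food_id: str, grams: float) -> None:
        if grams <= 1e-9:
            return
        self.portions[food_id] = self.portions.get(food_id, 0.0) + grams

    def scale(self, food_ids: Sequence[str], factor: float) -> None:
        for fid in food_ids:
            if fid in self.portions:
                self.portions[fid] *= factor

    def amount(self, nutrient_field: str) -> float:
        total = 0.0
        for fid, grams in self.portions.items():
            rec = self.table.lookup(fid)
            total += getattr(rec.nutrients, nutrient_field) * grams / 100.0
        return total


def _pick(rng: np.random.Generator, options: list[FoodRecord]) -> FoodRecord:
    return options[int(rng.integers(len(options)))]


def _choose_foods(
    spec: PlanSpec, table: FoodTable, rng: np.random.Generator, lean: bool
) -> tuple[dict[str, FoodRecord], list[FoodRecord]]:
    """Pick one food per serving group and one per protein source."""
    # serving-group representatives
    group_reps: dict[str, FoodRecord] = {}
    for group in _SERVING_GROUPS:
        if group not in spec.groups_to_cover:
            continue
        options = table.by_group(group)
        if not options:
            raise FeasibilityError(f"food table has no foods in group {group!r}")
        if lean:
            rec = min(options, key=lambda r: r.nutrients.carbohydrate_g / 100.0 * r.serving_size_g)
        else:
            rec = _pick(rng, options)
        group_reps[group] = rec

    # protein sources
    covered_protein_groups = [g for g in _PROTEIN_GROUPS if g in spec.groups_to_cover]
    source_by_group = {
        g: sorted({r.protein_source for r in table.by_group(g)})
        for g in covered_protein_groups
    }
    min_sources = len(covered_protein_groups)
    max_sources = sum(len(v) for v in source_by_group.values())
    if spec.n_protein_sources < min_sources:
        raise FeasibilityError(
            f"covering groups {covered_protein_groups} forces at least "
            f"{min_sources} protein source(s), but n_protein_sources="
            f"{spec.n_protein_sources}"
        )
    if spec.n_protein_sources > max_sources:
        raise FeasibilityError(
            f"only {max_sources} protein sources reachable from groups "
            f"{covered_protein_groups}, requested {spec.n_protein_sources}"
        )
    chosen_sources: list[str] = []
    for g in covered_protein_groups:  # one source per covered group first
        opts = [s for s in source_by_group[g] if s not in chosen_sources]
        chosen_sources.append(opts[int(rng.integers(len(opts)))])
    remaining = sorted(
        {s for opts in source_by_group.values() for s in opts} - set(chosen_sources)
    )
    while len(chosen_sources) < spec.n_protein_sources:
        idx = int(rng.integers(len(remaining)))
        chosen_sources.append(remaining.pop(idx))

    protein_foods: list[FoodRecord] = []
    for source in chosen_sources:
        options = [
            r for r in table.by_protein_source(source) if r.variety_group in spec.groups_to_cover
        ]
        if lean:
            rec = min(options, key=lambda r: r.nutrients.saturated_fat_g)
        else:
            rec = _pick(rng, options)
        protein_foods.append(rec)
    return group_reps, protein_foods


def _build(spec: PlanSpec, table: FoodTable, lean: bool) -> MealPlan:
    cfg = default_config(spec.sex, spec.age_years)
    rng = np.random.default_rng(spec.seed)
    energy = spec.requested_kcal * (1.0 + spec.target_deviation_pct / 100.0)
    c_pct, p_pct, f_pct = spec.macro_target
    protein_target = p_pct / 100.0 * energy / 4.0
    carb_target = c_pct / 100.0 * energy / 4.0
    fat_target = f_pct / 100.0 * energy / 9.0

    group_reps, protein_foods = _choose_foods(spec, table, rng, lean)
    b = _Builder(table)

    # serving-group portions fixed by the adequacy fractions
    targets = cfg.adequacy_targets.targets
    for group, rec in group_reps.items():
        comp = _GROUP_TO_COMPONENT[group]
        frac = spec.adequacy_fraction[comp]
        if frac <= 0:
            raise FeasibilityError(
                f"group {group!r} must be covered but its adequacy fraction is 0"
            )
        b.add(rec.food_id, frac * targets[comp] * rec.serving_size_g)

    # protein-source foods
    protein_ids = []
    for rec in protein_foods:
        grams = 45.0 if lean else float(rng.uniform(40.0, 70.0))
        b.add(rec.food_id, grams)
        protein_ids.append(rec.food_id)

    # scale protein foods down if they crowd out the protein / fat /
    # cholesterol budgets
    lam = 1.0
    base_protein = b.amount("protein_g")
    prot_from_sources = sum(
        table.lookup(fid).nutrients.protein_g * b.portions[fid] / 100.0 for fid in protein_ids
    )
    if base_protein > 0.85 * protein_target and prot_from_sources > 0:
        lam = min(
            lam,
            (0.85 * protein_target - (base_protein - prot_from_sources)) / prot_from_sources,
        )
    chol_rule = cfg.moderation_rules["cholesterol"].thresholds
    chol_band = spec.moderation_profile.get("cholesterol", "strict")
    chol_lo, chol_hi = _band_interval(chol_rule, chol_band)
    base_chol = b.amount("cholesterol_mg")
    if np.isfinite(chol_hi) and base_chol > 0.95 * chol_hi and base_chol > 0:
        lam = min(lam, 0.95 * chol_hi / base_chol)
    base_fat = b.amount("total_fat_g")
    fat_from_sources = sum(
        table.lookup(fid).nutrients.total_fat_g * b.portions[fid] / 100.0 for fid in protein_ids
    )
    if base_fat > 0.85 * fat_target and fat_from_sources > 0:
        lam = min(
            lam, max(0.0, (0.85 * fat_target - (base_fat - fat_from_sources)) / fat_from_sources)
        )
    if lam < 1.0:
        if lam <= 0.05:
            raise FeasibilityError(
                "protein-source foods cannot fit the macronutrient budget"
            )
        b.scale(protein_ids, lam)

    # micronutrient top-ups (zero-energy supplements)
    for comp, food_id in _SUPPLEMENTS.items():
        nutrient_field = _SUPPLEMENT_FIELD[comp]
        goal = spec.adequacy_fraction[comp] * targets[comp]
        have = b.amount(nutrient_field)
        if have < goal:
            density = getattr(table.lookup(food_id).nutrients, nutrient_field) / 100.0
            b.add(food_id, (goal - have) / density)

    # cholesterol: aim at the band representative, never below what the
    # whole foods already deliver
    rep = _BAND_REPS["cholesterol"][MODERATION_BANDS.index(chol_band)]
    base_chol = b.amount("cholesterol_mg")
    if base_chol > chol_hi:
        raise FeasibilityError(
            f"cholesterol from whole foods ({base_chol:.0f} mg) exceeds the "
            f"requested band (<= {chol_hi:.0f} mg)"
        )
    chol_goal = max(rep, base_chol)
    if chol_goal > base_chol:
        density = table.lookup("cholesterol_concentrate").nutrients.cholesterol_mg / 100.0
        b.add("cholesterol_concentrate", (chol_goal - base_chol) / density)

    # sodium: likewise via table salt
    na_rule = cfg.moderation_rules["sodium"].thresholds
    na_band = spec.moderation_profile.get("sodium", "strict")
    na_lo, na_hi = _band_interval(na_rule, na_band)
    base_na = b.amount("sodium_mg")
    if base_na > na_hi:
        raise FeasibilityError(
            f"sodium from whole foods ({base_na:.0f} mg) exceeds the requested "
            f"band (<= {na_hi:.0f} mg)"
        )
    na_goal = max(_BAND_REPS["sodium"][MODERATION_BANDS.index(na_band)], base_na)
    if na_goal > base_na:
        density = table.lookup("table_salt").nutrients.sodium_mg / 100.0
        b.add("table_salt", (na_goal - base_na) / density)

    # protein isolate solves the protein gap before the fat and carb solves
    delta_p = protein_target - b.amount("protein_g")
    if delta_p < -1e-6:
        raise FeasibilityError("protein from whole foods exceeds the protein target")
    whey = table.lookup("whey_protein_isolate")
    if delta_p > 0:
        b.add("whey_protein_isolate", 100.0 * delta_p / whey.nutrients.protein_g)

    # fatty-acid solve with three oils of independent composition
    base_fat = b.amount("total_fat_g")
    base_sfa = b.amount("saturated_fat_g")
    base_mufa = b.amount("mufa_g")
    base_pufa = b.amount("pufa_g")
    unclassified = base_fat - base_sfa - base_mufa - base_pufa
    if base_fat > fat_target + 1e-6:
        raise FeasibilityError("fat from whole foods exceeds the fat target")
    classified_final = fat_target - unclassified
    if classified_final <= 0:
        raise FeasibilityError("unclassified fat exceeds the fat budget")

    sfa_rule = cfg.moderation_rules["saturated_fat"].thresholds
    sfa_band = spec.moderation_profile.get("saturated_fat", "strict")
    sfa_lo, sfa_hi = _band_interval(sfa_rule, sfa_band)
    if spec.fatty_acid_target is not None:
        r_pufa, r_mufa = spec.fatty_acid_target
        sfa_final = classified_final / (1.0 + r_pufa + r_mufa)
        mufa_final = r_mufa * sfa_final
        pufa_final = r_pufa * sfa_final
    else:
        rep_pct = _BAND_REPS["saturated_fat"][MODERATION_BANDS.index(sfa_band)]
        sfa_final = rep_pct / 100.0 * energy / 9.0
        sfa_final = min(sfa_final, 0.95 * classified_final)
        sfa_final = max(sfa_final, base_sfa)
        sfa_pct = 100.0 * 9.0 * sfa_final / energy
        if sfa_pct > sfa_hi:
            raise FeasibilityError(
                f"saturated fat ({sfa_pct:.1f} %E) cannot stay inside the "
                f"requested band (<= {sfa_hi:.0f} %E)"
            )
        remainder = classified_final - sfa_final
        mufa_final = max(0.6 * remainder, base_mufa)
        pufa_final = classified_final - sfa_final - mufa_final
    deltas = np.array(
        [sfa_final - base_sfa, mufa_final - base_mufa, pufa_final - base_pufa]
    )
    if np.any(deltas < -1e-6):
        which = ("saturated", "monounsaturated", "polyunsaturated")[int(np.argmin(deltas))]
        raise FeasibilityError(
            f"{which} fat from whole foods exceeds the fatty-acid target"
        )
    deltas = np.clip(deltas, 0.0, None)
    comp = np.column_stack(
        [
            [
                table.lookup(oil).nutrients.saturated_fat_g / 100.0,
                table.lookup(oil).nutrients.mufa_g / 100.0,
                table.lookup(oil).nutrients.pufa_g / 100.0,
            ]
            for oil in _OILS
        ]
    )
    masses = np.linalg.solve(comp, deltas)
    if np.any(masses < -1e-6):
        raise FeasibilityError(
            "fatty-acid composition unreachable with the available oils"
        )
    for oil, grams in zip(_OILS, np.clip(masses, 0.0, None)):
        b.add(oil, float(grams))

    # empty calories via sugar, then the carbohydrate powder closes the gap
    empty_band = spec.moderation_profile.get("empty_calorie", "strict")
    empty_rule = cfg.moderation_rules["empty_calorie"].thresholds
    empty_lo, empty_hi = _band_interval(empty_rule, empty_band)
    empty_pct = _BAND_REPS["empty_calorie"][MODERATION_BANDS.index(empty_band)]
    sugar_carb_density = table.lookup("white_sugar").nutrients.carbohydrate_g / 100.0
    malto_density = table.lookup("maltodextrin_powder").nutrients.carbohydrate_g / 100.0
    for attempt_pct in (empty_pct, max(empty_lo * 1.02, 0.0)):
        sugar_g = attempt_pct / 100.0 * energy / 4.0 / sugar_carb_density
        delta_c = carb_target - b.amount("carbohydrate_g") - sugar_g * sugar_carb_density
        if delta_c >= -1e-6:
            break
    if delta_c < -1e-6:
        raise FeasibilityError("carbohydrate from whole foods exceeds the carb target")
    b.add("white_sugar", sugar_g)
    if delta_c > 0:
        b.add("maltodextrin_powder", delta_c / malto_density)

    # assemble items, round-robin over meal slots
    items = []
    for i, (fid, grams) in enumerate(b.portions.items()):
        items.append(MealItem(food_id=fid, portion_g=grams, meal_slot=MEAL_SLOTS[i % len(MEAL_SLOTS)]))
    plan = MealPlan(
        plan_id=f"{spec.source}-{spec.sex}-{int(round(spec.requested_kcal))}",
        source=spec.source,
        sex=spec.sex,
        age_years=spec.age_years,
        requested_kcal=spec.requested_kcal,
        items=tuple(items),
    )

    # post-condition guard: achieved energy within 1 % of the prescription
    intake = aggregate_intake(plan, table)
    if abs(intake.energy_kcal_generated - energy) > 0.01 * energy:
        raise FeasibilityError(
            f"achieved energy {intake.energy_kcal_generated:.0f} kcal misses the "
            f"prescribed {energy:.0f} kcal by more than 1%"
        )
    return plan


def generate_plan(spec: PlanSpec, table: FoodTable) -> MealPlan:
    """Generate one plan satisfying ``spec``; deterministic given its seed.

    Falls back once from random to "lean" (low-carb, low-SFA) representative
    foods before declaring the spec infeasible.
    """
    try:
        return _build(spec, table, lean=False)
    except FeasibilityError:
        return _build(spec, table, lean=True)


def generate_plan_with_truth(
    spec: PlanSpec, table: FoodTable, config: ScoringConfig | None = None
) -> tuple[MealPlan, dict]:
    """Generate a plan plus its ground-truth record for test oracles.

    The record carries the prescription and the *achieved* quantities
    (measured on the emitted plan), including the deviation bin and the
    variety/balance points the achieved values imply.
    """
    plan = generate_plan(spec, table)
    cfg = config or default_config(spec.sex, spec.age_years)
    intake = aggregate_intake(plan, table)
    signed = (
        100.0
        * (intake.energy_kcal_generated - spec.requested_kcal)
        / spec.requested_kcal
    )
    bal_macro, bal_fatty, bal_total = score_balance(intake, cfg)
    truth = {
        "plan_id": plan.plan_id,
        "source": spec.source,
        "sex": spec.sex,
        "requested_kcal": spec.requested_kcal,
        "target_deviation_pct": spec.target_deviation_pct,
        "achieved_signed_pct": signed,
        "expected_bin": classify_deviation(abs(signed)),
        "groups_to_cover": sorted(spec.groups_to_cover),
        "n_protein_sources": spec.n_protein_sources,
        "expected_variety_food_groups": score_variety_food_groups(intake),
        "expected_variety_protein_sources": score_variety_protein_sources(intake),
        "macro_target": list(spec.macro_target),
        "achieved_macro_pct": [
            intake.pct_energy_carb,
            intake.pct_energy_protein,
            intake.pct_energy_fat,
        ],
        "fatty_acid_target": (
            list(spec.fatty_acid_target) if spec.fatty_acid_target else None
        ),
        "achieved_ratios": [intake.pufa_to_sfa, intake.mufa_to_sfa],
        "expected_balance_total": bal_total,
        "seed": spec.seed,
    }
    return plan, truth


def derive_cell_seed(master_seed: int, source: str, sex: str, kcal: float) -> int:
    """Stable per-cell seed: adding a grid cell never perturbs the others."""
    key = f"{master_seed}|{source}|{sex}|{kcal:g}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class StudySpec:
    """A full study grid with per-source deviation and property distributions.

    The defaults (see :func:`default_study_spec`) emulate the published
    study's regime: near-maximal variety, adequacy mostly between 50 % and
    110 % of target, protein-heavy / fat-heavy macronutrient shares that
    fall outside the balance bands, fatty-acid ratios below the scored
    range, and per-source caloric-deviation bin patterns.
    """

    sources: tuple[str, ...] = ("chatbot_a", "chatbot_b", "chatbot_c")
    kcal_levels: tuple[float, ...] = (1400.0, 1500.0, 1600.0, 1700.0, 1800.0)
    sexes: tuple[str, ...] = ("female", "male")
    age_years: int = 35
    master_seed: int = 0
    #: per-source plan counts in the five deviation bins (low to high);
    #: each tuple must sum to len(kcal_levels) × len(sexes)
    deviation_bin_counts: Mapping[str, tuple[int, ...]] | None = None
    protein_pct_range: tuple[float, float] = (18.0, 24.0)
    fat_pct_range: tuple[float, float] = (24.0, 32.0)
    fatty_acid_ratio_range: tuple[float, float] = (0.3, 0.8)
    adequacy_fraction_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "vegetables": (0.7, 1.1),
            "fruit": (0.6, 1.0),
            "grains": (0.5, 0.85),
            "fibre": (0.7, 1.1),
            "iron": (0.7, 1.1),
            "calcium": (0.7, 1.1),
            "vitamin_c": (0.7, 1.1),
        }
    )
    p_all_groups: float = 0.9
    protein_source_weights: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.07, 3: 0.31, 4: 0.31, 5: 0.31}
    )
    moderation_band_weights: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "saturated_fat": (0.2, 0.4, 0.4),
            "cholesterol": (0.6, 0.3, 0.1),
            "sodium": (0.5, 0.3, 0.2),
            "empty_calorie": (0.5, 0.35, 0.15),
        }
    )

    def __post_init__(self) -> None:
        if not (self.sources and self.kcal_levels and self.sexes):
            raise ValidationError("study grid must be non-empty")
        n_per_source = len(self.kcal_levels) * len(self.sexes)
        if self.deviation_bin_counts is not None:
            for src, counts in self.deviation_bin_counts.items():
                if len(counts) != 5 or sum(counts) != n_per_source:
                    raise ValidationError(
                        f"deviation_bin_counts[{src!r}] must hold 5 counts summing "
                        f"to {n_per_source}"
                    )

    @property
    def grid_size(self) -> int:
        return len(self.sources) * len(self.kcal_levels) * len(self.sexes)


@dataclass(frozen=True)
class StudyResult:
    """Plans plus per-plan ground truth for a generated study."""

    plans: tuple[MealPlan, ...]
    ground_truth: tuple[dict, ...]


#: Magnitude ranges sampled inside each deviation bin, kept clear of the bin
#: edges so table-energy rounding cannot flip the bin.
_BIN_MAGNITUDES = ((0.5, 4.5), (5.5, 9.5), (10.5, 14.5), (15.5, 19.5), (21.0, 29.0))


def _draw_spec(
    study: StudySpec,
    source: str,
    sex: str,
    kcal: float,
    deviation_pct: float,
    seed: int,
) -> PlanSpec:
    rng = np.random.default_rng(seed)
    groups = set(SCORED_GROUPS)
    if rng.uniform() > study.p_all_groups:
        groups.discard(("vegetables", "fruits", "grains")[int(rng.integers(3))])
    n_src_choices = sorted(study.protein_source_weights)
    weights = np.array([study.protein_source_weights[k] for k in n_src_choices])
    n_sources = int(rng.choice(n_src_choices, p=weights / weights.sum()))
    fractions = {
        comp: float(rng.uniform(*study.adequacy_fraction_ranges[comp]))
        for comp in CONTROLLED_ADEQUACY
    }
    protein_pct = float(rng.uniform(*study.protein_pct_range))
    fat_pct = float(rng.uniform(*study.fat_pct_range))
    carb_pct = 100.0 - protein_pct - fat_pct
    ratios = (
        float(rng.uniform(*study.fatty_acid_ratio_range)),
        float(rng.uniform(*study.fatty_acid_ratio_range)),
    )
    profile = {}
    for comp, w in study.moderation_band_weights.items():
        w = np.array(w, dtype=float)
        profile[comp] = str(rng.choice(MODERATION_BANDS, p=w / w.sum()))
    return PlanSpec(
        source=source,
        sex=sex,
        age_years=study.age_years,
        requested_kcal=kcal,
        target_deviation_pct=deviation_pct,
        groups_to_cover=frozenset(groups),
        n_protein_sources=n_sources,
        adequacy_fraction=fractions,
        macro_target=(carb_pct, protein_pct, fat_pct),
        fatty_acid_target=ratios,
        moderation_profile=profile,
        seed=seed,
    )


def generate_study(study: StudySpec, table: FoodTable) -> StudyResult:
    """Generate one plan per grid cell, with per-source deviation patterns.

    Per-cell seeds derive from the master seed and the cell coordinates;
    infeasible property draws are rejected and redrawn deterministically
    (up to 8 attempts per cell).
    """
    plans: list[MealPlan] = []
    truths: list[dict] = []
    for source in study.sources:
        cells = [(sex, kcal) for kcal in study.kcal_levels for sex in study.sexes]
        src_rng = np.random.default_rng(
            derive_cell_seed(study.master_seed, source, "binperm", 0.0)
        )
        if study.deviation_bin_counts is not None:
            bins: list[int] = []
            for bin_idx, count in enumerate(study.deviation_bin_counts[source]):
                bins.extend([bin_idx] * count)
            bins = [bins[i] for i in src_rng.permutation(len(bins))]
        else:
            bins = [int(src_rng.integers(0, 2)) for _ in cells]
        deviations = []
        for bin_idx in bins:
            lo, hi = _BIN_MAGNITUDES[bin_idx]
            magnitude = float(src_rng.uniform(lo, hi))
            sign = 1.0 if bin_idx == 4 else float(src_rng.choice((-1.0, 1.0)))
            deviations.append(sign * magnitude)

        for (sex, kcal), dev in zip(cells, deviations):
            cell_seed = derive_cell_seed(study.master_seed, source, sex, kcal)
            last_err: FeasibilityError | None = None
            for attempt in range(8):
                seed = (cell_seed + 1000003 * attempt) % (2**31)
                spec = _draw_spec(study, source, sex, kcal, dev, seed)
                try:
                    plan, truth = generate_plan_with_truth(spec, table)
                except FeasibilityError as exc:
                    last_err = exc
                    continue
                plans.append(plan)
                truths.append(truth)
                break
            else:
                raise FeasibilityError(
                    f"cell ({source}, {sex}, {kcal:g} kcal): no feasible draw in 8 "
                    f"attempts; last error: {last_err}"
                )
    return StudyResult(plans=tuple(plans), ground_truth=tuple(truths))


def default_study_spec(master_seed: int = 0) -> StudySpec:
    """The packaged study conditions: 3 sources × 5 kcal levels × 2 sexes,
    with per-source deviation-bin patterns echoing the published audit
    (one high-variability source with half its plans ≥20 % over target, one
    intermediate, one precise source with nothing ≥20 %)."""
    return StudySpec(
        master_seed=master_seed,
        deviation_bin_counts={
            "chatbot_a": (2, 0, 1, 2, 5),
            "chatbot_b": (3, 2, 2, 2, 1),
            "chatbot_c": (2, 5, 2, 1, 0),
        },
    )
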