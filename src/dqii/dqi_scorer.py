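"""The Diet Quality Index-International: five sub-scores and the 0–100 total.

The index decomposes into

* variety — food groups (0–15): 3 points per DQI-I food group consumed
  (meat/poultry/fish/egg, dairy/beans, grains, fruits, vegetables);
* variety — protein sources (0, 1, 3 or 5): by the number of distinct
  protein-source *categories* consumed (meat, poultry, fish, dairy, beans,
  eggs) — two dairy foods still count as one source;
* adequacy (0–40): eight components (vegetable/fruit/grain servings, fibre,
  protein, iron, calcium, vitamin C) each banded 0–5 on percent of target;
* moderation (0–30): five components (total fat %E, saturated fat %E,
  cholesterol, sodium, empty-calorie energy %E) each banded 0–6,
  lower-is-better;
* balance (0–10): up to 6 points for macronutrient energy shares inside
  nested optimal bands, up to 4 for both fatty-acid ratios inside theirs.

The total is the sum of the five sub-scores, always.

Degenerate diets: a zero-energy day (e.g. water only) scores 0 on every
sub-score — with no energy, the %E-based moderation limits and the balance
shares are undefined, and treating "nothing consumed" as perfectly moderate
would be absurd.  A day with fat but no saturated fat has absent fatty-acid
ratios and earns 0 balance points from them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import ValidationError
from .food_composition import SCORED_GROUPS, FoodTable
from .meal_plan import DailyIntake, MealPlan, aggregate_intake
from .scoring_config import (
    ADEQUACY_COMPONENTS,
    MODERATION_COMPONENTS,
    ScoringConfig,
)

__all__ = [
    "DQIIScore",
    "score_variety_food_groups",
    "score_variety_protein_sources",
    "score_adequacy",
    "score_moderation",
    "score_balance",
    "score_plan",
    "SCORE_COLUMNS",
]

#: Score dimensions as they appear in tabular output (sub-scores + total).
SCORE_COLUMNS = (
    "variety_food_groups",
    "variety_protein_sources",
    "adequacy_total",
    "moderation_total",
    "balance_total",
    "total",
)


@dataclass(frozen=True)
class DQIIScore:
    """The five DQI-I sub-scores, their components, and the 0–100 total."""

    variety_food_groups: int
    variety_protein_sources: int
    adequacy_components: Mapping[str, int]
    adequacy_total: int
    moderation_components: Mapping[str, int]
    moderation_total: int
    balance_macro: int
    balance_fatty_acid: int
    balance_total: int
    total: int

    def __post_init__(self) -> None:
        if self.adequacy_total != sum(self.adequacy_components.values()):
            raise ValidationError("adequacy_total must equal the sum of its components")
        if self.moderation_total != sum(self.moderation_components.values()):
            raise ValidationError("moderation_total must equal the sum of its components")
        if self.balance_total != self.balance_macro + self.balance_fatty_acid:
            raise ValidationError("balance_total must equal macro + fatty-acid points")
        expected = (
            self.variety_food_groups
            + self.variety_protein_sources
            + self.adequacy_total
            + self.moderation_total
            + self.balance_total
        )
        if self.total != expected:
            raise ValidationError("total must equal the sum of the five sub-scores")
        object.__setattr__(self, "adequacy_components", dict(self.adequacy_components))
        object.__setattr__(self, "moderation_components", dict(self.moderation_components))

    def as_row(self) -> dict:
        """Flatten to one tabular row (component scores prefixed)."""
        row = {
            "variety_food_groups": self.variety_food_groups,
            "variety_protein_sources": self.variety_protein_sources,
        }
        row.update({f"adequacy_{k}": v for k, v in self.adequacy_components.items()})
        row["adequacy_total"] = self.adequacy_total
        row.update({f"moderation_{k}": v for k, v in self.moderation_components.items()})
        row["moderation_total"] = self.moderation_total
        row.update(
            balance_macro=self.balance_macro,
            balance_fatty_acid=self.balance_fatty_acid,
            balance_total=self.balance_total,
            total=self.total,
        )
        return row


def score_variety_food_groups(intake: DailyIntake) -> int:
    """3 points per scored food group present; "other" never counts."""
    return 3 * len(set(intake.groups_present) & set(SCORED_GROUPS))


def score_variety_protein_sources(intake: DailyIntake) -> int:
    """5/3/1/0 points for ≥3 / 2 / 1 / 0 distinct protein-source categories."""
    n = len(intake.protein_sources_present)
    if n >= 3:
        return 5
    return {2: 3, 1: 1, 0: 0}[n]


def _adequacy_amounts(intake: DailyIntake) -> dict[str, float]:
    return {
        "vegetables": intake.servings.get("vegetables", 0.0),
        "fruit": intake.servings.get("fruits", 0.0),
        "grains": intake.servings.get("grains", 0.0),
        "fibre": intake.totals.fibre_g,
        "protein": intake.totals.protein_g,
        "iron": intake.totals.iron_mg,
        "calcium": intake.totals.calcium_mg,
        "vitamin_c": intake.totals.vitamin_c_mg,
    }


def score_adequacy(
    intake: DailyIntake, config: ScoringConfig
) -> tuple[dict[str, int], int]:
    """Band each of the eight components on percent of target; return
    (per-component scores, total 0–40)."""
    amounts = _adequacy_amounts(intake)
    targets = config.adequacy_targets.targets
    components = {
        name: config.adequacy_bands.apply(100.0 * amounts[name] / targets[name])
        for name in ADEQUACY_COMPONENTS
    }
    return components, sum(components.values())


def _moderation_amounts(intake: DailyIntake) -> dict[str, float]:
    return {
        "total_fat": intake.pct_energy_fat,
        "saturated_fat": intake.pct_energy_sfa,
        "cholesterol": intake.totals.cholesterol_mg,
        "sodium": intake.totals.sodium_mg,
        "empty_calorie": intake.pct_energy_empty,
    }


def score_moderation(
    intake: DailyIntake, config: ScoringConfig
) -> tuple[dict[str, int], int]:
    """Band the five moderation quantities (lower is better); return
    (per-component scores, total 0–30).  Zero-energy days score 0."""
    if intake.atwater_kcal <= 0:
        components = {name: 0 for name in MODERATION_COMPONENTS}
        return components, 0
    amounts = _moderation_amounts(intake)
    components = {
        name: config.moderation_rules[name].apply(amounts[name])
        for name in MODERATION_COMPONENTS
    }
    return components, sum(components.values())


def score_balance(intake: DailyIntake, config: ScoringConfig) -> tuple[int, int, int]:
    """Return (macro points, fatty-acid points, balance total).

    Macro points come from the innermost nested band containing all three
    energy shares; fatty-acid points from the innermost band containing both
    ratios.  Absent ratios (no saturated fat) and zero-energy days score 0.
    """
    macro = 0
    if intake.atwater_kcal > 0:
        for band in config.macro_ratio_bands:  # best band first
            if band.contains(
                intake.pct_energy_carb, intake.pct_energy_protein, intake.pct_energy_fat
            ):
                macro = band.points
                break
    fatty = 0
    if intake.pufa_to_sfa is not None and intake.mufa_to_sfa is not None:
        for band in config.fatty_acid_bands:
            if band.contains(intake.pufa_to_sfa, intake.mufa_to_sfa):
                fatty = band.points
                break
    return macro, fatty, macro + fatty


def score_plan(plan: MealPlan, table: FoodTable, config: ScoringConfig) -> DQIIScore:
    """Aggregate a plan and compute its full :class:`DQIIScore`."""
    intake = aggregate_intake(plan, table)
    return score_intake(intake, config)


def score_intake(intake: DailyIntake, config: ScoringConfig) -> DQIIScore:
    """Compute the full score from an already-aggregated intake."""
    vfg = score_variety_food_groups(intake)
    vps = score_variety_protein_sources(intake)
    adeq_components, adeq_total = score_adequacy(intake, config)
    mod_components, mod_total = score_moderation(intake, config)
    bal_macro, bal_fatty, bal_total = score_balance(intake, config)
    return DQIIScore(
        variety_food_groups=vfg,
        variety_protein_sources=vps,
        adequacy_components=adeq_components,
        adequacy_total=adeq_total,
        moderation_components=mod_components,
        moderation_total=mod_total,
        balance_macro=bal_macro,
        balance_fatty_acid=bal_fatty,
        balance_total=bal_total,
        total=vfg + vps + adeq_total + mod_total + bal_total,
    )
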