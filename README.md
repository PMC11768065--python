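# dqii

Diet-quality scoring and caloric-accuracy auditing for structured one-day
meal plans, built around the **Diet Quality Index-International (DQI-I)**.

Automatically generated diet plans — from meal-planning apps, recommender
systems or conversational AI — are easy to produce and hard to audit.
`dqii` is for nutrition and digital-health researchers who need to answer,
reproducibly: *is a batch of generated daily meal plans nutritionally
sound, and does each plan actually deliver the energy that was requested?*

The package provides:

* a validated **food-composition table** model (per-100 g nutrients plus
  DQI-I food-group / protein-source / empty-calorie tags), with a packaged
  40-food reference table;
* a **meal-plan** model (JSON dialect) and nutrient aggregation into daily
  totals, Atwater energy shares and fatty-acid ratios;
* the **DQI-I scorer**: variety (0–15 food groups + 0–5 protein sources),
  adequacy (0–40 over 8 components vs sex-specific RDA/DRI targets),
  moderation (0–30 over 5 risk components), balance (0–10 for
  macronutrient shares and PUFA/SFA, MUFA/SFA ratios), total 0–100 —
  every target and band threshold is configuration, not code;
* a **caloric-accuracy audit**: signed percentage deviation from the
  requested kcal, binned into <5 %, 5–9.99 %, 10–14.99 %, 15–19.99 %,
  ≥20 % by magnitude;
* **comparison statistics**: per-group mean/SD, one-way ANOVA across plan
  sources (including a summary-statistics entry point for published
  tables whose raw data are unavailable), pooled/Welch t-tests by sex;
* a seeded **synthetic-plan generator** that emits plans with prescribed
  properties (deviation, group coverage, adequacy fractions, macro and
  fatty-acid composition, moderation bands) plus ground-truth sidecars,
  so the whole pipeline is testable without any external data;
* a **CLI** (`dqii simulate | score | deviations | compare | run`) and a
  one-call pipeline writing CSV reports and a JSON run manifest.

## Worked example

```python
from dqii import (load_reference_table, default_config, MealPlan, MealItem,
                  score_plan, compute_deviation)

table = load_reference_table()
plan = MealPlan(
    plan_id="demo-f-1500", source="demo", sex="female", age_years=35,
    requested_kcal=1500,
    items=(
        MealItem("rolled_oats_dry", 60, "breakfast"),
        MealItem("greek_yoghurt_nonfat", 170, "breakfast"),
        MealItem("banana_raw", 120, "snack1"),
        MealItem("salmon_atlantic_cooked", 120, "lunch"),
        MealItem("brown_rice_cooked", 180, "lunch"),
        MealItem("broccoli_raw", 150, "lunch"),
        MealItem("apple_raw", 150, "snack2"),
        MealItem("chicken_breast_grilled", 100, "dinner"),
        MealItem("quinoa_cooked", 150, "dinner"),
        MealItem("spinach_raw", 100, "dinner"),
        MealItem("olive_oil", 10, "dinner"),
    ),
)
config = default_config(sex="female", age_years=35)
score = score_plan(plan, table, config)
dev = compute_deviation(plan, table)
```

Printing the result gives:

```
total DQI-I    79
  variety      15 + 5
  adequacy     32   {'vegetables': 4, 'fruit': 4, 'grains': 4, 'fibre': 5, 'protein': 5, 'iron': 3, 'calcium': 2, 'vitamin_c': 5}
  moderation   27   {'total_fat': 3, 'saturated_fat': 6, 'cholesterol': 6, 'sodium': 6, 'empty_calorie': 6}
  balance      0 (macro 0, fatty acid 0)
energy         1387 kcal for a 1500 kcal request
deviation      -7.5%  ->  bin '5-9.99%'
```

Reading: the day covers all five food groups (15) and three or more
protein-source categories (5); adequacy reaches 32/40 (calcium is the
weak component at 25–50 % of its 1000 mg target); moderation loses points
only on total fat (between 20 and 30 %E); and balance scores 0 — the
macronutrient shares and fatty-acid ratios sit outside the optimal bands,
the typical failure mode for generated weight-loss menus.  The plan
undershoots its 1500 kcal request by 7.5 %, landing in the 5–9.99 %
deviation bin.

For a whole-study view, the one-liner

```bash
dqii run --outdir out --seed 7
```

simulates the default 30-plan study (3 sources × 5 calorie levels
1400–1800 kcal × 2 sexes), scores it, audits deviations, runs the
between-source ANOVA and between-sex t-tests, and writes `scored.csv`,
`deviation_detail.csv`, `deviation_table.csv`, `comparison_by_source.csv`,
`comparison_by_sex.csv`, the ground-truth sidecar and `manifest.json`.
Reruns with the same seed are byte-identical.

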