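# Methods

## The index

`dqii` scores one-day structured meal plans with the Diet Quality
Index-International (DQI-I), a 0–100 composite of five sub-scores:

| Sub-score | Range | Rule |
|---|---|---|
| Variety — food groups | 0–15 | 3 points per food group consumed (meat/poultry/fish/egg, dairy/beans, grains, fruits, vegetables) |
| Variety — protein sources | 0, 1, 3, 5 | by the number of distinct protein-source *categories* (meat, poultry, fish, dairy, beans, eggs) |
| Adequacy | 0–40 | 8 components (vegetable, fruit and grain servings; fibre, protein, iron, calcium, vitamin C) each banded 0–5 on percent of target |
| Moderation | 0–30 | 5 components (total fat %E, saturated fat %E, cholesterol, sodium, empty-calorie energy %E) each banded 0–6, lower is better |
| Balance | 0–10 | up to 6 points for macronutrient energy shares inside nested bands, up to 4 for both fatty-acid ratios (PUFA/SFA, MUFA/SFA) inside theirs |

The total is always the sum of the five sub-scores.  Default targets are
the adult US RDA/DRI values resolved by sex (e.g. iron 18 mg for women vs
8 mg for men at age 35); default band thresholds follow the index's source
publication (adequacy 0 → 0, >0 → 1, ≥25 % → 2, ≥50 % → 3, ≥75 % → 4,
≥100 % → 5; moderation e.g. total fat ≤20 %E → 6, ≤30 %E → 3, else 0;
macro bands 55–65 : 10–15 : 15–25 → 6, 52–68 : 9–16 : 13–27 → 4,
50–70 : 8–17 : 12–30 → 2; fatty-acid ratios both in 1–1.5 → 4, both in
0.8–1.7 → 2).  All of this is configuration data (YAML round-trip), not
code, so alternative threshold readings are expressible.

### Conventions and degenerate inputs

* **Energy shares** use Atwater-computed energy (4·protein + 4·carb +
  9·fat kcal) as the denominator, so the three macronutrient shares sum to
  exactly 100.  The composition table's `energy_kcal` is used only for the
  caloric-accuracy audit, where the question is what a label would say.
* **`carbohydrate_g` is available carbohydrate** (fibre carried
  separately), so the Atwater identity closes on the stored energy.
* **Zero-energy days** (water only) score 0 on every sub-score: with no
  energy the %E-based moderation limits and the balance shares are
  undefined, and "nothing consumed" is not a moderate diet.
* **Absent fatty-acid ratios** (no saturated fat) are `None`, never
  infinite, and earn 0 balance points.
* **Band-edge tolerance.** Inclusive band edges are evaluated with a 1e-9
  relative tolerance (`EDGE_TOL`).  This matters because the
  maximum-score diet is geometrically forced onto band corners: the only
  macronutrient composition inside both the optimal balance band and the
  strictest fat limit is exactly 65 : 15 : 20 %E, so a solved plan sits
  *on* three inclusive edges and float roundoff of order 1e-14 would
  otherwise flip integer scores.  The tolerance absorbs roundoff only; it
  is far below the resolution of any nutritional quantity.
* Deviation-bin boundaries are exact half-open intervals
  [0, 5), [5, 10), [10, 15), [15, 20), [20, ∞) on the deviation magnitude;
  the signed deviation is retained so over- and undershoot remain
  distinguishable.

## The reference food table

A packaged 40-food composition table (per 100 g edible portion) spans all
five variety groups and all six protein sources, with serving sizes for
the serving-based adequacy components.  `energy_kcal` is stored as the
Atwater value of the macronutrients (2 dp), which keeps label energy and
Atwater energy consistent by construction.  The "other" group carries the
generator's adjusters: three oils whose fatty-acid compositions are
linearly independent (coconut-, olive- and sunflower-like), a
carbohydrate powder, sugar (the explicit empty-calorie carrier), a whey
protein isolate, an inulin fibre supplement, iron/calcium/vitamin-C
premixes, table salt, still water, and a synthetic cholesterol
concentrate (a test article, not a food that exists at that density).
Whole-food nutrient values are representative of common composition-table
entries but are a self-contained fixture, not an extract of any database.

## The synthetic generator

Real chatbot-generated plans are not publishable data, so the generator
emulates their *statistical structure*: which food groups and protein
sources appear, what fraction of each adequacy target is delivered, the
macronutrient and fatty-acid composition, the moderation band of each
risk component, and the signed caloric deviation from the request.

Portions are solved in closed form (see the module docstring of
`dqii.synthetic`): serving-group portions come directly from the
prescribed adequacy fractions; micronutrients and sodium/cholesterol are
topped up with zero-energy supplements; protein, fat (a 3×3 linear solve
over the three oils) and carbohydrate close the Atwater energy exactly on
`requested_kcal × (1 + deviation/100)`.  Post-conditions: achieved energy
within 1 % of prescription, macro shares within 2 points, variety sets
exact.  Infeasible prescriptions (e.g. a 5 %-carbohydrate diet that must
still carry six grain servings) raise a feasibility error naming the
binding constraint; one deterministic retry swaps in low-carbohydrate /
low-saturated-fat representative foods first.

Two modelling consequences are worth knowing.  The protein adequacy
component follows from the macro target (protein share × energy), so it is
not independently prescribable.  And when a fatty-acid ratio target is
given, the saturated-fat share is determined by the fat budget and the
ratios, so the requested saturated-fat band is recorded rather than
enforced.

### Default study conditions

`default_study_spec()` fixes the packaged study: 3 sources × 5 calorie
levels (1400–1800 kcal, step 100) × 2 sexes = 30 plans, age 35.  The
per-source deviation-bin counts are (2, 0, 1, 2, 5), (3, 2, 2, 2, 1) and
(2, 5, 2, 1, 0) across the bins <5 % … ≥20 % — one high-variability
source with half its plans at ≥20 % over target, one intermediate, one
precise.  Plan properties are drawn identically for every source:
near-complete variety (all five groups with probability 0.9, usually ≥3
protein sources), adequacy fractions mostly 0.5–1.1 of target,
protein 18–24 %E and fat 24–32 %E (weight-loss-style compositions that
fall outside the balance bands), fatty-acid ratios 0.3–0.8 (below the
scored range), and mixed moderation bands.  Under these conditions a
typical study scores ≈ 15 / 4.9 / 33–34 / 15–16 / 0 on the five
sub-scores (total ≈ 69), i.e. high variety and adequacy with poor balance
— the regime the index typically reports for machine-generated
weight-loss menus.

Per-cell seeds are SHA-256 hashes of (master seed, source, sex, kcal), so
adding a grid cell never perturbs another cell, and identical study specs
reproduce byte-identical plan sets.  Infeasible property draws are
rejected and redrawn deterministically (≤8 attempts per cell; across 300
master seeds no cell has ever needed all 8).

**What passing tests do and do not show.**  The generator produces
arithmetically consistent, band-controllable diets; it does not emulate
menu realism (recipe structure, cuisine, palatability), day-to-day
variation, or correlated nutrient patterns of real foods beyond the 40
fixture entries.  Parameter-recovery results therefore validate the
*pipeline* (scoring, binning, statistics), not any claim about real
chatbot behaviour.

## Statistics

Per-group mean and sample SD (n−1); one-way ANOVA across sources; pooled
(default) or Welch two-sample t-test between sexes; two-sided tests at
α = 0.05; no multiple-testing correction (each dimension is tested on its
own, a deliberate mirror of the reporting convention this package
reproduces — treat the per-dimension p-values accordingly).  The ANOVA is
computed from the summary-statistic identities, so the
`anova_from_summary` entry point (for printed tables whose raw data are
unavailable) agrees exactly with the raw-data route; two-group ANOVA
satisfies F = t² against the pooled t-test.

Calibration is checked empirically: on 200 null studies (identical
property distributions across sources) the between-source ANOVA p-values
are consistent with uniformity (KS test) and the rejection rate at 0.05
stays inside a pre-set binomial band.  Two hundred replicates keep the
default suite a few seconds long while still detecting gross
miscalibration; scores are integers, so exact uniformity is approximate
by nature.

## Known limitations

* Serving-based vs gram-based scoring of the vegetable/fruit/grain
  adequacy components is a genuine ambiguity of the index; the serving
  convention is used, and the targets/serving sizes are configuration.
* The moderation sub-score uses five enumerable components (total fat,
  saturated fat, cholesterol, sodium, empty-calorie foods) with a 0–30
  maximum; descriptions of the index sometimes say "six groups" without
  naming a sixth.
* Only the adult (19–70 y) DRI band ships as default configuration.
* One-day plans only; multi-day averaging is out of scope.
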