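"""Caloric-accuracy audit: deviation from the requested energy target.

For each plan the audit computes the signed percentage deviation of the
generated energy (composition-table kcal — the energy a user would see on a
label) from the requested target, and bins the deviation *magnitude* into
the five ranges <5 %, 5–9.99 %, 10–14.99 %, 15–19.99 % and ≥20 %.  The
printed range labels are two-decimal renderings of contiguous half-open
intervals: [0, 5), [5, 10), [10, 15), [15, 20), [20, ∞).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import DQIIError, ValidationError
from .food_composition import FoodTable
from .meal_plan import MealPlan, aggregate_intake

__all__ = [
    "DEVIATION_BINS",
    "DeviationResult",
    "classify_deviation",
    "compute_deviation",
    "deviation_table",
    "deviation_detail",
]

#: Bin labels in increasing order of deviation magnitude.
DEVIATION_BINS = ("<5%", "5-9.99%", "10-14.99%", "15-19.99%", ">=20%")

#: Inclusive lower edges of the bins above.
_BIN_EDGES = (0.0, 5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class DeviationResult:
    """Signed and absolute caloric deviation of one plan, with its bin."""

    plan_id: str
    source: str
    requested_kcal: float
    generated_kcal: float
    signed_pct: float
    abs_pct: float
    bin: str


def classify_deviation(abs_pct: float) -> str:
    """Map a non-negative deviation magnitude onto its bin label."""
    if abs_pct < 0:
        raise ValidationError(f"abs_pct must be >= 0, got {abs_pct}")
    label = DEVIATION_BINS[0]
    for edge, name in zip(_BIN_EDGES, DEVIATION_BINS):
        if abs_pct >= edge:
            label = name
    return label


def compute_deviation(plan: MealPlan, table: FoodTable) -> DeviationResult:
    """Deviation of a plan's label energy from its requested target."""
    intake = aggregate_intake(plan, table)
    generated = intake.energy_kcal_generated
    signed = 100.0 * (generated - plan.requested_kcal) / plan.requested_kcal
    return DeviationResult(
        plan_id=plan.plan_id,
        source=plan.source,
        requested_kcal=plan.requested_kcal,
        generated_kcal=generated,
        signed_pct=signed,
        abs_pct=abs(signed),
        bin=classify_deviation(abs(signed)),
    )


def deviation_detail(plans: Sequence[MealPlan], table: FoodTable) -> pd.DataFrame:
    """Per-plan deviation results as a tidy frame (one row per plan)."""
    rows = [compute_deviation(p, table).__dict__ for p in plans]
    return pd.DataFrame(
        rows,
        columns=[
            "plan_id",
            "source",
            "requested_kcal",
            "generated_kcal",
            "signed_pct",
            "abs_pct",
            "bin",
        ],
    )


def deviation_table(plans: Sequence[MealPlan], table: FoodTable) -> pd.DataFrame:
    """Counts and percentages of plans per source per deviation bin.

    One row per source; count columns ``n_<bin>`` sum to the source's plan
    count and percentage columns ``pct_<bin>`` sum to 100.
    """
    if not plans:
        raise DQIIError("deviation_table requires at least one plan")
    detail = deviation_detail(plans, table)
    rows = []
    for source, grp in detail.groupby("source", sort=False):
        n = len(grp)
        counts = {b: int((grp["bin"] == b).sum()) for b in DEVIATION_BINS}
        row: dict = {"source": source, "n_plans": n}
        row.update({f"n_{b}": counts[b] for b in DEVIATION_BINS})
        row.update({f"pct_{b}": 100.0 * counts[b] / n for b in DEVIATION_BINS})
        rows.append(row)
    return pd.DataFrame(rows)
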