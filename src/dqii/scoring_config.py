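"""Reference targets and band tables for DQI-I scoring.

Everything the index needs beyond the arithmetic lives here as data: the
US RDA/DRI adequacy targets (sex-specific, adult band), the 0–5 adequacy
band table on percent-of-target, the 0–6 lower-is-better moderation rules,
and the nested balance bands for the macronutrient energy shares and the
fatty-acid ratios.  All of it is configurable and round-trips through YAML,
so alternative threshold readings are expressible without touching code.

Default thresholds follow the index's source publication:

* adequacy: percent of target ≥100 → 5, ≥75 → 4, ≥50 → 3, ≥25 → 2,
  >0 → 1, =0 → 0;
* moderation: total fat ≤20 %E → 6, ≤30 → 3, else 0; saturated fat ≤7 %E
  → 6, ≤10 → 3, else 0; cholesterol ≤300 mg → 6, ≤400 → 3, else 0; sodium
  ≤2400 mg → 6, ≤3400 → 3, else 0; empty-calorie energy ≤3 %E → 6, ≤10 → 3,
  else 0;
* balance: macronutrient shares (carb:protein:fat %E) 55–65:10–15:15–25 → 6,
  52–68:9–16:13–27 → 4, 50–70:8–17:12–30 → 2, else 0; fatty-acid ratios
  (PUFA/SFA and MUFA/SFA) both within 1–1.5 → 4, both within 0.8–1.7 → 2,
  else 0.

Band boundaries are inclusive on the favourable side (≥100 % earns 5,
≤20 %E earns 6).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError, ValidationError

__all__ = [
    "ADEQUACY_COMPONENTS",
    "MODERATION_COMPONENTS",
    "BandTable",
    "AdequacyTargets",
    "MacroBand",
    "FattyAcidBand",
    "ScoringConfig",
    "default_config",
    "load_config",
    "write_config",
]

#: Relative/absolute tolerance used when testing inclusive band edges, so
#: that float roundoff (e.g. an energy share solved to 20 + 4e-15 %E) cannot
#: flip an integer score across a boundary the value sits exactly on.
EDGE_TOL = 1e-9


def _at_most(value: float, bound: float) -> bool:
    return value <= bound + EDGE_TOL * max(1.0, abs(bound))


def _at_least(value: float, bound: float) -> bool:
    return value >= bound - EDGE_TOL * max(1.0, abs(bound))


ADEQUACY_COMPONENTS = (
    "vegetables",
    "fruit",
    "grains",
    "fibre",
    "protein",
    "iron",
    "calcium",
    "vitamin_c",
)

MODERATION_COMPONENTS = (
    "total_fat",
    "saturated_fat",
    "cholesterol",
    "sodium",
    "empty_calorie",
)

#: Units of the adequacy targets (servings for food groups, amounts for nutrients).
ADEQUACY_UNITS = {
    "vegetables": "servings",
    "fruit": "servings",
    "grains": "servings",
    "fibre": "g",
    "protein": "g",
    "iron": "mg",
    "calcium": "mg",
    "vitamin_c": "mg",
}


@dataclass(frozen=True)
class BandTable:
    """A step function from an amount (or percentage) onto an integer score.

    ``thresholds`` is an ordered list of ``(bound, points)`` pairs.  With
    ``direction="higher_is_better"`` each bound is an inclusive *lower*
    bound and the highest satisfied bound wins; with ``lower_is_better``
    each bound is an inclusive *upper* bound and the lowest satisfied bound
    wins.  Values outside every band score 0.  ``zero_floor`` forces a score
    of 0 at exactly zero intake (used by the adequacy table, whose first
    band is ">0 → 1").
    """

    thresholds: tuple[tuple[float, int], ...]
    direction: str = "higher_is_better"
    zero_floor: bool = False
    max_points: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("higher_is_better", "lower_is_better"):
            raise ValidationError(f"unknown band direction {self.direction!r}")
        if not self.thresholds:
            raise ValidationError("band table must have at least one threshold")
        object.__setattr__(self, "thresholds", tuple((float(b), int(p)) for b, p in self.thresholds))
        bounds = [b for b, _ in self.thresholds]
        points = [p for _, p in self.thresholds]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValidationError("band thresholds must be strictly increasing")
        if self.direction == "higher_is_better":
            ok = all(p2 > p1 for p1, p2 in zip(points, points[1:]))
        else:
            ok = all(p2 < p1 for p1, p2 in zip(points, points[1:]))
        if not ok:
            raise ValidationError(
                f"band points must be monotone for direction {self.direction!r}"
            )
        if self.max_points is not None and any(
            not (0 <= p <= self.max_points) for p in points
        ):
            raise ValidationError(
                f"band points must lie within [0, {self.max_points}]"
            )

    def apply(self, value: float) -> int:
        """Score ``value`` through the step function."""
        if self.zero_floor and value <= 0:
            return 0
        if self.direction == "higher_is_better":
            score = 0
            for bound, pts in self.thresholds:
                if _at_least(value, bound):
                    score = pts
            return score
        for bound, pts in self.thresholds:
            if _at_most(value, bound):
                return pts
        return 0

    def to_dict(self) -> dict:
        return {
            "thresholds": [[b, p] for b, p in self.thresholds],
            "direction": self.direction,
            "zero_floor": self.zero_floor,
            "max_points": self.max_points,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BandTable":
        return cls(
            thresholds=tuple((float(b), int(p)) for b, p in d["thresholds"]),
            direction=d.get("direction", "higher_is_better"),
            zero_floor=bool(d.get("zero_floor", False)),
            max_points=d.get("max_points"),
        )


@dataclass(frozen=True)
class AdequacyTargets:
    """Daily targets for the eight adequacy components, resolved for one sex.

    Food-group targets (vegetables, fruit, grains) are in servings per day;
    nutrient targets are absolute daily amounts (g or mg).
    """

    sex: str
    targets: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = tuple(self.targets)
        if set(keys) != set(ADEQUACY_COMPONENTS):
            raise ValidationError(
                "adequacy targets must cover exactly the 8 components "
                f"{ADEQUACY_COMPONENTS}; got {keys}"
            )
        for k, v in self.targets.items():
            if not v > 0:
                raise ValidationError(f"adequacy target {k!r} must be > 0, got {v}")
        object.__setattr__(self, "targets", dict(self.targets))


@dataclass(frozen=True)
class MacroBand:
    """One nested band on the (carb, protein, fat) energy shares, in %E."""

    points: int
    carb: tuple[float, float]
    protein: tuple[float, float]
    fat: tuple[float, float]

    def contains(self, carb: float, protein: float, fat: float) -> bool:
        return all(
            _at_least(v, lo) and _at_most(v, hi)
            for v, (lo, hi) in ((carb, self.carb), (protein, self.protein), (fat, self.fat))
        )

    def nested_within(self, outer: "MacroBand") -> bool:
        return all(
            o_lo <= i_lo and i_hi <= o_hi
            for (i_lo, i_hi), (o_lo, o_hi) in (
                (self.carb, outer.carb),
                (self.protein, outer.protein),
                (self.fat, outer.fat),
            )
        )


@dataclass(frozen=True)
class FattyAcidBand:
    """One nested band applying to both PUFA/SFA and MUFA/SFA ratios."""

    points: int
    ratio_range: tuple[float, float]

    def contains(self, pufa_to_sfa: float, mufa_to_sfa: float) -> bool:
        lo, hi = self.ratio_range
        return all(
            _at_least(r, lo) and _at_most(r, hi) for r in (pufa_to_sfa, mufa_to_sfa)
        )


@dataclass(frozen=True)
class ScoringConfig:
    """All reference data the DQI-I scorer needs, resolved for one profile."""

    sex: str
    age_years: int
    adequacy_targets: AdequacyTargets
    adequacy_bands: BandTable
    moderation_rules: Mapping[str, BandTable]
    macro_ratio_bands: tuple[MacroBand, ...]
    fatty_acid_bands: tuple[FattyAcidBand, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if set(self.moderation_rules) != set(MODERATION_COMPONENTS):
            raise ValidationError(
                "moderation rules must cover exactly the 5 components "
                f"{MODERATION_COMPONENTS}; got {tuple(self.moderation_rules)}"
            )
        for name, rule in self.moderation_rules.items():
            if rule.direction != "lower_is_better":
                raise ValidationError(
                    f"moderation rule {name!r} must be lower_is_better"
                )
            if max(p for _, p in rule.thresholds) > 6:
                raise ValidationError(f"moderation rule {name!r} exceeds 6 points")
        if max(p for _, p in self.adequacy_bands.thresholds) > 5:
            raise ValidationError("adequacy band exceeds 5 points")
        # nested balance bands, best (most points) first
        macro = tuple(self.macro_ratio_bands)
        if [b.points for b in macro] != sorted({b.points for b in macro}, reverse=True):
            raise ValidationError("macro bands must have strictly decreasing points")
        for inner, outer in zip(macro, macro[1:]):
            if not inner.nested_within(outer):
                raise ValidationError(
                    f"macro band ({inner.points} pts) is not nested inside "
                    f"({outer.points} pts)"
                )
        fab = tuple(self.fatty_acid_bands)
        if [b.points for b in fab] != sorted({b.points for b in fab}, reverse=True):
            raise ValidationError("fatty-acid bands must have strictly decreasing points")
        for inner, outer in zip(fab, fab[1:]):
            i_lo, i_hi = inner.ratio_range
            o_lo, o_hi = outer.ratio_range
            if not (o_lo <= i_lo and i_hi <= o_hi):
                raise ValidationError(
                    f"fatty-acid band ({inner.points} pts) is not nested inside "
                    f"({outer.points} pts)"
                )
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        object.__setattr__(self, "moderation_rules", dict(self.moderation_rules))
        object.__setattr__(self, "macro_ratio_bands", macro)
        object.__setattr__(self, "fatty_acid_bands", fab)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "age_years": self.age_years,
            "adequacy_targets": dict(self.adequacy_targets.targets),
            "adequacy_bands": self.adequacy_bands.to_dict(),
            "moderation_rules": {
                k: v.to_dict() for k, v in self.moderation_rules.items()
            },
            "macro_ratio_bands": [
                {
                    "points": b.points,
                    "carb": list(b.carb),
                    "protein": list(b.protein),
                    "fat": list(b.fat),
                }
                for b in self.macro_ratio_bands
            ],
            "fatty_acid_bands": [
                {"points": b.points, "ratio_range": list(b.ratio_range)}
                for b in self.fatty_acid_bands
            ],
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringConfig":
        try:
            return cls(
                sex=str(d["sex"]),
                age_years=int(d["age_years"]),
                adequacy_targets=AdequacyTargets(
                    sex=str(d["sex"]),
                    targets={k: float(v) for k, v in d["adequacy_targets"].items()},
                ),
                adequacy_bands=BandTable.from_dict(d["adequacy_bands"]),
                moderation_rules={
                    k: BandTable.from_dict(v) for k, v in d["moderation_rules"].items()
                },
                macro_ratio_bands=tuple(
                    MacroBand(
                        points=int(b["points"]),
                        carb=tuple(b["carb"]),
                        protein=tuple(b["protein"]),
                        fat=tuple(b["fat"]),
                    )
                    for b in d["macro_ratio_bands"]
                ),
                fatty_acid_bands=tuple(
                    FattyAcidBand(
                        points=int(b["points"]), ratio_range=tuple(b["ratio_range"])
                    )
                    for b in d["fatty_acid_bands"]
                ),
                alpha=float(d.get("alpha", 0.05)),
            )
        except KeyError as exc:
            raise ValidationError(f"config missing field {exc}") from None


# -- packaged defaults -----------------------------------------------------

#: Adult (19–70 y) daily adequacy targets; iron, vitamin C and fibre are
#: sex-specific under the US DRIs, calcium is 1000 mg for both sexes at 35,
#: and protein uses the RDA expressed for reference body weights.
_DEFAULT_TARGETS = {
    "female": {
        "vegetables": 4.0,  # servings
        "fruit": 3.0,       # servings
        "grains": 6.0,      # servings
        "fibre": 25.0,      # g
        "protein": 46.0,    # g
        "iron": 18.0,       # mg
        "calcium": 1000.0,  # mg
        "vitamin_c": 75.0,  # mg
    },
    "male": {
        "vegetables": 4.0,
        "fruit": 3.0,
        "grains": 6.0,
        "fibre": 38.0,
        "protein": 56.0,
        "iron": 8.0,
        "calcium": 1000.0,
        "vitamin_c": 90.0,
    },
}

_ADULT_AGE_RANGE = (19, 70)


def default_config(sex: str, age_years: int) -> ScoringConfig:
    """The packaged default configuration for an adult profile.

    Deterministic: two calls with the same arguments return equal configs.
    Raises :class:`ConfigError` outside the adult age band or for an unknown
    sex.
    """
    if sex not in _DEFAULT_TARGETS:
        raise ConfigError(f"unsupported sex {sex!r} (expected 'female' or 'male')")
    lo, hi = _ADULT_AGE_RANGE
    if not (lo <= age_years <= hi):
        raise ConfigError(
            f"no default targets for age {age_years}; supported band is {lo}-{hi} y"
        )
    adequacy_bands = BandTable(
        thresholds=((0.0, 1), (25.0, 2), (50.0, 3), (75.0, 4), (100.0, 5)),
        direction="higher_is_better",
        zero_floor=True,
        max_points=5,
    )
    moderation_rules = {
        "total_fat": BandTable(((20.0, 6), (30.0, 3)), "lower_is_better", max_points=6),
        "saturated_fat": BandTable(((7.0, 6), (10.0, 3)), "lower_is_better", max_points=6),
        "cholesterol": BandTable(((300.0, 6), (400.0, 3)), "lower_is_better", max_points=6),
        "sodium": BandTable(((2400.0, 6), (3400.0, 3)), "lower_is_better", max_points=6),
        "empty_calorie": BandTable(((3.0, 6), (10.0, 3)), "lower_is_better", max_points=6),
    }
    macro_bands = (
        MacroBand(6, (55.0, 65.0), (10.0, 15.0), (15.0, 25.0)),
        MacroBand(4, (52.0, 68.0), (9.0, 16.0), (13.0, 27.0)),
        MacroBand(2, (50.0, 70.0), (8.0, 17.0), (12.0, 30.0)),
    )
    fatty_acid_bands = (
        FattyAcidBand(4, (1.0, 1.5)),
        FattyAcidBand(2, (0.8, 1.7)),
    )
    return ScoringConfig(
        sex=sex,
        age_years=age_years,
        adequacy_targets=AdequacyTargets(sex=sex, targets=_DEFAULT_TARGETS[sex]),
        adequacy_bands=adequacy_bands,
        moderation_rules=moderation_rules,
        macro_ratio_bands=macro_bands,
        fatty_acid_bands=fatty_acid_bands,
        alpha=0.05,
    )


def write_config(config: ScoringConfig, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path


def load_config(path: str | Path) -> ScoringConfig:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return ScoringConfig.from_dict(data)
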