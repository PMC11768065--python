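"""Food-composition table: per-100 g nutrient profiles plus DQI-I tags.

The table mirrors the fields a practitioner would extract from USDA FoodData
Central: macro- and micronutrients per 100 g edible portion, the DQI-I
variety-group and protein-source classification of each food, an explicit
empty-calorie flag, and a serving size in grams (used for the serving-based
adequacy components: vegetables, fruit, grains).

Conventions
-----------
* All nutrients are stored **per 100 g** and scaled by ``portion_g / 100``
  downstream.
* ``carbohydrate_g`` is *available* carbohydrate (fibre is carried separately
  in ``fibre_g``), so the Atwater composition 4P + 4C + 9F closes on
  ``energy_kcal``.
* ``empty_calorie`` is an explicit per-food boolean: "empty-calorie foods"
  are an input classification, not a computed nutrient-density rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import DuplicateFoodError, FoodLookupError, SchemaError, ValidationError

__all__ = [
    "VARIETY_GROUPS",
    "SCORED_GROUPS",
    "PROTEIN_SOURCES",
    "NUTRIENT_FIELDS",
    "NutrientProfile",
    "FoodRecord",
    "FoodTable",
    "read_food_table",
    "write_food_table",
    "lookup_food",
    "load_reference_table",
]

#: The five DQI-I variety groups plus a catch-all for oils, condiments,
#: beverages and supplements.  "other" contributes nutrients but never
#: variety points.
VARIETY_GROUPS = (
    "meat_poultry_fish_egg",
    "dairy_beans",
    "grains",
    "fruits",
    "vegetables",
    "other",
)

#: The five groups that earn variety points.
SCORED_GROUPS = VARIETY_GROUPS[:5]

#: The six DQI-I protein-source categories; "none" for foods that are not a
#: protein source.
PROTEIN_SOURCES = ("meat", "poultry", "fish", "dairy", "beans", "eggs", "none")

#: Protein sources imply membership of one of these two variety groups.
_PROTEIN_GROUPS = ("meat_poultry_fish_egg", "dairy_beans")

#: Nutrient columns in canonical file order.
NUTRIENT_FIELDS = (
    "energy_kcal",
    "protein_g",
    "carbohydrate_g",
    "total_fat_g",
    "saturated_fat_g",
    "mufa_g",
    "pufa_g",
    "cholesterol_mg",
    "sodium_mg",
    "fibre_g",
    "iron_mg",
    "calcium_mg",
    "vitamin_c_mg",
)

#: CSV column order of the food-composition dialect.
TABLE_COLUMNS = (
    "food_id",
    "name",
    *NUTRIENT_FIELDS,
    "variety_group",
    "protein_source",
    "empty_calorie",
    "serving_size_g",
)

#: Atwater general factors, kcal per gram.
ATWATER_KCAL_PER_G = {"protein_g": 4.0, "carbohydrate_g": 4.0, "total_fat_g": 9.0}


@dataclass(frozen=True)
class NutrientProfile:
    """Nutrients per 100 g edible portion (or absolute daily totals).

    The same shape serves both per-100 g records and aggregated daily totals;
    both satisfy the non-negativity and fatty-acid closure invariants.
    """

    energy_kcal: float
    protein_g: float
    carbohydrate_g: float
    total_fat_g: float
    saturated_fat_g: float
    mufa_g: float
    pufa_g: float
    fibre_g: float
    cholesterol_mg: float
    sodium_mg: float
    iron_mg: float
    calcium_mg: float
    vitamin_c_mg: float
    #: Relative slack allowed when checking SFA + MUFA + PUFA <= total fat.
    fat_closure_tol: float = field(default=0.05, repr=False, compare=False)

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if f.name == "fat_closure_tol":
                continue
            v = getattr(self, f.name)
            if not (v >= 0):  # also rejects NaN
                raise ValidationError(f"nutrient {f.name!r} must be >= 0, got {v!r}")
        classified = self.saturated_fat_g + self.mufa_g + self.pufa_g
        limit = self.total_fat_g * (1.0 + self.fat_closure_tol)
        if classified > limit + 1e-9:
            raise ValidationError(
                "fatty-acid components exceed total fat: "
                f"SFA+MUFA+PUFA = {classified:.4g} g > {limit:.4g} g"
            )

    def atwater_kcal(self) -> float:
        """Energy from Atwater general factors: 4·protein + 4·carb + 9·fat."""
        return (
            4.0 * self.protein_g + 4.0 * self.carbohydrate_g + 9.0 * self.total_fat_g
        )

    def check_energy(self, rel_tol: float = 0.20) -> None:
        """Strict-energy check: Atwater energy within ``rel_tol`` of energy_kcal.

        Only meaningful for per-100 g records with non-trivial energy; zero
        energy foods (water, mineral supplements) pass trivially.
        """
        if self.energy_kcal <= 0 and self.atwater_kcal() <= 0:
            return
        ref = max(self.energy_kcal, 1e-9)
        if abs(self.atwater_kcal() - self.energy_kcal) > rel_tol * ref:
            raise ValidationError(
                f"Atwater energy {self.atwater_kcal():.1f} kcal deviates more than "
                f"{rel_tol:.0%} from declared energy {self.energy_kcal:.1f} kcal"
            )

    def scaled(self, factor: float) -> "NutrientProfile":
        """Return a copy with every nutrient multiplied by ``factor``."""
        return NutrientProfile(
            energy_kcal=self.energy_kcal * factor,
            protein_g=self.protein_g * factor,
            carbohydrate_g=self.carbohydrate_g * factor,
            total_fat_g=self.total_fat_g * factor,
            saturated_fat_g=self.saturated_fat_g * factor,
            mufa_g=self.mufa_g * factor,
            pufa_g=self.pufa_g * factor,
            fibre_g=self.fibre_g * factor,
            cholesterol_mg=self.cholesterol_mg * factor,
            sodium_mg=self.sodium_mg * factor,
            iron_mg=self.iron_mg * factor,
            calcium_mg=self.calcium_mg * factor,
            vitamin_c_mg=self.vitamin_c_mg * factor,
        )

    def __add__(self, other: "NutrientProfile") -> "NutrientProfile":
        return NutrientProfile(
            energy_kcal=self.energy_kcal + other.energy_kcal,
            protein_g=self.protein_g + other.protein_g,
            carbohydrate_g=self.carbohydrate_g + other.carbohydrate_g,
            total_fat_g=self.total_fat_g + other.total_fat_g,
            saturated_fat_g=self.saturated_fat_g + other.saturated_fat_g,
            mufa_g=self.mufa_g + other.mufa_g,
            pufa_g=self.pufa_g + other.pufa_g,
            fibre_g=self.fibre_g + other.fibre_g,
            cholesterol_mg=self.cholesterol_mg + other.cholesterol_mg,
            sodium_mg=self.sodium_mg + other.sodium_mg,
            iron_mg=self.iron_mg + other.iron_mg,
            calcium_mg=self.calcium_mg + other.calcium_mg,
            vitamin_c_mg=self.vitamin_c_mg + other.vitamin_c_mg,
        )

    @classmethod
    def zero(cls) -> "NutrientProfile":
        return cls(**{f: 0.0 for f in NUTRIENT_FIELDS})


@dataclass(frozen=True)
class FoodRecord:
    """One food: identity, per-100 g nutrients and DQI-I classification tags."""

    food_id: str
    name: str
    nutrients: NutrientProfile
    variety_group: str
    protein_source: str
    empty_calorie: bool
    serving_size_g: float

    def __post_init__(self) -> None:
        if not self.food_id:
            raise ValidationError("food_id must be non-empty")
        if self.variety_group not in VARIETY_GROUPS:
            raise ValidationError(
                f"{self.food_id}: unknown variety_group {self.variety_group!r}"
            )
        if self.protein_source not in PROTEIN_SOURCES:
            raise ValidationError(
                f"{self.food_id}: unknown protein_source {self.protein_source!r}"
            )
        if self.protein_source != "none" and self.variety_group not in _PROTEIN_GROUPS:
            raise ValidationError(
                f"{self.food_id}: protein source {self.protein_source!r} requires "
                f"variety group in {_PROTEIN_GROUPS}, got {self.variety_group!r}"
            )
        if not self.serving_size_g > 0:
            raise ValidationError(
                f"{self.food_id}: serving_size_g must be > 0, got {self.serving_size_g}"
            )


class FoodTable:
    """An ordered collection of :class:`FoodRecord` with unique food_ids."""

    def __init__(self, records: Iterable[FoodRecord]):
        self._records: dict[str, FoodRecord] = {}
        for rec in records:
            if rec.food_id in self._records:
                raise DuplicateFoodError(f"duplicate food_id {rec.food_id!r}")
            self._records[rec.food_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[FoodRecord]:
        return iter(self._records.values())

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._records

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodTable):
            return NotImplemented
        return list(self) == list(other)

    def lookup(self, food_id: str) -> FoodRecord:
        try:
            return self._records[food_id]
        except KeyError:
            raise FoodLookupError(f"unknown food_id {food_id!r}") from None

    def by_group(self, variety_group: str) -> list[FoodRecord]:
        return [r for r in self if r.variety_group == variety_group]

    def by_protein_source(self, source: str) -> list[FoodRecord]:
        return [r for r in self if r.protein_source == source]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self:
            row = {"food_id": rec.food_id, "name": rec.name}
            row.update({f: getattr(rec.nutrients, f) for f in NUTRIENT_FIELDS})
            row.update(
                variety_group=rec.variety_group,
                protein_source=rec.protein_source,
                empty_calorie=rec.empty_calorie,
                serving_size_g=rec.serving_size_g,
            )
            rows.append(row)
        return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def lookup_food(table: FoodTable, food_id: str) -> FoodRecord:
    """Return the unique record for ``food_id`` (module-level convenience)."""
    return table.lookup(food_id)


def _parse_bool(value, row: int) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ValidationError(f"row {row}: cannot parse empty_calorie value {value!r}")


def read_food_table(path: str | Path) -> FoodTable:
    """Read a food-composition CSV into a validated :class:`FoodTable`.

    Raises :class:`SchemaError` for missing/unknown columns,
    :class:`DuplicateFoodError` for repeated food_ids and
    :class:`ValidationError` (with the 1-based data row number) for invalid
    values.
    """
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in TABLE_COLUMNS]
    if unknown:
        raise SchemaError(f"{path.name}: unknown column(s) {', '.join(unknown)}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            nutrients = NutrientProfile(
                **{f: float(row[f]) for f in NUTRIENT_FIELDS}
            )
            rec = FoodRecord(
                food_id=str(row["food_id"]),
                name=str(row["name"]),
                nutrients=nutrients,
                variety_group=str(row["variety_group"]),
                protein_source=str(row["protein_source"]),
                empty_calorie=_parse_bool(row["empty_calorie"], i),
                serving_size_g=float(row["serving_size_g"]),
            )
        except DuplicateFoodError:
            raise
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    return FoodTable(records)


def write_food_table(table: FoodTable, path: str | Path) -> Path:
    """Write ``table`` as UTF-8 CSV; re-reading reproduces it field-for-field."""
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False, encoding="utf-8")
    return path


def load_reference_table() -> FoodTable:
    """Load the packaged 40-food reference table.

    The table spans all five DQI-I variety groups and all six protein
    sources, plus "other"-group adjusters (oils of distinct fatty-acid
    composition, a carbohydrate powder, a protein isolate, fibre and
    micronutrient supplements, salt and a synthetic cholesterol concentrate)
    that the synthetic-plan generator uses to solve portion masses in closed
    form.
    """
    from importlib.resources import as_file, files

    with as_file(files("dqii.data") / "food_table.csv") as path:
        return read_food_table(path)
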