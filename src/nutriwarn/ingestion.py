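"""Reading product extracts and running the exclusion cascade.

Stages, in fixed order:

1. deduplicate by barcode (first occurrence wins);
2. missing-information / nutrient-error exclusion;
3. no recognised SEARO category;
4. variety packs;
5. baby food;
6. missing required nutrients (sufficiency against every requested model);
7. "as sold" products lacking the dilution factor needed for reconstitution.

First matching rule wins, so the :class:`ExclusionLedger` partitions the
deduplicated input exactly.  Absent nutrient cells stay absent — never zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from .records import (
    FLAG_NAMES,
    NUTRIENTS,
    Basis,
    IngredientFlags,
    NutrientPanel,
    PerUnit,
    ProductRecord,
    TriState,
)
from .engines import ThresholdTable
from .taxonomy import Taxonomy, product_form

#: kcal per kJ and mg sodium per g salt, applied once at read time.
KJ_PER_KCAL = 4.184
SODIUM_MG_PER_SALT_G = 1000.0 / 2.5


class SchemaError(ValueError):
    """Header row does not provide the columns the schema maps."""


@dataclass(frozen=True)
class ColumnSchema:
    """Maps the canonical record fields onto an export dialect's columns.

    ``sodium_unit`` may be ``mg`` or ``salt_g`` (salt grams are converted to
    sodium mg at read time); ``energy_unit`` may be ``kcal`` or ``kj``.
    """

    columns: dict[str, str] = field(default_factory=dict)
    sodium_unit: str = "mg"
    energy_unit: str = "kcal"

    def column(self, field_name: str) -> str:
        return self.columns.get(field_name, field_name)

    @classmethod
    def from_dict(cls, data: dict) -> "ColumnSchema":
        return cls(
            columns=dict(data.get("columns", {})),
            sodium_unit=data.get("sodium_unit", "mg"),
            energy_unit=data.get("energy_unit", "kcal"),
        )


DEFAULT_SCHEMA = ColumnSchema()

#: Canonical CSV field order (default dialect, also used by the writer).
CSV_FIELDS: tuple[str, ...] = (
    "barcode",
    "name",
    "category_code",
    "energy",
    "total_fat",
    "saturated_fat",
    "total_sugar",
    "added_sugar",
    "sodium",
    "basis",
    "per",
    "flag_added_sugar",
    "flag_added_sodium",
    "flag_added_sat_fat",
    "flag_nns",
    "dilution_factor",
    "variety_pack",
    "baby_food",
)

_REQUIRED_FIELDS = ("barcode", "category_code")


@dataclass
class ExclusionLedger:
    """Counts per exclusion stage plus the retained totals at each cut."""

    raw_rows: int = 0
    duplicates_removed: int = 0
    missing_or_error: int = 0
    no_category: int = 0
    variety_pack: int = 0
    baby_food: int = 0
    missing_nutrients: int = 0
    no_preparation_instructions: int = 0
    unique_products: int = 0
    category_assigned: int = 0
    analyzable: int = 0

    STAGES = (
        "duplicates_removed",
        "missing_or_error",
        "no_category",
        "variety_pack",
        "baby_food",
        "missing_nutrients",
        "no_preparation_instructions",
    )

    def conservation_holds(self) -> bool:
        return (
            self.raw_rows - self.duplicates_removed == self.unique_products
            and self.unique_products
            - (self.missing_or_error + self.no_category + self.variety_pack + self.baby_food)
            == self.category_assigned
            and self.category_assigned
            - (self.missing_nutrients + self.no_preparation_instructions)
            == self.analyzable
        )

    def as_rows(self) -> list[tuple[str, int]]:
        keys = ("raw_rows",) + self.STAGES + ("unique_products", "category_assigned", "analyzable")
        return [(k, getattr(self, k)) for k in keys]

    def write_csv(self, path: Path | str) -> None:
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["stage", "count"])
            writer.writerows(self.as_rows())


def _parse_float(text: str) -> tuple[Optional[float], bool]:
    """Returns (value, error).  Empty cell -> (None, False); junk -> (None, True)."""
    text = text.strip()
    if not text or text.lower() in ("na", "nan", "none", "-"):
        return None, False
    try:
        return float(text), False
    except ValueError:
        return None, True


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "yes", "1")


def read_products(path: Path | str, schema: ColumnSchema = DEFAULT_SCHEMA) -> list[ProductRecord]:
    """Read one record per row; malformed numeric cells flag the record as a
    nutrient error instead of aborting the load."""
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        header = set(reader.fieldnames)
        missing = [schema.column(f) for f in _REQUIRED_FIELDS if schema.column(f) not in header]
        if missing:
            raise SchemaError(f"{path}: header lacks required column(s): {', '.join(missing)}")
        records = []
        for row in reader:
            records.append(_row_to_record(row, schema))
    return records


def _row_to_record(row: dict[str, str], schema: ColumnSchema) -> ProductRecord:
    def cell(field_name: str) -> str:
        return row.get(schema.column(field_name), "") or ""

    error = False
    amounts: dict[str, Optional[float]] = {}
    for nutrient in NUTRIENTS:
        value, bad = _parse_float(cell(nutrient))
        error = error or bad
        amounts[nutrient] = value
    if amounts["energy"] is not None and schema.energy_unit.lower() == "kj":
        amounts["energy"] = amounts["energy"] / KJ_PER_KCAL
    if amounts["sodium"] is not None and schema.sodium_unit.lower() == "salt_g":
        amounts["sodium"] = amounts["sodium"] * SODIUM_MG_PER_SALT_G

    basis_text = cell("basis").strip() or Basis.AS_CONSUMED.value
    per_text = cell("per").strip() or PerUnit.PER_100G.value
    try:
        basis = Basis(basis_text)
        per = PerUnit(per_text)
    except ValueError:
        basis, per = Basis.AS_CONSUMED, PerUnit.PER_100G
        error = True

    dilution, bad = _parse_float(cell("dilution_factor"))
    error = error or bad
    if dilution is not None and dilution <= 0:
        dilution, error = None, True

    flags = IngredientFlags(
        added_sugar=TriState.coerce(cell("flag_added_sugar") or None),
        added_sodium=TriState.coerce(cell("flag_added_sodium") or None),
        added_sat_fat=TriState.coerce(cell("flag_added_sat_fat") or None),
        nns=TriState.coerce(cell("flag_nns") or None),
    )
    barcode = cell("barcode").strip()
    if not barcode:
        barcode, error = "<missing>", True
    return ProductRecord(
        barcode=barcode,
        name=cell("name").strip(),
        category_code=cell("category_code").strip(),
        panel=NutrientPanel(basis=basis, per=per, **amounts),
        flags=flags,
        dilution_factor=dilution,
        variety_pack=_parse_bool(cell("variety_pack")),
        baby_food=_parse_bool(cell("baby_food")),
        nutrient_error=error,
    )


def write_products(records: Sequence[ProductRecord], path: Path | str) -> None:
    """Write records in the canonical CSV dialect (round-trips with
    :func:`read_products` under the default schema)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_FIELDS)
        for r in records:
            writer.writerow(
                [
                    r.barcode,
                    r.name,
                    r.category_code,
                    *("" if r.panel.get(n) is None else repr(r.panel.get(n)) for n in NUTRIENTS),
                    r.panel.basis.value,
                    r.panel.per.value,
                    r.flags.added_sugar.value,
                    r.flags.added_sodium.value,
                    r.flags.added_sat_fat.value,
                    r.flags.nns.value,
                    "" if r.dilution_factor is None else repr(r.dilution_factor),
                    str(r.variety_pack).lower(),
                    str(r.baby_food).lower(),
                ]
            )


def deduplicate(
    records: Sequence[ProductRecord], ledger: Optional[ExclusionLedger] = None
) -> tuple[list[ProductRecord], ExclusionLedger]:
    """Keep the first occurrence per barcode, in input order."""
    ledger = ledger or ExclusionLedger()
    seen: set[str] = set()
    kept: list[ProductRecord] = []
    for record in records:
        if record.barcode in seen:
            continue
        seen.add(record.barcode)
        kept.append(record)
    ledger.raw_rows += len(records)
    ledger.duplicates_removed += len(records) - len(kept)
    ledger.unique_products += len(kept)
    return kept, ledger


def is_missing_or_error(record: ProductRecord) -> bool:
    """Label-quality exclusion: parser-flagged errors or panel invariant
    violations (negative amounts, component > total)."""
    return record.nutrient_error or not record.panel.is_valid()


def apply_exclusions(
    records: Sequence[ProductRecord],
    taxonomy: Taxonomy,
    ledger: Optional[ExclusionLedger] = None,
) -> tuple[list[ProductRecord], ExclusionLedger]:
    """Category-assignment cascade; each record lands in exactly one bucket."""
    ledger = ledger or ExclusionLedger()
    kept: list[ProductRecord] = []
    for record in records:
        if is_missing_or_error(record):
            ledger.missing_or_error += 1
        elif record.category_code not in taxonomy:
            ledger.no_category += 1
        elif record.variety_pack:
            ledger.variety_pack += 1
        elif record.baby_food:
            ledger.baby_food += 1
        else:
            kept.append(record)
    ledger.category_assigned += len(kept)
    return kept, ledger


def reconstitute(
    panel: NutrientPanel, dilution_factor: Optional[float], is_beverage: bool = True
) -> NutrientPanel:
    """Dilute an "as sold" panel to "as consumed" per package instructions.

    Water contributes zero nutrients, so every amount is divided by the
    dilution factor.  Panels already "as consumed" pass through untouched.
    """
    if panel.basis is Basis.AS_CONSUMED:
        return panel
    if dilution_factor is None:
        raise ReconstitutionImpossible("missing dilution factor")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    diluted = panel.scaled(1.0 / dilution_factor)
    per = PerUnit.PER_100ML if is_beverage else panel.per
    return replace(diluted, basis=Basis.AS_CONSUMED, per=per)


class ReconstitutionImpossible(ValueError):
    """No preparation instructions: the caller counts the product under the
    ``no_preparation_instructions`` exclusion."""


def sufficiency_check(
    record: ProductRecord,
    models: Sequence[ThresholdTable],
    taxonomy: Taxonomy,
) -> bool:
    """True iff every nutrient referenced by any rule applicable to this
    record — in all requested models — is present on the panel."""
    needed: set[str] = set()
    for table in models:
        needed |= table.referenced_nutrients(record, taxonomy)
    return all(record.panel.present(n) for n in needed)


def prepare_analyzable(
    records: Sequence[ProductRecord],
    models: Sequence[ThresholdTable],
    taxonomy: Taxonomy,
    ledger: Optional[ExclusionLedger] = None,
) -> tuple[list[ProductRecord], ExclusionLedger]:
    """Sufficiency then reconstitution; survivors carry "as consumed" panels."""
    ledger = ledger or ExclusionLedger()
    kept: list[ProductRecord] = []
    for record in records:
        if not sufficiency_check(record, models, taxonomy):
            ledger.missing_nutrients += 1
            continue
        if record.panel.basis is Basis.AS_SOLD:
            category = taxonomy.lookup_category(record.category_code)
            try:
                panel = reconstitute(record.panel, record.dilution_factor, category.is_beverage)
            except ReconstitutionImpossible:
                ledger.no_preparation_instructions += 1
                continue
            record = replace_panel(record, panel)
        kept.append(record)
    ledger.analyzable += len(kept)
    return kept, ledger


def replace_panel(record: ProductRecord, panel: NutrientPanel) -> ProductRecord:
    return ProductRecord(
        barcode=record.barcode,
        name=record.name,
        category_code=record.category_code,
        panel=panel,
        flags=record.flags,
        dilution_factor=record.dilution_factor,
        variety_pack=record.variety_pack,
        baby_food=record.baby_food,
        nutrient_error=record.nutrient_error,
    )


def ingest_pipeline(
    records: Sequence[ProductRecord],
    models: Sequence[ThresholdTable],
    taxonomy: Taxonomy,
) -> tuple[list[ProductRecord], ExclusionLedger]:
    """Full cascade: dedupe -> exclusions -> sufficiency/reconstitution."""
    ledger = ExclusionLedger()
    unique, ledger = deduplicate(records, ledger)
    assigned, ledger = apply_exclusions(unique, taxonomy, ledger)
    analyzable, ledger = prepare_analyzable(assigned, models, taxonomy, ledger)
    return analyzable, ledger
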