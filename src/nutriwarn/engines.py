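"""Data-driven nutrient profile model engines.

A model is a :class:`ThresholdTable` loaded from CSV: one row per rule, keyed
either by SEARO category code (category-scoped models) or by product form
(food/beverage models with ingredient gating, i.e. CWO semantics).  The engine
itself knows nothing about particular models; SEARO vs CWO behaviour lives in
the table data plus two small evaluation entry points.

Rules map onto warning-label identities through their ``label`` column, so two
rules for the same nutrient of concern (total vs added sugar) still contribute
at most one label.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .records import FLAG_NAMES, NUTRIENTS, IngredientFlags, NutrientPanel, ProductRecord, TriState
from .taxonomy import ProductForm, Taxonomy, product_form

COMPARATORS = ("greater_than", "at_least")

SEARO = "SEARO"
CWO_PHASE3 = "CWO_phase3"

#: Label identity recorded when the SEARO non-nutritive-sweetener rule fires.
NNS_LABEL = "nns"


class ScopeError(KeyError):
    """A record's category/form has no rule list in the table — a
    table/taxonomy mismatch, not a data error."""


@dataclass(frozen=True)
class ThresholdRule:
    nutrient: str
    limit: float
    comparator: str = "greater_than"
    gate: tuple[str, ...] = ()  # ingredient flags; any "yes" opens the gate
    label: str = ""

    def __post_init__(self) -> None:
        if self.nutrient not in NUTRIENTS:
            raise ValueError(f"unknown nutrient: {self.nutrient!r}")
        if self.comparator not in COMPARATORS:
            raise ValueError(f"unknown comparator: {self.comparator!r}")
        if self.limit < 0:
            raise ValueError("limit must be non-negative")
        for flag in self.gate:
            if flag not in FLAG_NAMES:
                raise ValueError(f"unknown gate flag: {flag!r}")
        if not self.label:
            object.__setattr__(self, "label", self.nutrient)

    def exceeded_by(self, amount: float) -> bool:
        if self.comparator == "greater_than":
            return amount > self.limit
        return amount >= self.limit


@dataclass
class ThresholdTable:
    model_name: str
    scope: dict[str, list[ThresholdRule]]
    nns_rule_enabled: bool = False
    units: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def form_scoped(self) -> bool:
        """True when scope keys are product forms rather than category codes."""
        return set(self.scope) <= {ProductForm.FOOD.value, ProductForm.BEVERAGE.value}

    @classmethod
    def from_csv(
        cls,
        path: Path | str,
        model_name: str,
        nns_rule_enabled: bool = False,
    ) -> "ThresholdTable":
        scope: dict[str, list[ThresholdRule]] = {}
        units: dict[tuple[str, str], str] = {}
        with open(path, newline="", encoding="utf-8") as handle:
            for row in csv.DictReader(handle):
                key = row["scope"].strip()
                gate_text = (row.get("gate") or "").strip()
                gate = tuple(g for g in gate_text.split("|") if g)
                rule = ThresholdRule(
                    nutrient=row["nutrient"].strip(),
                    limit=float(row["limit"]),
                    comparator=(row.get("comparator") or "greater_than").strip(),
                    gate=gate,
                    label=(row.get("label") or "").strip(),
                )
                scope.setdefault(key, []).append(rule)
                units[(key, rule.nutrient)] = (row.get("unit") or "").strip()
        return cls(model_name=model_name, scope=scope, nns_rule_enabled=nns_rule_enabled, units=units)

    @classmethod
    def default_searo(cls) -> "ThresholdTable":
        ref = resources.files("nutriwarn.data") / "searo_thresholds.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path, model_name=SEARO, nns_rule_enabled=True)

    @classmethod
    def default_cwo_phase3(cls) -> "ThresholdTable":
        ref = resources.files("nutriwarn.data") / "cwo_phase3_thresholds.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path, model_name=CWO_PHASE3, nns_rule_enabled=False)

    def rules_for(self, record: ProductRecord, taxonomy: Taxonomy) -> list[ThresholdRule]:
        key = self.scope_key_for(record, taxonomy)
        try:
            return self.scope[key]
        except KeyError:
            raise ScopeError(
                f"{self.model_name}: no rules for scope key {key!r}"
            ) from None

    def scope_key_for(self, record: ProductRecord, taxonomy: Taxonomy) -> str:
        category = taxonomy.lookup_category(record.category_code)
        if self.form_scoped:
            return product_form(category).value
        return category.code

    def referenced_nutrients(self, record: ProductRecord, taxonomy: Taxonomy) -> frozenset[str]:
        """Nutrients any applicable rule reads, gated or not (sufficiency is
        assessed before gating)."""
        return frozenset(r.nutrient for r in self.rules_for(record, taxonomy))

    def validate(self, taxonomy: Taxonomy) -> list[str]:
        """Structural diagnostics: scope completeness, unit sanity."""
        problems: list[str] = []
        if self.form_scoped:
            for form in (ProductForm.FOOD, ProductForm.BEVERAGE):
                if form.value not in self.scope:
                    problems.append(f"missing form scope: {form.value}")
        else:
            for cat in taxonomy:
                if cat.code not in self.scope:
                    problems.append(f"missing category scope: {cat.code}")
            for key in self.scope:
                if key not in taxonomy:
                    problems.append(f"scope key not in taxonomy: {key}")
        expected_units = {"energy": "kcal", "sodium": "mg"}
        for (key, nutrient), unit in self.units.items():
            expected = expected_units.get(nutrient, "g")
            if unit and unit != expected:
                problems.append(f"{key}/{nutrient}: unit {unit!r}, expected {expected!r}")
        return problems


@dataclass(frozen=True)
class EvaluationResult:
    model_name: str
    criteria_met: frozenset[str]
    nns_triggered: bool = False

    @property
    def label_count(self) -> int:
        return len(self.criteria_met)

    @property
    def meets_any(self) -> bool:
        return self.label_count >= 1 or self.nns_triggered


def _evaluate_rules(
    panel: NutrientPanel,
    flags: IngredientFlags,
    rules: Iterable[ThresholdRule],
    apply_gates: bool,
    gate_unknown_strict: bool = False,
) -> set[str]:
    met: set[str] = set()
    for rule in rules:
        if apply_gates and rule.gate:
            states = [flags.get(f) for f in rule.gate]
            if gate_unknown_strict:
                open_ = any(s in (TriState.YES, TriState.UNKNOWN) for s in states)
            else:
                open_ = any(s is TriState.YES for s in states)
            if not open_:
                continue
        amount = panel.get(rule.nutrient)
        if amount is not None and rule.exceeded_by(amount):
            met.add(rule.label)
    return met


def evaluate_searo(
    record: ProductRecord,
    table: ThresholdTable,
    taxonomy: Taxonomy,
    nns_counts_as_label: bool = True,
) -> EvaluationResult:
    """Category-scoped evaluation; the NNS rule forces ``meets_any`` when the
    product declares a non-nutritive sweetener.

    ``nns_counts_as_label`` controls whether the NNS trigger also adds a label
    to ``criteria_met`` (and hence to the 0/1/2/3+ distribution) or only
    forces ``meets_any``.
    """
    rules = table.rules_for(record, taxonomy)
    met = _evaluate_rules(record.panel, record.flags, rules, apply_gates=True)
    nns = bool(table.nns_rule_enabled and record.flags.nns is TriState.YES)
    if nns and nns_counts_as_label:
        met.add(NNS_LABEL)
    return EvaluationResult(table.model_name, frozenset(met), nns_triggered=nns)


def evaluate_cwo(
    record: ProductRecord,
    table: ThresholdTable,
    taxonomy: Taxonomy,
    gate_unknown_strict: bool = False,
) -> EvaluationResult:
    """Form-scoped evaluation with added-ingredient gating: a gated rule is
    skipped unless a gate flag is declared "yes" (unknown counts as "no"
    unless ``gate_unknown_strict``)."""
    rules = table.rules_for(record, taxonomy)
    met = _evaluate_rules(
        record.panel,
        record.flags,
        rules,
        apply_gates=True,
        gate_unknown_strict=gate_unknown_strict,
    )
    return EvaluationResult(table.model_name, frozenset(met))


def evaluate(record: ProductRecord, table: ThresholdTable, taxonomy: Taxonomy, **kwargs) -> EvaluationResult:
    """Dispatch on table semantics (form-scoped+gated vs category-scoped)."""
    if table.form_scoped:
        return evaluate_cwo(record, table, taxonomy, **kwargs)
    return evaluate_searo(record, table, taxonomy, **kwargs)


class BatchEvaluationError(RuntimeError):
    def __init__(self, barcode: str, cause: Exception):
        super().__init__(f"evaluation failed for barcode {barcode!r}: {cause}")
        self.barcode = barcode
        self.cause = cause


def evaluate_batch(
    records: Sequence[ProductRecord],
    tables: Sequence[ThresholdTable],
    taxonomy: Taxonomy,
    nns_counts_as_label: bool = True,
    gate_unknown_strict: bool = False,
) -> list[dict[str, EvaluationResult]]:
    """Order-preserving pure evaluation of every record against every model."""
    out: list[dict[str, EvaluationResult]] = []
    for record in records:
        per_model: dict[str, EvaluationResult] = {}
        for table in tables:
            try:
                if table.form_scoped:
                    per_model[table.model_name] = evaluate_cwo(
                        record, table, taxonomy, gate_unknown_strict=gate_unknown_strict
                    )
                else:
                    per_model[table.model_name] = evaluate_searo(
                        record, table, taxonomy, nns_counts_as_label=nns_counts_as_label
                    )
            except Exception as exc:  # attach offending barcode
                raise BatchEvaluationError(record.barcode, exc) from exc
        out.append(per_model)
    return out
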