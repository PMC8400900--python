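"""Aggregate per-product evaluations into coverage and label-count tables.

Percentages are always 100 x numerator / denominator; the display policy
(round-half-up vs truncate, number of decimals) is explicit because source
tables of this kind are frequently inconsistent about it.  Empty denominators
render "-", never 0 or NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .engines import EvaluationResult
from .ingestion import ExclusionLedger
from .records import ProductRecord
from .taxonomy import Taxonomy

TOTAL_CODE = "Total"


@dataclass(frozen=True)
class RoundingPolicy:
    """How percentages are rendered: ``round`` (half-up) or ``truncate``."""

    mode: str = "round"
    decimals: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("round", "truncate"):
            raise ValueError(f"unknown rounding mode: {self.mode!r}")
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")

    def apply(self, value: float) -> float:
        quantum = Decimal(1).scaleb(-self.decimals)
        rounding = ROUND_HALF_UP if self.mode == "round" else ROUND_DOWN
        return float(Decimal(repr(value)).quantize(quantum, rounding=rounding))


def percentage(numerator: int, denominator: int, policy: Optional[RoundingPolicy] = None) -> Optional[float]:
    """100 x num / den, rendered per policy; ``None`` for an empty denominator."""
    if denominator == 0:
        return None
    raw = 100.0 * numerator / denominator
    return policy.apply(raw) if policy else raw


def format_pct(value: Optional[float], decimals: int = 1) -> str:
    if value is None:
        return "-"
    return f"{value:.{decimals}f}" if decimals else f"{value:.0f}"


def label_distribution(
    label_counts: Sequence[int],
    bucket_top: int = 3,
    policy: Optional[RoundingPolicy] = None,
) -> tuple[list[int], list[Optional[float]]]:
    """Bucket counts top-coded at ``bucket_top`` (0, 1, ..., bucket_top+).

    Returns (counts, percentages); buckets partition the input so counts sum
    to ``len(label_counts)``.
    """
    if bucket_top < 1:
        raise ValueError("bucket_top must be >= 1")
    counts = [0] * (bucket_top + 1)
    for n in label_counts:
        if n < 0:
            raise ValueError("label counts must be non-negative")
        counts[min(n, bucket_top)] += 1
    total = len(label_counts)
    pcts = [percentage(c, total, policy) for c in counts]
    return counts, pcts


@dataclass
class ModelStats:
    """Per-category coverage and label-count distribution for one model."""

    n_meeting_any: int = 0
    bucket_counts: list[int] = field(default_factory=list)
    #: count meeting via threshold labels alone, ignoring any forced-trigger
    #: convention (differs from n_meeting_any only for NNS-only products).
    n_meeting_by_labels: int = 0

    def pct_meeting_any(self, n_evaluable: int, policy: Optional[RoundingPolicy] = None) -> Optional[float]:
        return percentage(self.n_meeting_any, n_evaluable, policy)


@dataclass
class CategoryReport:
    category_code: str
    category_name: str
    n_total: int
    n_evaluable: int
    models: dict[str, ModelStats] = field(default_factory=dict)


@dataclass
class StudyReport:
    rows: list[CategoryReport]
    total: CategoryReport
    model_names: list[str]
    policy: RoundingPolicy
    bucket_top: int = 3
    ledger: Optional[ExclusionLedger] = None

    def row(self, code: str) -> CategoryReport:
        if code == TOTAL_CODE:
            return self.total
        for r in self.rows:
            if r.category_code == code:
                return r
        raise KeyError(code)

    def coverage_pct(self, code: str, model: str, policy: Optional[RoundingPolicy] = None) -> Optional[float]:
        row = self.row(code)
        return row.models[model].pct_meeting_any(row.n_evaluable, policy or self.policy)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for row in [self.total] + self.rows:
            entry: dict[str, object] = {
                "category_code": row.category_code,
                "category_name": row.category_name,
                "n_total": row.n_total,
                "n_evaluable": row.n_evaluable,
            }
            for model in self.model_names:
                stats = row.models[model]
                pct = stats.pct_meeting_any(row.n_evaluable, self.policy)
                entry[f"{model}_n_meeting"] = stats.n_meeting_any
                entry[f"{model}_pct_meeting"] = format_pct(pct, self.policy.decimals)
                if stats.bucket_counts:
                    total_eval = row.n_evaluable
                    for i, count in enumerate(stats.bucket_counts):
                        name = f"{i}" if i < len(stats.bucket_counts) - 1 else f"{i}+"
                        entry[f"{model}_labels_{name}_pct"] = format_pct(
                            percentage(count, total_eval, self.policy), self.policy.decimals
                        )
            records.append(entry)
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_text(self) -> str:
        return self.to_dataframe().to_string(index=False)

    def summary(self) -> dict:
        """Headline numbers for machine consumption."""
        out: dict[str, object] = {
            "n_evaluable": self.total.n_evaluable,
            "models": {},
        }
        for model in self.model_names:
            stats = self.total.models[model]
            pct = stats.pct_meeting_any(self.total.n_evaluable, self.policy)
            bucket_pcts = [
                percentage(c, self.total.n_evaluable, self.policy)
                for c in stats.bucket_counts
            ]
            out["models"][model] = {
                "n_meeting_any": stats.n_meeting_any,
                "pct_meeting_any": pct,
                "n_meeting_by_labels": stats.n_meeting_by_labels,
                "bucket_counts": stats.bucket_counts,
                "bucket_pcts": bucket_pcts,
            }
        return out


class ReportIntegrityError(ValueError):
    pass


def build_report(
    results: Sequence[Mapping[str, EvaluationResult]],
    records: Sequence[ProductRecord],
    taxonomy: Taxonomy,
    rounding: RoundingPolicy = RoundingPolicy(),
    n_total_by_category: Optional[Mapping[str, int]] = None,
    bucket_top: int = 3,
    ledger: Optional[ExclusionLedger] = None,
) -> StudyReport:
    """Fold aligned (record, per-model result) pairs into a study report.

    ``n_total_by_category`` supplies the category-assigned counts (pre
    sufficiency cut); when omitted the evaluable counts are used.
    """
    if len(results) != len(records):
        raise ReportIntegrityError(
            f"{len(results)} result rows vs {len(records)} records"
        )
    model_names: list[str] = []
    for per_model in results:
        for name in per_model:
            if name not in model_names:
                model_names.append(name)

    by_code: dict[str, list[tuple[ProductRecord, Mapping[str, EvaluationResult]]]] = {
        cat.code: [] for cat in taxonomy
    }
    for record, per_model in zip(records, results):
        category = taxonomy.category_for(record.category_code)
        if category is None:
            raise ReportIntegrityError(
                f"barcode {record.barcode!r}: unknown category {record.category_code!r}"
            )
        by_code[category.code].append((record, per_model))

    def stats_for(pairs, model: str) -> ModelStats:
        label_counts = [pm[model].label_count for _, pm in pairs if model in pm]
        meets = sum(1 for _, pm in pairs if model in pm and pm[model].meets_any)
        by_labels = sum(1 for n in label_counts if n >= 1)
        counts, _ = label_distribution(label_counts, bucket_top) if label_counts else ([0] * (bucket_top + 1), [])
        return ModelStats(n_meeting_any=meets, bucket_counts=counts, n_meeting_by_labels=by_labels)

    rows: list[CategoryReport] = []
    for cat in taxonomy:
        pairs = by_code[cat.code]
        n_eval = len(pairs)
        n_total = (
            n_total_by_category.get(cat.code, n_eval) if n_total_by_category else n_eval
        )
        rows.append(
            CategoryReport(
                category_code=cat.code,
                category_name=cat.name,
                n_total=n_total,
                n_evaluable=n_eval,
                models={m: stats_for(pairs, m) for m in model_names},
            )
        )

    all_pairs = [p for cat in taxonomy for p in by_code[cat.code]]
    total = CategoryReport(
        category_code=TOTAL_CODE,
        category_name="Total",
        n_total=sum(r.n_total for r in rows),
        n_evaluable=len(all_pairs),
        models={m: stats_for(all_pairs, m) for m in model_names},
    )
    return StudyReport(
        rows=rows,
        total=total,
        model_names=model_names,
        policy=rounding,
        bucket_top=bucket_top,
        ledger=ledger,
    )


def compare_models(
    report: StudyReport, model_a: str, model_b: str
) -> tuple[list[tuple[str, Optional[float]]], Optional[str]]:
    """Signed per-category coverage differences (A minus B, unrounded) and the
    code of the largest absolute gap among categories with evaluable products."""
    diffs: list[tuple[str, Optional[float]]] = []
    largest: Optional[str] = None
    largest_gap = -1.0
    for row in report.rows:
        if row.n_evaluable == 0:
            diffs.append((row.category_code, None))
            continue
        a = row.models[model_a].pct_meeting_any(row.n_evaluable)
        b = row.models[model_b].pct_meeting_any(row.n_evaluable)
        gap = a - b
        diffs.append((row.category_code, gap))
        if abs(gap) > largest_gap:
            largest_gap = abs(gap)
            largest = row.category_code
    return diffs, largest
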