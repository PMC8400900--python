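"""Seeded synthetic product databases.

Generates records with the statistical structure the pipeline assumes:
a configurable category mix, right-skewed (log-normal) nutrient amounts with
component nutrients derived as fractions of their totals, ingredient flags
correlated with amounts through a logistic link, per-nutrient missingness,
planted duplicates/errors, and "as sold" concentrates with or without
dilution instructions.  Also provides industry-style biased subsampling and
coverage calibration so selection-bias experiments are reproducible.

All randomness flows from one ``numpy`` generator seeded in the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .engines import EvaluationResult, ThresholdTable
from .records import Basis, IngredientFlags, NutrientPanel, PerUnit, ProductRecord, TriState
from .taxonomy import Taxonomy

#: Category mix of a large packaged-food extract (category-assigned counts),
#: used as the default category weighting.
DEFAULT_CATEGORY_COUNTS: dict[str, int] = {
    "1": 3148, "2": 2669, "3": 1050, "4": 2619, "5A": 4092, "5B": 1022,
    "5C": 4, "6A": 517, "6B": 905, "6C": 2123, "6D": 1883, "6E": 249,
    "7": 595, "8": 426, "9": 626, "10": 1219, "11": 1715, "12": 630,
    "13": 20, "14A": 466, "14B": 216, "15": 89, "16": 2448, "17": 86,
    "18": 2702,
}

#: Nutrients drawn directly from log-normals; saturated fat and added sugar
#: are generated as fractions of their totals so panel invariants hold.
BASE_NUTRIENTS = ("energy", "total_fat", "total_sugar", "sodium")

#: Plausibility caps per 100 g / 100 ml.
CAPS = {"energy": 900.0, "total_fat": 100.0, "total_sugar": 100.0, "sodium": 10000.0}

_SAT_FRACTION = (0.2, 0.9)
_ADDED_FRACTION = (0.3, 1.0)


class ConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_products: int = 1000
    category_weights: dict[str, float] = field(default_factory=dict)
    #: per category: nutrient -> (log-location, log-scale); sigma 0 is a point mass
    nutrient_params: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    #: per-nutrient probability an amount is absent from the panel
    missingness: dict[str, float] = field(default_factory=dict)
    flag_unknown_rate: float = 0.10
    nns_rate_food: float = 0.01
    nns_rate_beverage: float = 0.05
    duplicate_rate: float = 0.0
    error_rate: float = 0.0
    no_category_rate: float = 0.0
    variety_rate: float = 0.0
    baby_rate: float = 0.0
    #: probability a record is generated "as sold" with dilution instructions
    p_as_sold: float = 0.05
    #: probability a record is "as sold" with NO instructions (excluded later)
    p_no_instructions: float = 0.0

    def validate(self) -> None:
        if self.n_products < 0:
            raise ConfigError("n_products must be >= 0")
        if not self.category_weights:
            raise ConfigError("category_weights must be non-empty")
        total = sum(self.category_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ConfigError(f"category_weights sum to {total}, expected 1")
        probs = {
            "flag_unknown_rate": self.flag_unknown_rate,
            "nns_rate_food": self.nns_rate_food,
            "nns_rate_beverage": self.nns_rate_beverage,
            "duplicate_rate": self.duplicate_rate,
            "error_rate": self.error_rate,
            "no_category_rate": self.no_category_rate,
            "variety_rate": self.variety_rate,
            "baby_rate": self.baby_rate,
            "p_as_sold": self.p_as_sold,
            "p_no_instructions": self.p_no_instructions,
            **{f"missingness[{k}]": v for k, v in self.missingness.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} = {p} outside [0, 1]")

    @classmethod
    def default(
        cls,
        seed: int = 0,
        n_products: int = 1000,
        taxonomy: Optional[Taxonomy] = None,
        tables: Optional[Sequence[ThresholdTable]] = None,
        target_sufficiency_fail: float = 19722 / 31519,
        target_no_instructions: float = 1296 / 11797,
    ) -> "GeneratorConfig":
        """Defaults tuned so the exclusion cascade removes roughly the same
        fractions as a real-world extract: ~62.6% failing sufficiency and
        ~11% of the survivors lacking reconstitution instructions."""
        taxonomy = taxonomy or Taxonomy.default()
        tables = list(tables) if tables else [ThresholdTable.default_searo(), ThresholdTable.default_cwo_phase3()]
        total = sum(DEFAULT_CATEGORY_COUNTS.values())
        weights = {c: n / total for c, n in DEFAULT_CATEGORY_COUNTS.items()}
        params = {cat.code: default_nutrient_params(cat.code, tables) for cat in taxonomy}
        p_miss = solve_missingness(target_sufficiency_fail, weights, taxonomy, tables)
        return cls(
            seed=seed,
            n_products=n_products,
            category_weights=weights,
            nutrient_params=params,
            missingness={n: p_miss for n in ("energy", "total_fat", "saturated_fat", "total_sugar", "added_sugar", "sodium")},
            p_no_instructions=target_no_instructions,
        )


def default_nutrient_params(code: str, tables: Sequence[ThresholdTable]) -> dict[str, tuple[float, float]]:
    """Centre each base nutrient's log-normal on the category's own limit when
    one exists (≈50% exceedance per rule), else on a generic magnitude."""
    generic = {"energy": (math.log(200.0), 0.6), "total_fat": (math.log(8.0), 0.8),
               "total_sugar": (math.log(8.0), 1.0), "sodium": (math.log(300.0), 1.0)}
    params = dict(generic)
    for table in tables:
        rules = table.scope.get(code, [])
        for rule in rules:
            if rule.nutrient in BASE_NUTRIENTS:
                params[rule.nutrient] = (math.log(max(rule.limit, 0.5)), 0.8)
    return params


def _required_union(code: str, taxonomy: Taxonomy, tables: Sequence[ThresholdTable]) -> frozenset[str]:
    cat = taxonomy.lookup_category(code)
    needed: set[str] = set()
    for table in tables:
        key = ("beverage" if cat.is_beverage else "food") if table.form_scoped else cat.code
        needed |= {r.nutrient for r in table.scope.get(key, [])}
    return frozenset(needed)


def solve_missingness(
    target_fail: float,
    weights: Mapping[str, float],
    taxonomy: Taxonomy,
    tables: Sequence[ThresholdTable],
) -> float:
    """Per-nutrient absence probability p such that, with independent drops,
    the weighted probability of failing sufficiency matches ``target_fail``.
    Solved by bisection on Σ_c w_c (1 - (1-p)^{k_c}) = target."""
    ks = {code: len(_required_union(code, taxonomy, tables)) for code in weights}

    def fail(p: float) -> float:
        return sum(w * (1.0 - (1.0 - p) ** ks[c]) for c, w in weights.items())

    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if fail(mid) < target_fail:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _sample_amounts(
    rng: np.random.Generator, params: Mapping[str, tuple[float, float]]
) -> dict[str, float]:
    """One full consistent panel (all six nutrients, invariants satisfied)."""
    amounts: dict[str, float] = {}
    for nutrient in BASE_NUTRIENTS:
        mu, sigma = params[nutrient]
        value = math.exp(mu + sigma * rng.standard_normal()) if sigma > 0 else math.exp(mu)
        amounts[nutrient] = min(value, CAPS[nutrient])
    amounts["saturated_fat"] = amounts["total_fat"] * rng.uniform(*_SAT_FRACTION)
    amounts["added_sugar"] = amounts["total_sugar"] * rng.uniform(*_ADDED_FRACTION)
    return amounts


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _draw_flag(rng: np.random.Generator, p_yes: float, unknown_rate: float) -> TriState:
    if rng.random() < unknown_rate:
        return TriState.UNKNOWN
    return TriState.YES if rng.random() < p_yes else TriState.NO


def _sample_flags(
    rng: np.random.Generator, amounts: Mapping[str, float], is_beverage: bool, config: GeneratorConfig
) -> IngredientFlags:
    # logistic links keep flags correlated with the amounts they gate
    p_sugar = _sigmoid(0.6 * (amounts["added_sugar"] - 4.0))
    p_sodium = _sigmoid(0.01 * (amounts["sodium"] - 200.0))
    p_sat = _sigmoid(0.8 * (amounts["saturated_fat"] - 3.0))
    nns_rate = config.nns_rate_beverage if is_beverage else config.nns_rate_food
    return IngredientFlags(
        added_sugar=_draw_flag(rng, p_sugar, config.flag_unknown_rate),
        added_sodium=_draw_flag(rng, p_sodium, config.flag_unknown_rate),
        added_sat_fat=_draw_flag(rng, p_sat, config.flag_unknown_rate),
        nns=_draw_flag(rng, nns_rate, config.flag_unknown_rate),
    )


def generate(config: GeneratorConfig, taxonomy: Optional[Taxonomy] = None) -> list[ProductRecord]:
    """Deterministic product database for a config; see module docstring."""
    config.validate()
    taxonomy = taxonomy or Taxonomy.default()
    rng = np.random.default_rng(config.seed)
    codes = sorted(config.category_weights)
    weights = np.array([config.category_weights[c] for c in codes])
    weights = weights / weights.sum()

    records: list[ProductRecord] = []
    for i in range(config.n_products):
        code = codes[rng.choice(len(codes), p=weights)]
        cat = taxonomy.lookup_category(code)
        params = config.nutrient_params.get(code) or default_nutrient_params(code, [])
        amounts = _sample_amounts(rng, params)
        flags = _sample_flags(rng, amounts, cat.is_beverage, config)

        # preparation basis: concentrates carry amplified "as sold" amounts
        basis, per = Basis.AS_CONSUMED, (PerUnit.PER_100ML if cat.is_beverage else PerUnit.PER_100G)
        dilution: Optional[float] = None
        u_prep = rng.random()
        factor = float(rng.uniform(2.0, 8.0))
        if u_prep < config.p_no_instructions:
            basis, per = Basis.AS_SOLD, PerUnit.PER_100G
            amounts = {k: v * factor for k, v in amounts.items()}
        elif u_prep < config.p_no_instructions + config.p_as_sold:
            basis, per = Basis.AS_SOLD, PerUnit.PER_100G
            amounts = {k: v * factor for k, v in amounts.items()}
            dilution = factor

        present = {
            n: (None if rng.random() < config.missingness.get(n, 0.0) else v)
            for n, v in amounts.items()
        }
        panel = NutrientPanel(basis=basis, per=per, **present)

        category_code = code
        nutrient_error = False
        u_plant = rng.random()
        if u_plant < config.error_rate:
            nutrient_error = True
        elif u_plant < config.error_rate + config.no_category_rate:
            category_code = "99"
        variety = rng.random() < config.variety_rate
        baby = (not variety) and rng.random() < config.baby_rate

        records.append(
            ProductRecord(
                barcode=f"B{i:07d}",
                name=f"product-{i}",
                category_code=category_code,
                panel=panel,
                flags=flags,
                dilution_factor=dilution,
                variety_pack=variety,
                baby_food=baby,
                nutrient_error=nutrient_error,
            )
        )

    n_dups = int(round(config.duplicate_rate * config.n_products))
    if n_dups and records:
        for j in rng.integers(0, len(records), size=n_dups):
            records.append(records[int(j)])
    return records


@dataclass(frozen=True)
class BiasSpec:
    """Industry-style selection: products are over-sampled in proportion to
    ``(1 + label_count) ** weight_exponent``; exponent 0 is simple random
    sampling."""

    sample_size: int = 1306
    weight_exponent: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_size < 0:
            raise ValueError("sample_size must be >= 0")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")


def biased_subsample(
    records: Sequence[ProductRecord],
    results: Sequence[Mapping[str, EvaluationResult]],
    spec: BiasSpec,
    seed: int,
    model_name: Optional[str] = None,
) -> list[ProductRecord]:
    """Weighted sampling without replacement (Efraimidis–Spirakis keys)."""
    if len(records) != len(results):
        raise ValueError("records and results must align")
    if spec.sample_size >= len(records):
        return list(records)
    rng = np.random.default_rng(seed)
    counts = []
    for per_model in results:
        name = model_name or next(iter(per_model))
        counts.append(per_model[name].label_count)
    weights = (1.0 + np.asarray(counts, dtype=float)) ** spec.weight_exponent
    keys = rng.random(len(records)) ** (1.0 / weights)
    chosen = np.argsort(keys)[-spec.sample_size:]
    return [records[i] for i in sorted(chosen)]


def calibrate_to_table1(
    targets: Mapping[str, float],
    base_config: Optional[GeneratorConfig] = None,
    table: Optional[ThresholdTable] = None,
    taxonomy: Optional[Taxonomy] = None,
    n_probe: int = 2000,
    tol: float = 1.0,
    probe_seed: int = 12345,
) -> GeneratorConfig:
    """Shift each category's log-locations (monotone bisection) so expected
    coverage — the fraction of panels meeting at least one rule — matches the
    target percentage within ``tol`` points.

    Targets of 0 or 100 are met exactly with degenerate point-mass panels.
    """
    taxonomy = taxonomy or Taxonomy.default()
    table = table or ThresholdTable.default_searo()
    config = base_config or GeneratorConfig.default(taxonomy=taxonomy)
    params = {c: dict(p) for c, p in config.nutrient_params.items()}

    for code, target in targets.items():
        if not 0.0 <= target <= 100.0:
            raise ConfigError(f"target for {code} outside [0, 100]: {target}")
        cat_params = params.get(code) or default_nutrient_params(code, [table])
        if target <= 0.0:
            params[code] = {n: (-30.0, 0.0) for n in BASE_NUTRIENTS}
            continue
        if target >= 100.0:
            high = math.log(max(CAPS.values()) * 10)
            params[code] = {n: (high, 0.0) for n in BASE_NUTRIENTS}
            continue
        params[code] = _bisect_shift(
            code, cat_params, target, table, taxonomy, n_probe, tol, probe_seed
        )
    return replace(config, nutrient_params=params)


def _probe_coverage(
    code: str,
    cat_params: Mapping[str, tuple[float, float]],
    shift: float,
    z: Mapping[str, np.ndarray],
    fractions: tuple[np.ndarray, np.ndarray],
    rules,
) -> float:
    """Coverage of the category's rules over a fixed probe sample, as the
    log-locations slide by ``shift`` (common random numbers keep it monotone)."""
    sat_frac, added_frac = fractions
    amounts: dict[str, np.ndarray] = {}
    for nutrient in BASE_NUTRIENTS:
        mu, sigma = cat_params[nutrient]
        amounts[nutrient] = np.minimum(np.exp(mu + shift + sigma * z[nutrient]), CAPS[nutrient])
    amounts["saturated_fat"] = amounts["total_fat"] * sat_frac
    amounts["added_sugar"] = amounts["total_sugar"] * added_frac
    met = np.zeros(len(sat_frac), dtype=bool)
    for rule in rules:
        values = amounts[rule.nutrient]
        met |= values > rule.limit if rule.comparator == "greater_than" else values >= rule.limit
    return 100.0 * float(met.mean())


def _bisect_shift(
    code, cat_params, target, table, taxonomy, n_probe, tol, probe_seed
) -> dict[str, tuple[float, float]]:
    rng = np.random.default_rng(probe_seed)
    z = {n: rng.standard_normal(n_probe) for n in BASE_NUTRIENTS}
    fractions = (rng.uniform(*_SAT_FRACTION, n_probe), rng.uniform(*_ADDED_FRACTION, n_probe))
    rules = table.scope.get(code, [])
    if not rules:
        return dict(cat_params)

    lo, hi = -12.0, 12.0
    cov_lo = _probe_coverage(code, cat_params, lo, z, fractions, rules)
    cov_hi = _probe_coverage(code, cat_params, hi, z, fractions, rules)
    if target <= cov_lo:
        shift = lo
    elif target >= cov_hi:
        shift = hi
    else:
        for _ in range(60):
            mid = (lo + hi) / 2
            if _probe_coverage(code, cat_params, mid, z, fractions, rules) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-9:
                break
        shift = (lo + hi) / 2
    return {n: (mu + shift, sigma) for n, (mu, sigma) in cat_params.items()}


def exclusion_fixture(
    n_raw: int = 41_255,
    n_duplicates: int = 6_113,
    n_missing_or_error: int = 1_339,
    n_no_category: int = 1_921,
    n_variety: int = 204,
    n_baby: int = 159,
    n_missing_nutrients: int = 19_722,
    n_no_instructions: int = 1_296,
    seed: int = 0,
    taxonomy: Optional[Taxonomy] = None,
) -> list[ProductRecord]:
    """Deterministic dataset with exact planted counts for every stage of the
    exclusion cascade; the remainder is fully analyzable.

    Defaults mirror a large real-world extract: 41,255 rows -> 35,142 unique
    -> 31,519 category-assigned -> 10,501 analyzable.
    """
    taxonomy = taxonomy or Taxonomy.default()
    n_unique = n_raw - n_duplicates
    planted = n_missing_or_error + n_no_category + n_variety + n_baby
    if planted + n_missing_nutrients + n_no_instructions > n_unique:
        raise ConfigError("planted exclusions exceed the unique-record budget")
    rng = np.random.default_rng(seed)
    codes = [c.code for c in taxonomy]

    def clean(i: int, code: str) -> ProductRecord:
        # comfortably above zero, below every cap; all six nutrients present
        return ProductRecord(
            barcode=f"F{i:07d}",
            name=f"fixture-{i}",
            category_code=code,
            panel=NutrientPanel(
                energy=100.0, total_fat=5.0, saturated_fat=2.0,
                total_sugar=8.0, added_sugar=4.0, sodium=120.0,
                basis=Basis.AS_CONSUMED, per=PerUnit.PER_100G,
            ),
        )

    records: list[ProductRecord] = []
    i = 0
    for _ in range(n_missing_or_error):
        r = clean(i, codes[int(rng.integers(len(codes)))])
        r.nutrient_error = True
        records.append(r); i += 1
    for _ in range(n_no_category):
        r = clean(i, "99")
        records.append(r); i += 1
    for _ in range(n_variety):
        r = clean(i, codes[int(rng.integers(len(codes)))])
        r.variety_pack = True
        records.append(r); i += 1
    for _ in range(n_baby):
        r = clean(i, codes[int(rng.integers(len(codes)))])
        r.baby_food = True
        records.append(r); i += 1
    for _ in range(n_missing_nutrients):
        r = clean(i, codes[int(rng.integers(len(codes)))])
        r.panel = NutrientPanel(basis=Basis.AS_CONSUMED, per=PerUnit.PER_100G)  # nothing declared
        records.append(r); i += 1
    for _ in range(n_no_instructions):
        r = clean(i, codes[int(rng.integers(len(codes)))])
        r.panel = replace(r.panel, basis=Basis.AS_SOLD)
        r.dilution_factor = None
        records.append(r); i += 1
    while i < n_unique:
        records.append(clean(i, codes[int(rng.integers(len(codes)))])); i += 1

    records = [records[k] for k in rng.permutation(n_unique)]  # order must not matter
    for j in rng.integers(0, n_unique, size=n_duplicates):
        records.append(records[int(j)])
    return records
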