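"""Independent brute-force rule evaluator used as the oracle for the engines.

Deliberately shares no code with the package's evaluation path: it re-reads
the threshold CSVs with the stdlib csv module and applies every rule with
explicit comparisons.
"""

import csv
from importlib import resources


def load_threshold_rows(filename):
    ref = resources.files("nutriwarn.data") / filename
    with ref.open(encoding="utf-8") as handle:
        return list(csv.DictReader(handle))


def searo_oracle(category_code, amounts, nns_flag, rows, nns_counts_as_label=True):
    """Returns (labels, nns_triggered) for a category-scoped model with the
    non-nutritive-sweetener override.  ``amounts`` maps nutrient -> float or
    None; ``nns_flag`` is "yes"/"no"/"unknown"."""
    labels = set()
    for row in rows:
        if row["scope"] != category_code:
            continue
        amount = amounts.get(row["nutrient"])
        if amount is None:
            continue
        limit = float(row["limit"])
        if row["comparator"] == "greater_than":
            met = amount > limit
        elif row["comparator"] == "at_least":
            met = amount >= limit
        else:
            raise ValueError(row["comparator"])
        if met:
            labels.add(row["label"])
    nns_triggered = nns_flag == "yes"
    if nns_triggered and nns_counts_as_label:
        labels.add("nns")
    return labels, nns_triggered


def cwo_oracle(form, amounts, flag_states, rows, gate_unknown_strict=False):
    """Labels for a form-scoped gated model.  ``flag_states`` maps flag name
    -> "yes"/"no"/"unknown"."""
    labels = set()
    for row in rows:
        if row["scope"] != form:
            continue
        gates = [g for g in (row.get("gate") or "").split("|") if g]
        if gates:
            if gate_unknown_strict:
                gate_open = any(flag_states[g] in ("yes", "unknown") for g in gates)
            else:
                gate_open = any(flag_states[g] == "yes" for g in gates)
            if not gate_open:
                continue
        amount = amounts.get(row["nutrient"])
        if amount is None:
            continue
        limit = float(row["limit"])
        if row["comparator"] == "greater_than":
            met = amount > limit
        elif row["comparator"] == "at_least":
            met = amount >= limit
        else:
            raise ValueError(row["comparator"])
        if met:
            labels.add(row["label"])
    return labels


def random_record_inputs(rng, codes):
    """Draw a random product for oracle comparison: category, sparse amounts,
    tri-state flags."""
    code = codes[int(rng.integers(len(codes)))]
    amounts = {}
    for nutrient, scale in (
        ("energy", 400.0),
        ("total_fat", 40.0),
        ("saturated_fat", 20.0),
        ("total_sugar", 40.0),
        ("added_sugar", 25.0),
        ("sodium", 1200.0),
    ):
        if rng.random() < 0.15:
            amounts[nutrient] = None
        else:
            amounts[nutrient] = float(rng.random() * scale)
    states = ("yes", "no", "unknown")
    flags = {
        name: states[int(rng.integers(3))]
        for name in ("added_sugar", "added_sodium", "added_sat_fat", "nns")
    }
    return code, amounts, flags
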