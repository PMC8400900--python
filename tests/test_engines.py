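import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nutriwarn as nw
from nutriwarn.engines import BatchEvaluationError, ScopeError, evaluate_cwo, evaluate_searo
from nutriwarn.records import IngredientFlags, NutrientPanel, TriState

from conftest import make_record, zero_panel_record
from oracle import cwo_oracle, load_threshold_rows, random_record_inputs, searo_oracle

ALL_NO = IngredientFlags(TriState.NO, TriState.NO, TriState.NO, TriState.NO)
ALL_YES = IngredientFlags(TriState.YES, TriState.YES, TriState.YES, TriState.YES)


def searo_limit(table, code, nutrient):
    (rule,) = [r for r in table.scope[code] if r.nutrient == nutrient]
    return rule.limit


class TestEvaluateSearo:
    def test_zero_panel_meets_nothing(self, taxonomy, searo_table):
        result = evaluate_searo(zero_panel_record(flags=ALL_NO), searo_table, taxonomy)
        assert result.label_count == 0
        assert not result.meets_any

    def test_nns_alone_forces_meets_any(self, taxonomy, searo_table):
        flags = IngredientFlags(nns=TriState.YES)
        record = zero_panel_record(category_code="6C", flags=flags)
        result = evaluate_searo(record, searo_table, taxonomy)
        assert result.meets_any
        assert result.nns_triggered

    def test_nns_meets_any_only_mode(self, taxonomy, searo_table):
        flags = IngredientFlags(nns=TriState.YES)
        record = zero_panel_record(category_code="6C", flags=flags)
        result = evaluate_searo(record, searo_table, taxonomy, nns_counts_as_label=False)
        assert result.meets_any and result.label_count == 0

    def test_sugar_one_over_category1_limit(self, taxonomy, searo_table):
        # hand-applied oracle: only the sugar rule fires
        limit = searo_limit(searo_table, "1", "total_sugar")
        record = make_record(
            category_code="1", flags=ALL_NO,
            energy=0.0, total_fat=0.0, saturated_fat=0.0,
            total_sugar=limit + 1.0, added_sugar=0.0, sodium=0.0,
        )
        result = evaluate_searo(record, searo_table, taxonomy)
        assert result.criteria_met == frozenset({"sugar"})
        assert result.label_count == 1

    def test_amount_exactly_at_limit_not_met(self, taxonomy, searo_table):
        # shipped category rules use strict greater_than
        limit = searo_limit(searo_table, "1", "total_sugar")
        record = zero_panel_record(flags=ALL_NO)
        record.panel = dataclasses.replace(record.panel, total_sugar=limit)
        assert evaluate_searo(record, searo_table, taxonomy).label_count == 0

    def test_two_rules_same_label_count_once(self, taxonomy, searo_table):
        # category 2 has total_sugar and added_sugar rules, both labelled "sugar"
        record = make_record(
            category_code="2", flags=ALL_NO,
            energy=0.0, total_fat=0.0, saturated_fat=0.0,
            total_sugar=90.0, added_sugar=80.0, sodium=0.0,
        )
        result = evaluate_searo(record, searo_table, taxonomy)
        assert result.criteria_met == frozenset({"sugar"})

    def test_missing_scope_raises_scope_error(self, taxonomy, searo_table):
        table = dataclasses.replace(searo_table, scope={k: v for k, v in searo_table.scope.items() if k != "1"})
        with pytest.raises(ScopeError):
            evaluate_searo(zero_panel_record(), table, taxonomy)


class TestEvaluateCwo:
    def test_over_sugar_limit_but_not_added(self, taxonomy, cwo_table):
        record = make_record(
            category_code="6B", flags=ALL_NO,
            energy=0.0, total_fat=0.0, saturated_fat=0.0,
            total_sugar=9.0, added_sugar=0.0, sodium=0.0,
        )
        result = evaluate_cwo(record, cwo_table, taxonomy)
        assert "sugar" not in result.criteria_met
        assert result.label_count == 0

    def test_same_beverage_with_added_sugar_labelled(self, taxonomy, cwo_table):
        flags = IngredientFlags(added_sugar=TriState.YES)
        record = make_record(
            category_code="6B", flags=flags,
            energy=0.0, total_fat=0.0, saturated_fat=0.0,
            total_sugar=9.0, added_sugar=5.0, sodium=0.0,
        )
        result = evaluate_cwo(record, cwo_table, taxonomy)
        assert "sugar" in result.criteria_met

    def test_zero_panel_all_gates_open(self, taxonomy, cwo_table):
        result = evaluate_cwo(zero_panel_record(flags=ALL_YES), cwo_table, taxonomy)
        assert result.label_count == 0

    def test_gate_unknown_strict_mode(self, taxonomy, cwo_table):
        record = make_record(
            category_code="1",
            energy=0.0, total_fat=0.0, saturated_fat=0.0,
            total_sugar=50.0, added_sugar=0.0, sodium=0.0,
        )  # all flags unknown
        lax = evaluate_cwo(record, cwo_table, taxonomy)
        strict = evaluate_cwo(record, cwo_table, taxonomy, gate_unknown_strict=True)
        assert lax.label_count == 0
        assert "sugar" in strict.criteria_met


class TestEvaluateBatch:
    def test_empty(self, taxonomy, searo_table, cwo_table):
        assert nw.evaluate_batch([], [searo_table, cwo_table], taxonomy) == []

    def test_one_record_two_models(self, taxonomy, searo_table, cwo_table):
        out = nw.evaluate_batch([zero_panel_record()], [searo_table, cwo_table], taxonomy)
        assert len(out) == 1
        assert set(out[0]) == {nw.SEARO, nw.CWO_PHASE3}

    def test_batch_equals_singletons(self, taxonomy, searo_table, cwo_table):
        rng = np.random.default_rng(3)
        codes = [c.code for c in taxonomy]
        records = [_random_record(rng, codes, i) for i in range(40)]
        batch = nw.evaluate_batch(records, [searo_table, cwo_table], taxonomy)
        singles = [nw.evaluate_batch([r], [searo_table, cwo_table], taxonomy)[0] for r in records]
        assert batch == singles

    def test_error_carries_barcode(self, taxonomy, searo_table):
        broken = dataclasses.replace(searo_table, scope={})
        record = zero_panel_record(barcode="BAD001")
        with pytest.raises(BatchEvaluationError, match="BAD001"):
            nw.evaluate_batch([record], [broken], taxonomy)


def _random_record(rng, codes, i):
    code, amounts, flag_states = random_record_inputs(rng, codes)
    flags = IngredientFlags(**{k: TriState(v) for k, v in flag_states.items()})
    return nw.ProductRecord(
        barcode=f"R{i:05d}",
        name="r",
        category_code=code,
        panel=NutrientPanel(**amounts),
        flags=flags,
    )


class TestOracleEquivalence:
    def test_searo_matches_bruteforce(self, taxonomy, searo_table):
        rows = load_threshold_rows("searo_thresholds.csv")
        rng = np.random.default_rng(42)
        codes = [c.code for c in taxonomy]
        for i in range(2000):
            record = _random_record(rng, codes, i)
            expected, nns = searo_oracle(
                record.category_code,
                {n: record.panel.get(n) for n in nw.NUTRIENTS},
                record.flags.nns.value,
                rows,
            )
            result = evaluate_searo(record, searo_table, taxonomy)
            assert result.criteria_met == frozenset(expected)
            assert result.nns_triggered == nns

    def test_cwo_matches_bruteforce(self, taxonomy, cwo_table):
        rows = load_threshold_rows("cwo_phase3_thresholds.csv")
        rng = np.random.default_rng(43)
        codes = [c.code for c in taxonomy]
        for i in range(2000):
            record = _random_record(rng, codes, i)
            form = "beverage" if taxonomy.lookup_category(record.category_code).is_beverage else "food"
            expected = cwo_oracle(
                form,
                {n: record.panel.get(n) for n in nw.NUTRIENTS},
                {k: record.flags.get(k).value for k in ("added_sugar", "added_sodium", "added_sat_fat", "nns")},
                rows,
            )
            result = evaluate_cwo(record, cwo_table, taxonomy)
            assert result.criteria_met == frozenset(expected)


class TestProperties:
    @given(data=st.data())
    @settings(max_examples=300, deadline=None)
    def test_monotonic_in_amounts(self, data, taxonomy, searo_table, cwo_table):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31)))
        codes = [c.code for c in taxonomy]
        record = _random_record(rng, codes, 0)
        nutrient = data.draw(st.sampled_from(nw.NUTRIENTS))
        current = record.panel.get(nutrient)
        bumped = (current or 0.0) + data.draw(st.floats(min_value=0.0, max_value=500.0))
        higher = dataclasses.replace(record.panel, **{nutrient: bumped})
        record_hi = dataclasses.replace(record, panel=higher)
        for table, fn in ((searo_table, evaluate_searo), (cwo_table, evaluate_cwo)):
            assert fn(record_hi, table, taxonomy).label_count >= fn(record, table, taxonomy).label_count

    def test_gating_dominance(self, taxonomy, cwo_table):
        rng = np.random.default_rng(7)
        codes = [c.code for c in taxonomy]
        for i in range(300):
            record = _random_record(rng, codes, i)
            closed = evaluate_cwo(dataclasses.replace(record, flags=ALL_NO), cwo_table, taxonomy)
            opened = evaluate_cwo(dataclasses.replace(record, flags=ALL_YES), cwo_table, taxonomy)
            assert closed.label_count == 0  # every shipped CWO rule is gated
            assert closed.criteria_met <= opened.criteria_met

    def test_dairy_divergence_mechanism(self, taxonomy, searo_table, cwo_table):
        """Dairy beverages over the sugar limit without added sugar are
        labelled by the category model but not by the gated model — and the
        divergence vanishes when the added-sugar flag is set."""
        record = make_record(
            category_code="6B", flags=IngredientFlags(added_sugar=TriState.NO, nns=TriState.NO),
            energy=0.0, total_fat=0.0, saturated_fat=0.0,
            total_sugar=8.0, added_sugar=0.0, sodium=0.0,
        )
        searo = evaluate_searo(record, searo_table, taxonomy)
        cwo = evaluate_cwo(record, cwo_table, taxonomy)
        assert searo.meets_any and not cwo.meets_any

        flagged = dataclasses.replace(record, flags=IngredientFlags(added_sugar=TriState.YES, nns=TriState.NO))
        assert evaluate_cwo(flagged, cwo_table, taxonomy).meets_any


class TestThresholdTableValidation:
    def test_shipped_defaults_clean(self, taxonomy, searo_table, cwo_table):
        assert searo_table.validate(taxonomy) == []
        assert cwo_table.validate(taxonomy) == []

    def test_missing_category_reported(self, taxonomy, searo_table):
        table = dataclasses.replace(
            searo_table, scope={k: v for k, v in searo_table.scope.items() if k != "5C"}
        )
        assert any("5C" in p for p in table.validate(taxonomy))

    def test_negative_limit_rejected(self):
        with pytest.raises(ValueError):
            nw.ThresholdRule(nutrient="sodium", limit=-1.0)

    def test_unknown_nutrient_rejected(self):
        with pytest.raises(ValueError):
            nw.ThresholdRule(nutrient="fiber", limit=1.0)
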