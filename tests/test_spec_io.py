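"""Expression grammars and tabular template round trips."""

from __future__ import annotations

from datetime import date
from decimal import Decimal

import pytest
from hypothesis import given, settings, strategies as st

from peririsk.fixtures import (
    FixtureConfig,
    make_meningitis_fixture,
    print_rule,
    random_rule,
    random_spec,
)
from peririsk.risk_model import And, CondRef, Not, Or, validate_spec
from peririsk.spec_io import (
    ExprSyntaxError,
    SpecLayoutError,
    format_condition,
    format_probability,
    format_rule,
    parse_condition_expr,
    parse_probability,
    parse_rule_expr,
    read_spec,
    write_spec,
)

KPIS = {"Age_in_months": "number", "Vaccination_status": "text",
        "Weight_kg": "number", "Antibiotic_prevention": "boolean",
        "Birth_date": "date"}


class TestConditionGrammar:
    def test_age_interval_condition(self):
        cond = parse_condition_expr("c1: Age_in_months IN [0, 5)", KPIS)
        assert cond.id == "c1"
        assert cond.kpi == "Age_in_months"
        assert cond.operator == "IN"
        r = cond.range
        assert (r.lower, r.upper) == (Decimal(0), Decimal(5))
        assert r.lower_closed and not r.upper_closed

    def test_text_equality_condition(self):
        cond = parse_condition_expr('c4: Vaccination_status == "no"', KPIS)
        assert cond.kpi == "Vaccination_status"
        assert cond.operator == "=="
        assert cond.range.kind == "literal" and cond.range.literal == "no"

    def test_empty_half_open_interval_parses(self):
        cond = parse_condition_expr("cx: Weight_kg IN [5, 5)", KPIS)
        assert cond.range.is_empty_interval()

    def test_boolean_and_date_literals(self):
        cond = parse_condition_expr("c6: Antibiotic_prevention == false", KPIS)
        assert cond.range.literal is False
        cond = parse_condition_expr("c7: Birth_date >= 2015-06-01", KPIS)
        assert cond.range.literal == date(2015, 6, 1)

    def test_unbounded_interval_round_trips(self):
        text = "c8: Age_in_months IN [18, *)"
        cond = parse_condition_expr(text, KPIS)
        assert cond.range.upper is None
        assert format_condition(cond) == text

    def test_arithmetic_lhs(self):
        cond = parse_condition_expr(
            "c9: (Age_in_months + Weight_kg) / 2 < 10", KPIS)
        assert cond.lhs_expression == "(Age_in_months + Weight_kg) / 2"
        assert cond.kpi == "Age_in_months"
        assert cond.range.literal == Decimal(10)

    def test_unknown_kpi_rejected_with_position(self):
        with pytest.raises(ExprSyntaxError, match="Pulse"):
            parse_condition_expr("c1: Pulse IN [0, 5)", KPIS)

    def test_syntax_error_carries_column(self):
        with pytest.raises(ExprSyntaxError) as err:
            parse_condition_expr("c1: Age_in_months IN [0, ]", KPIS)
        assert err.value.column == 25

    @pytest.mark.parametrize("brackets,at_lower,at_upper", [
        ("[]", True, True), ("[)", True, False),
        ("(]", False, True), ("()", False, False),
    ])
    def test_bracket_openness_at_exact_bounds(self, brackets, at_lower, at_upper):
        text = f"c1: Age_in_months IN {brackets[0]}2, 8{brackets[1]}"
        rng = parse_condition_expr(text, KPIS).range
        assert rng.contains(Decimal(2)) is at_lower
        assert rng.contains(Decimal(8)) is at_upper
        assert rng.contains(Decimal(5))
        assert not rng.contains(Decimal(9))


class TestRuleGrammar:
    def test_worked_example_rule(self):
        ast = parse_rule_expr("(c1 AND c4 AND c6) OR (c3 AND c5 AND c6)")
        assert ast == Or((And((CondRef("c1"), CondRef("c4"), CondRef("c6"))),
                          And((CondRef("c3"), CondRef("c5"), CondRef("c6")))))

    def test_atomic_rule(self):
        assert parse_rule_expr("c1") == CondRef("c1")

    def test_not_binds_tighter_than_and_than_or(self):
        ast = parse_rule_expr("NOT (c1 OR c2) AND c3")
        assert ast == And((Not(Or((CondRef("c1"), CondRef("c2")))),
                           CondRef("c3")))
        assert parse_rule_expr("NOT c1 AND c2 OR c3") == Or((
            And((Not(CondRef("c1")), CondRef("c2"))), CondRef("c3")))

    def test_same_operator_nesting_is_flattened(self):
        assert parse_rule_expr("c1 AND (c2 AND c3)") == \
            And((CondRef("c1"), CondRef("c2"), CondRef("c3")))

    def test_unknown_condition_id_rejected(self):
        with pytest.raises(ExprSyntaxError, match="c9"):
            parse_rule_expr("c1 AND c9", ["c1", "c2"])

    @settings(max_examples=300, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_grammar_totality_on_printed_rules(self, seed):
        """Every rule emitted by the independent fixture printer parses
        back to the identical AST."""
        import random

        rng = random.Random(seed)
        ids = [f"c{i}" for i in range(1, rng.randint(2, 9))]
        rule = random_rule(rng, ids)
        assert parse_rule_expr(print_rule(rule), ids) == rule
        assert parse_rule_expr(format_rule(rule), ids) == rule


class TestProbabilities:
    @pytest.mark.parametrize("text,lo,hi", [
        ("5–9%", "0.05", "0.09"),
        ("5-9%", "0.05", "0.09"),
        ("5 to 9%", "0.05", "0.09"),
        ("7%", "0.07", "0.07"),
        ("0.5%", "0.005", "0.005"),
    ])
    def test_percent_parsing(self, text, lo, hi):
        assert parse_probability(text) == (Decimal(lo), Decimal(hi))

    def test_canonical_rendering_inverts_parsing(self):
        for text in ("5–9%", "7%", "12.5%"):
            assert parse_probability(format_probability(
                parse_probability(text))) == parse_probability(text)


class TestSpecRoundTrips:
    @pytest.mark.parametrize("fmt", ["csv", "tsv", "xlsx"])
    def test_meningitis_round_trip(self, tmp_path, meningitis_spec, fmt):
        target = tmp_path / ("spec.xlsx" if fmt == "xlsx" else "spec")
        write_spec(meningitis_spec, target, fmt)
        assert read_spec(target, fmt) == meningitis_spec

    def test_conditions_sheet_holds_source_expression(self, tmp_path,
                                                      meningitis_spec):
        write_spec(meningitis_spec, tmp_path / "spec", "csv")
        text = (tmp_path / "spec" / "CONDITIONS.csv").read_text()
        assert "Age_in_months IN [0, 5)" in text
        assert 'Vaccination_status == ""no""' in text  # RFC-4180 quoting

    def test_random_specs_round_trip(self, tmp_path):
        for seed in range(40):
            spec = random_spec(FixtureConfig(seed=seed,
                                             arithmetic_probability=0.2))
            assert validate_spec(spec) == []
            write_spec(spec, tmp_path / f"s{seed}", "csv")
            assert read_spec(tmp_path / f"s{seed}", "csv") == spec

    def test_second_write_is_byte_stable(self, tmp_path):
        spec = random_spec(FixtureConfig(seed=11))
        write_spec(spec, tmp_path / "a", "csv")
        write_spec(read_spec(tmp_path / "a"), tmp_path / "b", "csv")
        for name in ("PHASES", "KPIS", "CONDITIONS", "RISKS", "CONSTANTS"):
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == \
                (tmp_path / "b" / f"{name}.csv").read_bytes()

    def test_phases_and_kpis_alone_form_a_valid_spec(self, tmp_path,
                                                     meningitis_spec):
        write_spec(meningitis_spec, tmp_path / "full", "csv")
        (tmp_path / "part").mkdir()
        for name in ("PHASES", "KPIS"):
            (tmp_path / "part" / f"{name}.csv").write_bytes(
                (tmp_path / "full" / f"{name}.csv").read_bytes())
        spec = read_spec(tmp_path / "part", "csv")
        assert spec.risks == () and spec.conditions == ()
        assert spec.phases == meningitis_spec.phases

    def test_layout_error_names_sheet(self, tmp_path):
        (tmp_path / "bad").mkdir()
        (tmp_path / "bad" / "PHASES.csv").write_text("phase,rank\nindication,1\n")
        (tmp_path / "bad" / "KPIS.csv").write_text(
            "name,datatype,unit,phases,source\n")
        with pytest.raises(SpecLayoutError, match="PHASES"):
            read_spec(tmp_path / "bad", "csv")

    def test_validation_diagnostics_promoted_to_error(self, tmp_path,
                                                      meningitis_spec):
        write_spec(meningitis_spec, tmp_path / "spec", "csv")
        risks = tmp_path / "spec" / "RISKS.csv"
        text = risks.read_text()
        assert "c1 AND c4 AND c6" in text
        risks.write_text(text.replace("c1 AND c4 AND c6",
                                      "c1 AND c9 AND c6"))
        with pytest.raises(SpecLayoutError, match="c9"):
            read_spec(tmp_path / "spec", "csv")

    def test_revalidation_after_round_trip_is_identical(self, tmp_path):
        spec = random_spec(FixtureConfig(seed=3))
        write_spec(spec, tmp_path / "s", "csv")
        assert validate_spec(read_spec(tmp_path / "s")) == validate_spec(spec)
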