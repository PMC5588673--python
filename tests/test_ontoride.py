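"""Detection engine: DNF normalization, three-valued evaluation,
classification and explanation enumeration."""

from __future__ import annotations

import dataclasses
import itertools
import random
from decimal import Decimal

import pytest

from peririsk.fixtures import (
    FixtureConfig,
    label_record,
    oracle_evaluate,
    random_records,
    random_rule,
    random_spec,
)
from peririsk.ontoride import (
    DNFBlowupError,
    TruthValue,
    detect_risks,
    evaluate_condition,
    evaluate_conjunction,
    evaluate_rule,
    evaluate_rule_ast,
    phase_kpi_set,
    to_dnf,
)
from peririsk.risk_model import And, CondRef, KPIRecord, Not, Or
from peririsk.spec_io import parse_rule_expr

T, F, U = TruthValue.TRUE, TruthValue.FALSE, TruthValue.UNKNOWN


def _conj_ids(dnf):
    return [[(lit.condition_id, lit.positive) for lit in conj]
            for conj in dnf.conjunctions]


class TestToDNF:
    def test_single_distributivity_step(self):
        dnf = to_dnf(parse_rule_expr("(c1 OR c3) AND c6"))
        assert _conj_ids(dnf) == [[("c1", True), ("c6", True)],
                                  [("c3", True), ("c6", True)]]

    def test_de_morgan_pushes_not_to_leaves(self):
        dnf = to_dnf(parse_rule_expr("NOT (c1 OR c2)"))
        assert _conj_ids(dnf) == [[("c1", False), ("c2", False)]]

    def test_dnf_of_worked_example_preserves_conjunction_order(self):
        dnf = to_dnf(parse_rule_expr("(c1 AND c4 AND c6) OR (c3 AND c5 AND c6)"))
        assert _conj_ids(dnf) == [
            [("c1", True), ("c4", True), ("c6", True)],
            [("c3", True), ("c5", True), ("c6", True)]]

    def test_contradictions_and_duplicates_removed(self):
        dnf = to_dnf(parse_rule_expr("(c1 AND NOT c1) OR c2 OR c2"))
        assert _conj_ids(dnf) == [[("c2", True)]]

    def test_subsumed_conjunctions_pruned(self):
        dnf = to_dnf(parse_rule_expr("c1 OR (c1 AND c2)"))
        assert _conj_ids(dnf) == [[("c1", True)]]

    def test_blowup_guard_raises(self):
        # (a1 OR b1) AND ... AND (a12 OR b12) has 2^12 conjunctions
        clauses = " AND ".join(f"(a{i} OR b{i})" for i in range(12))
        rule = parse_rule_expr(clauses)
        with pytest.raises(DNFBlowupError):
            to_dnf(rule, max_literals=1000)

    @pytest.mark.parametrize("seed", range(4))
    def test_dnf_agrees_with_oracle_on_all_boolean_assignments(self, seed):
        rng = random.Random(seed)
        for _ in range(60):
            ids = [f"c{i}" for i in range(1, rng.randint(2, 9))]
            rule = random_rule(rng, ids, not_probability=0.3)
            dnf = to_dnf(rule)
            for vals in itertools.product([T, F], repeat=len(ids)):
                a = dict(zip(ids, vals))
                assert evaluate_rule(dnf, a) == oracle_evaluate(rule, a)

    def test_dnf_is_sound_refinement_on_three_valued_states(self):
        """On partial assignments the DNF may refine unknown to false —
        exactly when no completion can satisfy the rule — and otherwise
        agrees with direct Kleene evaluation."""
        rng = random.Random(99)
        for _ in range(80):
            ids = [f"c{i}" for i in range(1, rng.randint(2, 7))]
            rule = random_rule(rng, ids, not_probability=0.3)
            dnf = to_dnf(rule)
            for vals in itertools.product([T, F, U], repeat=len(ids)):
                a = dict(zip(ids, vals))
                d, o = evaluate_rule(dnf, a), oracle_evaluate(rule, a)
                assert d == o or (d is F and o is U)
                assert evaluate_rule_ast(rule, a) == o


class TestConditionEvaluation:
    def test_age_three_months_inside_interval(self, meningitis_spec,
                                              meningitis_records):
        cond = meningitis_spec.condition_map()["c1"]
        record = meningitis_records["positive"]
        assert evaluate_condition(cond, record, meningitis_spec) is T

    def test_age_five_months_outside_half_open_interval(self, meningitis_spec,
                                                        meningitis_records):
        cond = meningitis_spec.condition_map()["c1"]
        record = meningitis_records["boundary_age_5"]
        assert evaluate_condition(cond, record, meningitis_spec) is F

    def test_missing_kpi_evaluates_unknown(self, meningitis_spec,
                                           meningitis_records):
        cond = meningitis_spec.condition_map()["c1"]
        record = meningitis_records["missing_age"]
        assert evaluate_condition(cond, record, meningitis_spec) is U

    def test_type_mismatch_raises(self, meningitis_spec):
        cond = meningitis_spec.condition_map()["c1"]
        record = KPIRecord("s", "indication", "t",
                           values={"Age_in_months": "three"})
        with pytest.raises(TypeError, match="Age_in_months"):
            evaluate_condition(cond, record, meningitis_spec)

    def test_arithmetic_lhs_uses_exact_rational_arithmetic(self,
                                                           meningitis_spec):
        from peririsk.risk_model import Condition, ValueRange

        # (1/3) * 3 must compare exactly equal to 1
        cond = Condition("c9", "Weight_kg", "==",
                         ValueRange("literal", literal=Decimal(1)),
                         lhs_expression="(Weight_kg / 3) * 3")
        spec = dataclasses.replace(
            meningitis_spec, conditions=meningitis_spec.conditions + (cond,))
        record = KPIRecord("s", "indication", "t",
                           values={"Weight_kg": Decimal(1)})
        assert evaluate_condition(cond, record, spec) is T

    def test_constants_resolve_in_arithmetic(self, meningitis_spec):
        from peririsk.risk_model import Condition, ValueRange

        cond = Condition("c9", "Weight_kg", ">",
                         ValueRange("literal", literal=Decimal(10)),
                         lhs_expression="Weight_kg * growth_factor")
        spec = dataclasses.replace(
            meningitis_spec,
            conditions=meningitis_spec.conditions + (cond,),
            constants={"growth_factor": Decimal(2)})
        record = KPIRecord("s", "indication", "t",
                           values={"Weight_kg": Decimal(6)})
        assert evaluate_condition(cond, record, spec) is T


class TestConjunctionEvaluation:
    def test_false_dominates_unknown(self):
        from peririsk.ontoride import Literal as Lit

        conj = (Lit("c1"), Lit("c4"))
        assert evaluate_conjunction(conj, {"c1": F}) is F

    def test_negative_literal_of_unknown_stays_unknown(self):
        from peririsk.ontoride import Literal as Lit

        assert evaluate_conjunction((Lit("c1", positive=False),), {}) is U
        assert evaluate_conjunction((Lit("c1", positive=False),),
                                    {"c1": F}) is T

    def test_matches_brute_force_three_valued_evaluator(self):
        from peririsk.ontoride import Literal as Lit

        rng = random.Random(5)
        for _ in range(50):
            n = rng.randint(1, 6)
            conj = tuple(Lit(f"c{i}", rng.random() < 0.7) for i in range(n))
            ast = And(tuple(
                CondRef(l.condition_id) if l.positive
                else Not(CondRef(l.condition_id)) for l in conj)) \
                if n > 1 else (
                CondRef(conj[0].condition_id) if conj[0].positive
                else Not(CondRef(conj[0].condition_id)))
            for vals in itertools.product([T, F, U], repeat=n):
                a = dict(zip((l.condition_id for l in conj), vals))
                assert evaluate_conjunction(conj, a) == oracle_evaluate(ast, a)


class TestDetectRisks:
    def test_worked_example_positive_record_is_risk_situation(
            self, meningitis_spec, meningitis_records):
        report = detect_risks(meningitis_spec, meningitis_records["positive"])
        assert report.classification == "risk"
        assert [f.risk_name for f in report.findings] == ["Infection_Risk_001"]
        (explanation,) = report.findings[0].explanations
        assert len(explanation.literals) == 3
        assert explanation.sentence == (
            'Age_in_months IN [0, 5) and Vaccination_status == "no" '
            "and Antibiotic_prevention == false")

    def test_unsatisfying_record_is_non_risk(self, meningitis_spec,
                                             meningitis_records):
        report = detect_risks(meningitis_spec, meningitis_records["negative"])
        assert report.classification == "non-risk"
        assert report.findings == ()

    def test_boundary_age_five_is_non_risk(self, meningitis_spec,
                                           meningitis_records):
        report = detect_risks(meningitis_spec,
                              meningitis_records["boundary_age_5"])
        assert report.classification == "non-risk"

    def test_missing_kpi_yields_indeterminate_with_names(self, meningitis_spec,
                                                         meningitis_records):
        report = detect_risks(meningitis_spec,
                              meningitis_records["missing_age"])
        assert report.classification == "indeterminate"
        assert report.missing_kpis == ("Age_in_months",)

    def test_unknown_phase_filter_rejected(self, meningitis_spec,
                                           meningitis_records):
        with pytest.raises(ValueError, match="recovery"):
            detect_risks(meningitis_spec, meningitis_records["positive"],
                         phase_filter="recovery")

    def test_phase_filter_findings_are_subset_of_unfiltered(self):
        for seed in range(10):
            cfg = FixtureConfig(seed=seed, n_records=3, missing_rate=0.1)
            spec = random_spec(cfg)
            for lr in random_records(spec, cfg):
                all_names = {f.risk_name
                             for f in detect_risks(spec, lr.record).findings}
                for phase in spec.phases:
                    sub = {f.risk_name
                           for f in detect_risks(spec, lr.record,
                                                 phase_filter=phase).findings}
                    assert sub <= all_names

    def test_reports_are_deterministic(self, meningitis_spec,
                                       meningitis_records):
        from peririsk.report import dumps_report

        a = dumps_report(detect_risks(meningitis_spec,
                                      meningitis_records["positive"]))
        b = dumps_report(detect_risks(meningitis_spec,
                                      meningitis_records["positive"]))
        assert a == b

    def test_classification_trichotomy_and_completeness(self):
        for seed in range(15):
            cfg = FixtureConfig(seed=seed, n_records=4, missing_rate=0.0)
            spec = random_spec(cfg)
            for lr in random_records(spec, cfg):
                report = detect_risks(spec, lr.record)
                assert report.classification in ("risk", "non-risk")

    def test_findings_match_oracle_labels_end_to_end(self):
        for seed in range(25):
            cfg = FixtureConfig(seed=seed, n_records=4, missing_rate=0.2,
                                arithmetic_probability=0.15)
            spec = random_spec(cfg)
            for lr in random_records(spec, cfg):
                report = detect_risks(spec, lr.record)
                assert report.classification == lr.classification
                engine = {
                    f.risk_name: frozenset(
                        frozenset((cid, pos) for cid, _, _, _, pos in e.literals)
                        for e in f.explanations)
                    for f in report.findings}
                truth = {name: frozenset(conjs)
                         for name, conjs in lr.satisfied.items() if conjs}
                assert engine == truth


class TestPhaseKPISet:
    def test_worked_example_indication_phase(self, meningitis_spec):
        assert phase_kpi_set(meningitis_spec, "indication") == [
            "Age_in_months", "Bone_thickness_mm", "Vaccination_status",
            "Inner_ear_malformation", "Antibiotic_prevention"]

    def test_phase_without_relevant_risks_is_empty(self, meningitis_spec):
        assert phase_kpi_set(meningitis_spec, "postoperative") == []

    def test_every_returned_kpi_is_referenced_by_a_relevant_risk(self):
        from peririsk.risk_model import rule_condition_ids

        for seed in range(10):
            spec = random_spec(FixtureConfig(seed=seed))
            cond_map = spec.condition_map()
            for phase in spec.phases:
                referenced = set()
                for risk in spec.risks:
                    if phase in spec.phases_of(risk):
                        for cid in rule_condition_ids(risk.rule):
                            referenced.add(cond_map[cid].kpi)
                for kpi in phase_kpi_set(spec, phase):
                    assert kpi in referenced or any(
                        cond_map[cid].lhs_expression
                        and kpi in cond_map[cid].lhs_expression
                        for risk in spec.risks
                        if phase in spec.phases_of(risk)
                        for cid in rule_condition_ids(risk.rule))
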