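"""Risk detection engine.

For every risk the boolean rule is normalized to disjunctive normal form
(NOT pushed to the leaves by De Morgan, then AND distributed over OR); each
conjunction of the DNF is one possible explanation of the risk.  Conditions
are checked against the patient's KPI snapshot — membership of the current
value in the specified value range — under Kleene three-valued logic so
that a missing KPI yields *unknown* rather than silently false.  A
situation is classified ``risk`` when at least one rule is satisfied,
``non-risk`` when every rule is false, and ``indeterminate`` otherwise.

No description-logic reasoner is involved: rules with arithmetic
expressions and named constants are evaluated natively with exact
arithmetic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from peririsk.risk_model import (
    And,
    CondRef,
    Condition,
    KPIRecord,
    Not,
    Or,
    RiskSpecification,
    RuleExpression,
    ScalarValue,
    rule_condition_ids,
)
from peririsk.spec_io import _Cursor, _tokenize, format_condition
from peririsk.report import RiskFinding, RiskReport

__all__ = [
    "TruthValue",
    "Literal",
    "DNFRule",
    "Explanation",
    "DNFBlowupError",
    "to_dnf",
    "evaluate_condition",
    "evaluate_conjunction",
    "evaluate_rule",
    "evaluate_rule_ast",
    "detect_risks",
    "phase_kpi_set",
]


class TruthValue(enum.Enum):
    """Kleene three-valued truth; UNKNOWN arises only from missing KPIs."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    def negate(self) -> "TruthValue":
        if self is TruthValue.TRUE:
            return TruthValue.FALSE
        if self is TruthValue.FALSE:
            return TruthValue.TRUE
        return TruthValue.UNKNOWN


def kleene_and(values) -> TruthValue:
    result = TruthValue.TRUE
    for v in values:
        if v is TruthValue.FALSE:
            return TruthValue.FALSE
        if v is TruthValue.UNKNOWN:
            result = TruthValue.UNKNOWN
    return result


def kleene_or(values) -> TruthValue:
    result = TruthValue.FALSE
    for v in values:
        if v is TruthValue.TRUE:
            return TruthValue.TRUE
        if v is TruthValue.UNKNOWN:
            result = TruthValue.UNKNOWN
    return result


@dataclass(frozen=True)
class Literal:
    """A condition reference with polarity; ``positive=False`` means the
    negated condition."""

    condition_id: str
    positive: bool = True


Conjunction = tuple[Literal, ...]


@dataclass(frozen=True)
class DNFRule:
    """A rule in disjunctive normal form: an ordered list of conjunctions,
    logically equivalent to the source rule expression."""

    conjunctions: tuple[Conjunction, ...]


class DNFBlowupError(ValueError):
    """Raised when DNF expansion exceeds the configured literal bound —
    the signature of a pathological rule."""


@dataclass(frozen=True)
class Explanation:
    """One satisfied conjunction of a detected risk.

    ``literals`` holds, per conjunction member, the condition id, the KPI
    name, the patient's current value, the specified range (rendered), and
    the polarity; ``sentence`` is the human-readable conjunction, e.g.
    ``Age_in_months IN [0, 5) and Vaccination_status == "no" and
    Antibiotic_prevention == false``.
    """

    risk_name: str
    conjunction_index: int
    literals: tuple[tuple[str, str, Optional[str], str, bool], ...]
    sentence: str


# ---------------------------------------------------------------------------
# DNF transformation


def _to_nnf(node: RuleExpression, negated: bool = False) -> RuleExpression:
    """Negation normal form via De Morgan; NOT survives only on leaves."""
    if isinstance(node, CondRef):
        return Not(node) if negated else node
    if isinstance(node, Not):
        return _to_nnf(node.child, not negated)
    if isinstance(node, And):
        children = tuple(_to_nnf(c, negated) for c in node.children)
        return Or(children) if negated else And(children)
    if isinstance(node, Or):
        children = tuple(_to_nnf(c, negated) for c in node.children)
        return And(children) if negated else Or(children)
    raise TypeError(f"unknown rule node {type(node).__name__}")


def _merge(a: dict[str, bool], b: dict[str, bool]) -> Optional[dict[str, bool]]:
    """Merge two conjunctions (id -> polarity); None on contradiction."""
    out = dict(a)
    for cid, pol in b.items():
        if cid in out:
            if out[cid] != pol:
                return None
        else:
            out[cid] = pol
    return out


def to_dnf(rule: RuleExpression, *, max_literals: int = 10_000) -> DNFRule:
    """Transform a rule to DNF by De Morgan and distributivity.

    Contradictory conjunctions (c AND NOT c) are dropped, duplicates are
    removed, and subsumed conjunctions (supersets of another conjunction)
    are pruned so every remaining conjunction is a minimal explanation.
    Source order of conjunctions is preserved.  Expansion beyond
    ``max_literals`` raises :class:`DNFBlowupError`.
    """
    nnf = _to_nnf(rule)

    def expand(node: RuleExpression) -> list[dict[str, bool]]:
        if isinstance(node, CondRef):
            return [{node.id: True}]
        if isinstance(node, Not):
            assert isinstance(node.child, CondRef)
            return [{node.child.id: False}]
        if isinstance(node, Or):
            out: list[dict[str, bool]] = []
            for c in node.children:
                out.extend(expand(c))
            _guard(out)
            return out
        if isinstance(node, And):
            acc: list[dict[str, bool]] = [{}]
            for c in node.children:
                branch = expand(c)
                nxt: list[dict[str, bool]] = []
                for left in acc:
                    for right in branch:
                        merged = _merge(left, right)
                        if merged is not None:
                            nxt.append(merged)
                acc = nxt
                _guard(acc)
            return acc
        raise TypeError(f"unknown NNF node {type(node).__name__}")

    def _guard(conjs: list[dict[str, bool]]) -> None:
        if sum(len(c) for c in conjs) > max_literals:
            raise DNFBlowupError(
                f"DNF expansion exceeds {max_literals} literals")

    raw = expand(nnf)

    # dedupe (keep first occurrence), then prune subsumed conjunctions
    seen: set[frozenset] = set()
    unique: list[dict[str, bool]] = []
    for conj in raw:
        key = frozenset(conj.items())
        if key and key not in seen:
            seen.add(key)
            unique.append(conj)
    keys = [frozenset(c.items()) for c in unique]
    kept: list[dict[str, bool]] = []
    for i, conj in enumerate(unique):
        if any(j != i and keys[j] < keys[i] for j in range(len(unique))):
            continue  # a strictly smaller conjunction already implies this one
        kept.append(conj)

    conjunctions = tuple(
        tuple(Literal(cid, pol) for cid, pol in conj.items()) for conj in kept)
    return DNFRule(conjunctions=conjunctions)


# ---------------------------------------------------------------------------
# condition evaluation


class _MissingKPI(Exception):
    def __init__(self, names: list[str]):
        self.names = names


def _as_fraction(value) -> Fraction:
    if isinstance(value, Decimal):
        return Fraction(value)
    if isinstance(value, Fraction):
        return value
    raise TypeError(f"not a number: {value!r}")


def _eval_arithmetic(expr: str, values: Mapping[str, ScalarValue],
                     constants: Mapping[str, ScalarValue]) -> Fraction:
    """Evaluate an arithmetic left-hand side with exact rational
    arithmetic; raises :class:`_MissingKPI` for absent KPIs."""
    cur = _Cursor(_tokenize(expr), expr)

    def primary() -> Fraction:
        tok = cur.cur
        if tok.kind == "number":
            cur.advance()
            return Fraction(Decimal(tok.value))
        if tok.kind == "name":
            cur.advance()
            if tok.value in values:
                return _as_fraction(values[tok.value])
            if tok.value in constants:
                return _as_fraction(constants[tok.value])
            raise _MissingKPI([tok.value])
        if tok.kind == "punct" and tok.value == "(":
            cur.advance()
            v = add_expr()
            cur.expect("punct", ")")
            return v
        raise cur.fail("expected a number, name, or '('")

    def factor() -> Fraction:
        if cur.cur.kind == "punct" and cur.cur.value == "-":
            cur.advance()
            return -factor()
        return primary()

    def mul_expr() -> Fraction:
        v = factor()
        while cur.cur.kind == "punct" and cur.cur.value in "*/":
            op = cur.advance().value
            rhs = factor()
            v = v * rhs if op == "*" else v / rhs
        return v

    def add_expr() -> Fraction:
        v = mul_expr()
        while cur.cur.kind == "punct" and cur.cur.value in "+-":
            op = cur.advance().value
            rhs = mul_expr()
            v = v + rhs if op == "+" else v - rhs
        return v

    result = add_expr()
    if cur.cur.kind != "eof":
        raise cur.fail("trailing input after expression")
    return result


def _check_value_type(cond: Condition, value: ScalarValue,
                      datatype: str) -> None:
    ok = {
        "boolean": lambda v: isinstance(v, bool),
        "number": lambda v: isinstance(v, Decimal) and not isinstance(v, bool),
        "date": lambda v: hasattr(v, "isoformat") and not hasattr(v, "hour"),
        "text": lambda v: isinstance(v, str),
    }[datatype]
    if not ok(value):
        raise TypeError(
            f"condition {cond.id}: KPI {cond.kpi!r} value {value!r} "
            f"does not match datatype {datatype!r}")


def evaluate_condition(cond: Condition, record: KPIRecord,
                       spec: RiskSpecification) -> TruthValue:
    """Three-valued check whether the current KPI value (or computed
    left-hand side) lies in the condition's value range."""
    constants = spec.constants
    if cond.lhs_expression is not None:
        try:
            value: ScalarValue = _eval_arithmetic(
                cond.lhs_expression, record.values, constants)
        except _MissingKPI:
            return TruthValue.UNKNOWN
    else:
        if cond.kpi not in record.values:
            if cond.kpi in constants:
                value = constants[cond.kpi]
            else:
                return TruthValue.UNKNOWN
        else:
            value = record.values[cond.kpi]
        datatype = spec.kpi_map()[cond.kpi].datatype if cond.kpi in spec.kpi_map() \
            else None
        if datatype is not None:
            _check_value_type(cond, value, datatype)

    if isinstance(value, str):
        value = value.strip()

    op = cond.operator
    rng = cond.range
    if op == "IN":
        hit = rng.contains(value)
    elif op == "==":
        hit = value == rng.literal
    elif op == "!=":
        hit = value != rng.literal
    elif op == "<":
        hit = value < rng.literal
    elif op == "<=":
        hit = value <= rng.literal
    elif op == ">":
        hit = value > rng.literal
    elif op == ">=":
        hit = value >= rng.literal
    else:  # pragma: no cover - guarded by validate_spec
        raise ValueError(f"unknown operator {op!r}")
    return TruthValue.TRUE if hit else TruthValue.FALSE


def evaluate_conjunction(conjunction: Conjunction,
                         assignment: Mapping[str, TruthValue]) -> TruthValue:
    """Kleene conjunction over literals: false dominates unknown dominates
    true; a negative literal negates the three-valued condition result."""
    def lit_value(lit: Literal) -> TruthValue:
        v = assignment.get(lit.condition_id, TruthValue.UNKNOWN)
        return v if lit.positive else v.negate()

    return kleene_and(lit_value(lit) for lit in conjunction)


def evaluate_rule(dnf: DNFRule,
                  assignment: Mapping[str, TruthValue]) -> TruthValue:
    """Three-valued evaluation of a normalized rule.

    Because contradictory conjunctions are removed during normalization,
    this is a *refinement* of Kleene evaluation of the source rule: it may
    return false where the source evaluates unknown, exactly when the only
    unknown conjunctions can never become true under any completion of the
    missing KPIs.  It never disagrees on true, and agrees everywhere on
    complete (two-valued) assignments.
    """
    return kleene_or(
        evaluate_conjunction(c, assignment) for c in dnf.conjunctions)


def evaluate_rule_ast(rule: RuleExpression,
                      assignment: Mapping[str, TruthValue]) -> TruthValue:
    """Kleene evaluation of the source rule by structural recursion; the
    engine classifies situations with this, so missing data propagates as
    unknown exactly as written."""
    if isinstance(rule, CondRef):
        return assignment.get(rule.id, TruthValue.UNKNOWN)
    if isinstance(rule, Not):
        return evaluate_rule_ast(rule.child, assignment).negate()
    if isinstance(rule, And):
        return kleene_and(evaluate_rule_ast(c, assignment)
                          for c in rule.children)
    if isinstance(rule, Or):
        return kleene_or(evaluate_rule_ast(c, assignment)
                         for c in rule.children)
    raise TypeError(f"unknown rule node {type(rule).__name__}")


# ---------------------------------------------------------------------------
# detection


def _literal_sentence(cond: Condition, positive: bool) -> str:
    body = format_condition(cond, with_id=False)
    return body if positive else f"NOT ({body})"


def _record_value_str(record: KPIRecord, kpi: str) -> Optional[str]:
    from peririsk.spec_io import format_value

    if kpi in record.values:
        return format_value(record.values[kpi])
    return None


def phase_kpi_set(spec: RiskSpecification, phase: str) -> list[str]:
    """KPIs needed in a phase: the union of KPIs referenced by all risks
    relevant in that phase (cross-process risks included), deduplicated in
    specification order."""
    if phase not in spec.phases:
        raise ValueError(f"undeclared phase {phase!r}")
    cond_map = spec.condition_map()
    kpi_names = {k.name for k in spec.kpis}
    referenced: set[str] = set()
    for risk in spec.risks:
        if phase not in spec.phases_of(risk):
            continue
        for cid in rule_condition_ids(risk.rule):
            cond = cond_map[cid]
            if cond.lhs_expression is not None:
                import re as _re

                for name in _re.findall(r"[A-Za-z_][A-Za-z0-9_]*",
                                        cond.lhs_expression):
                    if name in kpi_names:
                        referenced.add(name)
            else:
                referenced.add(cond.kpi)
    return [k.name for k in spec.kpis if k.name in referenced]


def _condition_kpis(cond: Condition, kpi_names: set[str]) -> list[str]:
    if cond.lhs_expression is not None:
        import re as _re

        return [n for n in _re.findall(r"[A-Za-z_][A-Za-z0-9_]*",
                                       cond.lhs_expression) if n in kpi_names]
    return [cond.kpi] if cond.kpi in kpi_names else []


def detect_risks(spec: RiskSpecification, record: KPIRecord,
                 phase_filter: Optional[str] = None, *,
                 max_literals: int = 10_000) -> RiskReport:
    """Evaluate every relevant risk rule against a patient KPI snapshot.

    Each risk's rule is brought to DNF and all conjunctions are evaluated;
    every satisfied conjunction becomes one :class:`Explanation`.  The
    situation is classified ``risk`` if at least one risk is recognized,
    ``non-risk`` if every rule is false, and ``indeterminate`` if no rule
    is true but at least one is unknown (the missing KPIs are listed).

    ``phase_filter`` restricts evaluation to risks relevant in that phase;
    cross-process risks are always included.
    """
    from peririsk.report import order_findings

    if phase_filter is not None and phase_filter not in spec.phases:
        raise ValueError(f"undeclared phase {phase_filter!r}")

    cond_map = spec.condition_map()
    kpi_names = {k.name for k in spec.kpis}
    assignment: dict[str, TruthValue] = {}

    findings: list[RiskFinding] = []
    any_unknown = False
    missing: list[str] = []

    for risk in spec.risks:
        if phase_filter is not None and phase_filter not in spec.phases_of(risk):
            continue
        dnf = to_dnf(risk.rule, max_literals=max_literals)
        for cid in rule_condition_ids(risk.rule):
            if cid not in assignment:
                assignment[cid] = evaluate_condition(
                    cond_map[cid], record, spec)
        conj_values = [evaluate_conjunction(c, assignment)
                       for c in dnf.conjunctions]
        # classify from the source rule (pure Kleene); the DNF drives the
        # explanations — pruning never changes which conjunctions are true
        risk_truth = evaluate_rule_ast(risk.rule, assignment)
        if risk_truth is TruthValue.TRUE:
            explanations = []
            for idx, (conj, value) in enumerate(zip(dnf.conjunctions,
                                                    conj_values)):
                if value is not TruthValue.TRUE:
                    continue
                lits = tuple(
                    (lit.condition_id,
                     cond_map[lit.condition_id].kpi,
                     _record_value_str(record, cond_map[lit.condition_id].kpi),
                     format_condition(cond_map[lit.condition_id], with_id=False),
                     lit.positive)
                    for lit in conj)
                sentence = " and ".join(
                    _literal_sentence(cond_map[lit.condition_id], lit.positive)
                    for lit in conj)
                explanations.append(Explanation(
                    risk_name=risk.name, conjunction_index=idx,
                    literals=lits, sentence=sentence))
            findings.append(RiskFinding(
                risk_name=risk.name,
                category=risk.category,
                explanations=tuple(explanations),
                adverse_links=risk.adverse_links,
                relevant_phases=spec.phases_of(risk),
            ))
        elif risk_truth is TruthValue.UNKNOWN:
            any_unknown = True
            for cid in rule_condition_ids(risk.rule):
                if assignment[cid] is TruthValue.UNKNOWN:
                    for name in _condition_kpis(cond_map[cid], kpi_names):
                        if name not in record.values and name not in missing:
                            missing.append(name)

    if findings:
        classification = "risk"
    elif any_unknown:
        classification = "indeterminate"
    else:
        classification = "non-risk"

    missing_ordered = tuple(
        k.name for k in spec.kpis if k.name in set(missing))
    return RiskReport(
        subject_id=record.subject_id,
        timestamp=record.timestamp,
        phase=record.phase,
        classification=classification,
        findings=tuple(order_findings(findings, spec.severity_scale)),
        kpi_values={k: v for k, v in record.values.items()},
        missing_kpis=missing_ordered if classification == "indeterminate" else (),
    )
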