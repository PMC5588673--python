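"""Synthetic specifications, patient records with ground truth, and the
brute-force evaluation oracle.

The hand-built meningitis example models the risk of bacterial dura mater
infection during cochlear implantation in infants: young age (bone
thickness of the skull below ~2 mm under 5 months of age), absent
pneumococcus/meningococcus/haemophilus vaccination, and absent antibiotic
prevention jointly raise the meningitis risk, whose occurrence probability
is 5–9%.  Conditions c1 (``Age_in_months IN [0, 5)``), c4
(``Vaccination_status == "no"``) and c6 (``Antibiotic_prevention ==
false``) follow the published example; c2, c3 and c5 are plausible
reconstructions and are flagged as such in :data:`MENINGITIS_RECONSTRUCTED`.

The random generators are fully seeded: identical configurations reproduce
identical specifications and records.  Ground-truth labels are computed by
an oracle that deliberately shares no code with the detection engine —
direct three-valued recursion over the rule AST and a naive set-product
DNF — so agreement between engine and oracle is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from datetime import date, timedelta
from decimal import Decimal
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from peririsk.ontoride import TruthValue
from peririsk.risk_model import (
    DEFAULT_SEVERITY_SCALE,
    AdverseSituationLink,
    And,
    CondRef,
    Condition,
    KPIDefinition,
    KPIRecord,
    Not,
    Or,
    RiskDefinition,
    RiskSpecification,
    RuleExpression,
    ScalarValue,
    ValueRange,
)

__all__ = [
    "FixtureConfig",
    "LabeledRecord",
    "MENINGITIS_RECONSTRUCTED",
    "make_meningitis_fixture",
    "random_spec",
    "random_records",
    "random_rule",
    "oracle_evaluate",
    "naive_dnf",
    "oracle_condition_truth",
    "print_rule",
]


# ---------------------------------------------------------------------------
# the worked meningitis example

#: Condition ids whose content is reconstructed rather than published.
MENINGITIS_RECONSTRUCTED = frozenset({"c2", "c3", "c5"})


def make_meningitis_fixture() -> tuple[RiskSpecification, list[KPIRecord]]:
    """The cochlear-implantation infection example with four treatment
    phases, six conditions, and records covering the positive, negative,
    boundary (age exactly 5 months) and missing-KPI cases."""
    phases = ("indication", "preoperative", "intraoperative", "postoperative")
    kpis = (
        KPIDefinition("Age_in_months", "number", unit="months",
                      measurement_phases=("indication",),
                      acquisition_source="patient record"),
        KPIDefinition("Weight_kg", "number", unit="kg",
                      measurement_phases=("indication", "preoperative"),
                      acquisition_source="patient record"),
        KPIDefinition("Bone_thickness_mm", "number", unit="mm",
                      measurement_phases=("indication",),
                      acquisition_source="imaging report"),
        KPIDefinition("Vaccination_status", "text",
                      measurement_phases=("indication",),
                      acquisition_source="patient record"),
        KPIDefinition("Inner_ear_malformation", "boolean",
                      measurement_phases=("indication",),
                      acquisition_source="imaging report"),
        KPIDefinition("Antibiotic_prevention", "boolean",
                      measurement_phases=("preoperative",),
                      acquisition_source="checklist"),
    )
    d = Decimal
    conditions = (
        Condition("c1", "Age_in_months", "IN",
                  ValueRange("interval", lower=d(0), upper=d(5),
                             lower_closed=True, upper_closed=False)),
        Condition("c2", "Weight_kg", "IN",
                  ValueRange("interval", lower=d(0), upper=d(6),
                             lower_closed=True, upper_closed=False)),
        Condition("c3", "Bone_thickness_mm", "<",
                  ValueRange("literal", literal=d(2))),
        Condition("c4", "Vaccination_status", "==",
                  ValueRange("literal", literal="no")),
        Condition("c5", "Inner_ear_malformation", "==",
                  ValueRange("literal", literal=True)),
        Condition("c6", "Antibiotic_prevention", "==",
                  ValueRange("literal", literal=False)),
    )
    rule = Or((
        And((CondRef("c1"), CondRef("c4"), CondRef("c6"))),
        And((CondRef("c3"), CondRef("c5"), CondRef("c6"))),
    ))
    risks = (
        RiskDefinition(
            name="Infection_Risk_001",
            category="medical",
            rule=rule,
            relevant_phases=("indication", "preoperative"),
            adverse_links=(AdverseSituationLink(
                adverse_situation="Meningitis",
                probability=(Decimal("0.05"), Decimal("0.09")),
                severity="major"),),
        ),
    )
    spec = RiskSpecification(phases=phases, kpis=kpis, conditions=conditions,
                             risks=risks)

    def record(subject: str, **values: ScalarValue) -> KPIRecord:
        return KPIRecord(subject_id=subject, phase="indication",
                         timestamp="2016-03-01T09:00:00", values=values)

    records = [
        # age 3 months, unvaccinated, no antibiotic prevention -> risk
        record("positive", Age_in_months=d(3), Weight_kg=d(7),
               Bone_thickness_mm=d("2.5"), Vaccination_status="no",
               Inner_ear_malformation=False, Antibiotic_prevention=False),
        # vaccinated, antibiotic prevention given -> non-risk
        record("negative", Age_in_months=d(9), Weight_kg=d(8),
               Bone_thickness_mm=d("2.5"), Vaccination_status="yes",
               Inner_ear_malformation=False, Antibiotic_prevention=True),
        # age exactly 5 months: outside the half-open interval [0, 5)
        record("boundary_age_5", Age_in_months=d(5), Weight_kg=d(7),
               Bone_thickness_mm=d("2.5"), Vaccination_status="no",
               Inner_ear_malformation=False, Antibiotic_prevention=True),
        # age unrecorded while the first conjunction is otherwise satisfied
        record("missing_age", Weight_kg=d(7),
               Bone_thickness_mm=d("2.5"), Vaccination_status="no",
               Inner_ear_malformation=False, Antibiotic_prevention=False),
    ]
    return spec, records


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic generators; identical configurations
    (including the seed) reproduce identical outputs."""

    seed: int = 0
    n_phases: int = 4
    n_kpis: int = 8
    datatype_mix: Mapping[str, float] = field(default_factory=lambda: {
        "number": 0.5, "text": 0.2, "boolean": 0.2, "date": 0.1})
    n_conditions: int = 10
    n_risks: int = 4
    max_rule_depth: int = 3
    max_fanout: int = 3
    not_probability: float = 0.2
    arithmetic_probability: float = 0.1
    missing_rate: float = 0.0
    n_records: int = 10


# ---------------------------------------------------------------------------
# random specifications


def _random_decimal(rng: random.Random, lo: int = -20, hi: int = 100) -> Decimal:
    whole = rng.randint(lo, hi)
    if rng.random() < 0.5:
        return Decimal(whole)
    return Decimal(f"{whole}.{rng.randint(0, 99):02d}")


def _random_date(rng: random.Random) -> date:
    return date(2015, 1, 1) + timedelta(days=rng.randint(0, 1500))


def _random_interval(rng: random.Random, sample) -> ValueRange:
    a, b = sample(), sample()
    while b == a:
        b = sample()
    lo, hi = (a, b) if a < b else (b, a)
    lower_closed = rng.random() < 0.7
    upper_closed = rng.random() < 0.3
    r = rng.random()
    if r < 0.1:
        return ValueRange("interval", lower=None, upper=hi,
                          lower_closed=True, upper_closed=upper_closed)
    if r < 0.2:
        return ValueRange("interval", lower=lo, upper=None,
                          lower_closed=lower_closed, upper_closed=False)
    return ValueRange("interval", lower=lo, upper=hi,
                      lower_closed=lower_closed, upper_closed=upper_closed)


_TEXT_VALUES = ("no", "yes", "unknown", "pending", "abnormal", "normal")


def _random_condition(rng: random.Random, cid: str, kpi: KPIDefinition,
                      number_kpis: Sequence[str],
                      constants: Mapping[str, ScalarValue],
                      arithmetic_probability: float) -> Condition:
    dt = kpi.datatype
    if dt == "number":
        if (arithmetic_probability and len(number_kpis) >= 2
                and rng.random() < arithmetic_probability):
            a, b = rng.sample(list(number_kpis), 2)
            const = rng.choice(sorted(constants) or [None]) \
                if constants and rng.random() < 0.5 else None
            pattern = rng.choice(
                [f"{a} + {b}", f"{a} - {b}", f"({a} + {b}) / 2"]
                + ([f"{a} * {const}"] if const else []))
            op = rng.choice(("<", "<=", ">", ">=", "IN"))
            if op == "IN":
                return Condition(cid, a, "IN",
                                 _random_interval(rng, lambda: _random_decimal(rng)),
                                 lhs_expression=pattern)
            return Condition(cid, a, op,
                             ValueRange("literal", literal=_random_decimal(rng)),
                             lhs_expression=pattern)
        op = rng.choice(("IN", "IN", "==", "!=", "<", "<=", ">", ">="))
        if op == "IN":
            if rng.random() < 0.15:
                members = sorted({_random_decimal(rng) for _ in range(
                    rng.randint(1, 3))})
                return Condition(cid, kpi.name, "IN",
                                 ValueRange("set", members=tuple(members)))
            return Condition(cid, kpi.name, "IN",
                             _random_interval(rng, lambda: _random_decimal(rng)))
        return Condition(cid, kpi.name, op,
                         ValueRange("literal", literal=_random_decimal(rng)))
    if dt == "date":
        op = rng.choice(("IN", "<", "<=", ">", ">=", "=="))
        if op == "IN":
            return Condition(cid, kpi.name, "IN",
                             _random_interval(rng, lambda: _random_date(rng)))
        return Condition(cid, kpi.name, op,
                         ValueRange("literal", literal=_random_date(rng)))
    if dt == "boolean":
        return Condition(cid, kpi.name, rng.choice(("==", "!=")),
                         ValueRange("literal", literal=rng.random() < 0.5))
    op = rng.choice(("==", "==", "!=", "IN"))
    if op == "IN":
        members = rng.sample(_TEXT_VALUES, rng.randint(1, 3))
        return Condition(cid, kpi.name, "IN", ValueRange("set", members=tuple(members)))
    return Condition(cid, kpi.name, op,
                     ValueRange("literal", literal=rng.choice(_TEXT_VALUES)))


def random_rule(rng: random.Random, condition_ids: Sequence[str],
                max_depth: int = 3, max_fanout: int = 3,
                not_probability: float = 0.2) -> RuleExpression:
    """A random rule AST in canonical form: AND/OR n-ary, never directly
    nested under a node of the same kind (the parser's flattened shape)."""

    def build(depth: int, parent: Optional[type]) -> RuleExpression:
        if depth >= max_depth or rng.random() < 0.35:
            leaf: RuleExpression = CondRef(rng.choice(condition_ids))
            if rng.random() < not_probability:
                leaf = Not(leaf)
            return leaf
        kinds = [k for k in (And, Or) if k is not parent]
        kind = rng.choice(kinds)
        n = rng.randint(2, max_fanout)
        children = tuple(build(depth + 1, kind) for _ in range(n))
        node: RuleExpression = kind(children)
        if rng.random() < not_probability * 0.5:
            node = Not(node)
        return node

    node = build(0, None)
    if isinstance(node, (CondRef, Not)) and rng.random() < 0.5:
        return node
    return node


def random_spec(config: FixtureConfig) -> RiskSpecification:
    """A seeded, reproducible random specification satisfying every model
    invariant by construction."""
    rng = random.Random(config.seed)
    phases = tuple(f"phase_{i}" for i in range(1, config.n_phases + 1))

    datatypes = sorted(config.datatype_mix)
    weights = [config.datatype_mix[d] for d in datatypes]
    kpis = []
    for i in range(1, config.n_kpis + 1):
        dt = rng.choices(datatypes, weights=weights)[0]
        n_phases = rng.randint(0, min(2, len(phases)))
        chosen_phases = set(rng.sample(phases, n_phases))
        measured = tuple(p for p in phases if p in chosen_phases)
        kpis.append(KPIDefinition(
            name=f"kpi_{i}", datatype=dt,
            unit="mm" if dt == "number" and rng.random() < 0.5 else "",
            measurement_phases=measured,
            acquisition_source=rng.choice(
                ("patient record", "checklist", "sensor", ""))))

    constants: dict[str, ScalarValue] = {}
    for i in range(rng.randint(0, 2)):
        constants[f"const_{i + 1}"] = _random_decimal(rng, 1, 9)

    number_kpis = [k.name for k in kpis if k.datatype == "number"]
    conditions = tuple(
        _random_condition(rng, f"c{i}", rng.choice(kpis), number_kpis,
                          constants, config.arithmetic_probability)
        for i in range(1, config.n_conditions + 1))
    cond_ids = [c.id for c in conditions]

    risks = []
    for i in range(1, config.n_risks + 1):
        category = rng.choice(("medical", "medical", "organizational",
                               "technical", "human", "cross-process"))
        if category == "cross-process":
            relevant: tuple[str, ...] = ()
        else:
            n = rng.randint(1, len(phases))
            chosen = set(rng.sample(phases, n))
            relevant = tuple(p for p in phases if p in chosen)
        links = tuple(
            AdverseSituationLink(
                adverse_situation=f"Adverse_situation_{rng.randint(1, 6)}_{i}_{j}",
                probability=_random_probability(rng),
                severity=rng.choice(DEFAULT_SEVERITY_SCALE))
            for j in range(rng.randint(1, 2)))
        risks.append(RiskDefinition(
            name=f"Risk_{i:03d}", category=category,
            rule=random_rule(rng, cond_ids, config.max_rule_depth,
                             config.max_fanout, config.not_probability),
            relevant_phases=relevant, adverse_links=links))

    return RiskSpecification(phases=phases, kpis=tuple(kpis),
                             conditions=conditions, risks=tuple(risks),
                             constants=constants)


def _random_probability(rng: random.Random) -> tuple[Decimal, Decimal]:
    lo = Decimal(rng.randint(0, 80)) / 100
    if rng.random() < 0.3:
        return lo, lo
    hi = lo + Decimal(rng.randint(1, 19)) / 100
    return lo, hi


# ---------------------------------------------------------------------------
# random records with ground truth


@dataclass(frozen=True)
class LabeledRecord:
    """A record plus its oracle-computed ground truth: per risk the set of
    satisfied DNF conjunctions (frozensets of (condition id, polarity)),
    and the overall classification."""

    record: KPIRecord
    satisfied: Mapping[str, frozenset]
    rule_truth: Mapping[str, TruthValue]
    classification: str


def _interesting_values(spec: RiskSpecification, kpi: KPIDefinition,
                        rng: random.Random) -> list[ScalarValue]:
    values: list[ScalarValue] = []
    for cond in spec.conditions:
        if cond.kpi != kpi.name or cond.lhs_expression is not None:
            continue
        r = cond.range
        if r.kind == "interval":
            for bound in (r.lower, r.upper):
                if bound is not None:
                    values.append(bound)
                    if isinstance(bound, Decimal):
                        values.extend((bound - 1, bound + 1))
                    else:
                        values.extend((bound - timedelta(days=30),
                                       bound + timedelta(days=30)))
        elif r.kind == "set":
            values.extend(r.members)
        elif r.literal is not None and not isinstance(r.literal, bool):
            values.append(r.literal)
            if isinstance(r.literal, Decimal):
                values.extend((r.literal - 1, r.literal + 1))
    if kpi.datatype == "number":
        values.append(_random_decimal(rng))
    elif kpi.datatype == "date":
        values.append(_random_date(rng))
    elif kpi.datatype == "boolean":
        values.extend((True, False))
    else:
        values.append(rng.choice(_TEXT_VALUES))
    return values


def random_records(spec: RiskSpecification, config: FixtureConfig
                   ) -> list[LabeledRecord]:
    """Seeded records over a specification, each labelled with its exact
    ground truth; missing values are injected at ``config.missing_rate``
    and the labels reflect three-valued truth."""
    rng = random.Random(config.seed + 1)
    out = []
    for i in range(config.n_records):
        values: dict[str, ScalarValue] = {}
        for kpi in spec.kpis:
            if rng.random() < config.missing_rate:
                continue
            values[kpi.name] = rng.choice(_interesting_values(spec, kpi, rng))
        record = KPIRecord(
            subject_id=f"subject_{i:03d}",
            phase=rng.choice(spec.phases) if spec.phases else "",
            timestamp=f"2016-01-{(i % 28) + 1:02d}T08:00:00",
            values=values)
        out.append(label_record(spec, record))
    return out


def label_record(spec: RiskSpecification, record: KPIRecord) -> LabeledRecord:
    """Ground truth for one record, computed entirely by the oracle path."""
    assignment = {c.id: oracle_condition_truth(c, record, spec)
                  for c in spec.conditions}
    satisfied: dict[str, frozenset] = {}
    rule_truth: dict[str, TruthValue] = {}
    for risk in spec.risks:
        truth = oracle_evaluate(risk.rule, assignment)
        rule_truth[risk.name] = truth
        conj_hits = []
        for conj in naive_dnf(risk.rule):
            values = [assignment.get(cid, TruthValue.UNKNOWN)
                      if positive else
                      assignment.get(cid, TruthValue.UNKNOWN).negate()
                      for cid, positive in conj]
            if all(v is TruthValue.TRUE for v in values):
                conj_hits.append(conj)
        satisfied[risk.name] = frozenset(conj_hits)
    if any(t is TruthValue.TRUE for t in rule_truth.values()):
        classification = "risk"
    elif any(t is TruthValue.UNKNOWN for t in rule_truth.values()):
        classification = "indeterminate"
    else:
        classification = "non-risk"
    return LabeledRecord(record=record, satisfied=satisfied,
                         rule_truth=rule_truth, classification=classification)


# ---------------------------------------------------------------------------
# the oracle (independent of the detection engine)

_RANK = {TruthValue.FALSE: 0, TruthValue.UNKNOWN: 1, TruthValue.TRUE: 2}
_BY_RANK = {v: k for k, v in _RANK.items()}


def oracle_evaluate(rule: RuleExpression,
                    assignment: Mapping[str, TruthValue]) -> TruthValue:
    """Direct recursive three-valued evaluation of a rule AST — no
    normalization.  Kleene logic via the rank ordering
    false < unknown < true: AND is min, OR is max, NOT is rank reversal."""
    if isinstance(rule, CondRef):
        return assignment.get(rule.id, TruthValue.UNKNOWN)
    if isinstance(rule, Not):
        return _BY_RANK[2 - _RANK[oracle_evaluate(rule.child, assignment)]]
    if isinstance(rule, And):
        return _BY_RANK[min(_RANK[oracle_evaluate(c, assignment)]
                            for c in rule.children)]
    if isinstance(rule, Or):
        return _BY_RANK[max(_RANK[oracle_evaluate(c, assignment)]
                            for c in rule.children)]
    raise TypeError(f"unknown rule node {type(rule).__name__}")


def naive_dnf(rule: RuleExpression) -> list[frozenset]:
    """Reference DNF by plain set products: conjunctions as frozensets of
    (condition id, polarity); contradictions dropped, duplicates and
    supersets of other conjunctions pruned; source order preserved."""

    def expand(node: RuleExpression, negated: bool) -> list[frozenset]:
        if isinstance(node, CondRef):
            return [frozenset({(node.id, not negated)})]
        if isinstance(node, Not):
            return expand(node.child, not negated)
        branches = [expand(c, negated) for c in node.children]
        is_product = isinstance(node, And) != negated  # De Morgan
        if not is_product:
            return [c for b in branches for c in b]
        out = []
        for combo in itertools.product(*branches):
            merged = frozenset().union(*combo)
            ids = [cid for cid, _ in merged]
            if len(ids) == len(set(ids)):  # no contradiction
                out.append(merged)
        return out

    raw = expand(rule, False)
    unique = list(dict.fromkeys(raw))
    return [c for c in unique
            if not any(o < c for o in unique if o != c)]


def oracle_condition_truth(cond: Condition, record: KPIRecord,
                           spec: RiskSpecification) -> TruthValue:
    """Independent condition check used for ground-truth labels: plain
    Python comparisons, with arithmetic left-hand sides evaluated by
    substituting exact rationals into the expression."""
    if cond.lhs_expression is not None:
        env: dict[str, Fraction] = {}
        import re

        for name in set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*",
                                   cond.lhs_expression)):
            if name in record.values:
                env[name] = Fraction(record.values[name])
            elif name in spec.constants:
                env[name] = Fraction(spec.constants[name])
            else:
                return TruthValue.UNKNOWN
        value: ScalarValue = eval(  # noqa: S307 - sanitized grammar
            compile(cond.lhs_expression, "<lhs>", "eval"),
            {"__builtins__": {}}, {**env, "Fraction": Fraction})
    elif cond.kpi in record.values:
        value = record.values[cond.kpi]
    elif cond.kpi in spec.constants:
        value = spec.constants[cond.kpi]
    else:
        return TruthValue.UNKNOWN

    if isinstance(value, str):
        value = value.strip()
    r = cond.range
    op = cond.operator
    if op == "IN":
        if r.kind == "set":
            hit = value in r.members
        else:
            above = r.lower is None or (
                value >= r.lower if r.lower_closed else value > r.lower)
            below = r.upper is None or (
                value <= r.upper if r.upper_closed else value < r.upper)
            hit = above and below
    elif op == "==":
        hit = value == r.literal
    elif op == "!=":
        hit = value != r.literal
    else:
        hit = {"<": value < r.literal, "<=": value <= r.literal,
               ">": value > r.literal, ">=": value >= r.literal}[op]
    return TruthValue.TRUE if hit else TruthValue.FALSE


# ---------------------------------------------------------------------------
# independent expression printer (for grammar-totality checks)


def print_rule(rule: RuleExpression) -> str:
    """Fully parenthesized rendering of a rule — an independent printer
    whose output must parse back to the identical AST."""
    if isinstance(rule, CondRef):
        return rule.id
    if isinstance(rule, Not):
        return f"NOT ({print_rule(rule.child)})" \
            if not isinstance(rule.child, CondRef) else f"NOT {rule.child.id}"
    joiner = " AND " if isinstance(rule, And) else " OR "
    return "(" + joiner.join(print_rule(c) for c in rule.children) + ")"
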