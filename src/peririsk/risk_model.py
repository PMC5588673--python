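"""Domain model for perioperative risk specifications.

The model renders the ontological risk vocabulary as concrete data: a risk
is a composite property made of single condition properties over KPIs; a
situation possessing at least one risk is a risk situation.  A patient
snapshot at a point in time of risk detection (a *potential risk situation*)
is a :class:`KPIRecord`; the adverse situation a risk may lead to, with its
occurrence probability and severity, is an :class:`AdverseSituationLink`.

All value types are exact: numbers are :class:`decimal.Decimal`, dates are
:class:`datetime.date`, text is compared case-sensitively after whitespace
trim, booleans are Python booleans.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date
from decimal import Decimal
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "DATATYPES",
    "CATEGORIES",
    "DEFAULT_SEVERITY_SCALE",
    "Diagnostic",
    "ValueRange",
    "Condition",
    "RuleExpression",
    "CondRef",
    "Not",
    "And",
    "Or",
    "AdverseSituationLink",
    "KPIDefinition",
    "RiskDefinition",
    "RiskSpecification",
    "KPIRecord",
    "validate_spec",
    "rule_condition_ids",
]

DATATYPES = ("boolean", "text", "date", "number")
CATEGORIES = ("medical", "organizational", "technical", "human", "cross-process")

#: Default ordinal severity scale, least to most severe.  The scale is data,
#: not code: specifications may configure their own ordered vocabulary.
DEFAULT_SEVERITY_SCALE = (
    "negligible",
    "minor",
    "moderate",
    "major",
    "catastrophic",
)

#: Operators applicable to ordered datatypes only (number, date).
ORDERING_OPERATORS = ("<", "<=", ">", ">=")
OPERATORS = ("IN", "==", "!=") + ORDERING_OPERATORS

ScalarValue = Union[bool, str, date, Decimal]

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding with a location path.

    ``severity`` is ``"error"`` for invariant violations and ``"warning"``
    for satisfiable-but-suspect constructs (e.g. an empty half-open
    interval, which can never hold).
    """

    location: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return f"{self.severity}: {self.location}: {self.message}"


@dataclass(frozen=True)
class ValueRange:
    """A value constraint: an interval, a finite set, or a single literal.

    Interval bounds of ``None`` denote minus/plus infinity; openness is
    carried per bound.  A degenerate interval (lower == upper) is only
    satisfiable when both bounds are closed.
    """

    kind: str  # "interval" | "set" | "literal"
    lower: Optional[Union[Decimal, date]] = None
    upper: Optional[Union[Decimal, date]] = None
    lower_closed: bool = True
    upper_closed: bool = False
    members: tuple[ScalarValue, ...] = ()
    literal: Optional[ScalarValue] = None

    def is_empty_interval(self) -> bool:
        if self.kind != "interval" or self.lower is None or self.upper is None:
            return False
        if self.lower > self.upper:
            return True
        if self.lower == self.upper:
            return not (self.lower_closed and self.upper_closed)
        return False

    def contains(self, value: ScalarValue) -> bool:
        """Membership under interval-openness semantics."""
        if self.kind == "literal":
            return value == self.literal
        if self.kind == "set":
            return any(value == m for m in self.members)
        if self.lower is not None:
            if value < self.lower or (value == self.lower and not self.lower_closed):
                return False
        if self.upper is not None:
            if value > self.upper or (value == self.upper and not self.upper_closed):
                return False
        return True


@dataclass(frozen=True)
class Condition:
    """A single property: one KPI (or arithmetic expression over KPIs and
    constants) constrained by an operator and a value range."""

    id: str
    kpi: str
    operator: str
    range: ValueRange
    lhs_expression: Optional[str] = None


class RuleExpression:
    """Base class of risk-rule AST nodes (see :class:`CondRef`,
    :class:`Not`, :class:`And`, :class:`Or`)."""

    __slots__ = ()


@dataclass(frozen=True)
class CondRef(RuleExpression):
    id: str


@dataclass(frozen=True)
class Not(RuleExpression):
    child: RuleExpression


@dataclass(frozen=True)
class And(RuleExpression):
    children: tuple[RuleExpression, ...]


@dataclass(frozen=True)
class Or(RuleExpression):
    children: tuple[RuleExpression, ...]


def rule_condition_ids(rule: RuleExpression) -> list[str]:
    """Condition ids referenced by a rule, in source order, deduplicated."""
    out: list[str] = []

    def walk(node: RuleExpression) -> None:
        if isinstance(node, CondRef):
            if node.id not in out:
                out.append(node.id)
        elif isinstance(node, Not):
            walk(node.child)
        elif isinstance(node, (And, Or)):
            for c in node.children:
                walk(c)

    walk(rule)
    return out


@dataclass(frozen=True)
class AdverseSituationLink:
    """Link from a risk to an adverse situation it may evolve into.

    ``probability`` is a closed sub-interval of [0, 1]; a point probability
    is stored as a degenerate interval.  ``severity`` must be a member of
    the specification's ordinal severity scale.
    """

    adverse_situation: str
    probability: tuple[Decimal, Decimal]
    severity: str


@dataclass(frozen=True)
class KPIDefinition:
    """A named, typed risk-relevant parameter with its measurement phases
    and acquisition source (e.g. patient record, checklist, sensor)."""

    name: str
    datatype: str
    unit: str = ""
    measurement_phases: tuple[str, ...] = ()
    acquisition_source: str = ""


@dataclass(frozen=True)
class RiskDefinition:
    """A composite property: a boolean rule over conditions, the phases in
    which the risk is relevant, and its adverse-situation links.

    A ``cross-process`` risk carries an empty ``relevant_phases`` list and
    is treated as relevant in every phase.
    """

    name: str
    category: str
    rule: RuleExpression
    relevant_phases: tuple[str, ...] = ()
    adverse_links: tuple[AdverseSituationLink, ...] = ()

    def is_cross_process(self) -> bool:
        return self.category == "cross-process"


@dataclass(frozen=True)
class RiskSpecification:
    """A complete risk specification: ordered treatment phases, KPIs,
    conditions, risks, named constants, and the severity scale."""

    phases: tuple[str, ...] = ()
    kpis: tuple[KPIDefinition, ...] = ()
    conditions: tuple[Condition, ...] = ()
    risks: tuple[RiskDefinition, ...] = ()
    constants: Mapping[str, ScalarValue] = field(default_factory=dict)
    severity_scale: tuple[str, ...] = DEFAULT_SEVERITY_SCALE

    def kpi_map(self) -> dict[str, KPIDefinition]:
        return {k.name: k for k in self.kpis}

    def condition_map(self) -> dict[str, Condition]:
        return {c.id: c for c in self.conditions}

    def risk_map(self) -> dict[str, RiskDefinition]:
        return {r.name: r for r in self.risks}

    def phases_of(self, risk: RiskDefinition) -> tuple[str, ...]:
        """Phases a risk is relevant in; cross-process expands to all."""
        if risk.is_cross_process() and not risk.relevant_phases:
            return self.phases
        return risk.relevant_phases


@dataclass(frozen=True)
class KPIRecord:
    """A patient's KPI values at one point in time of risk detection — the
    snapshot of a potential risk situation.  Missing KPIs are simply absent
    from ``values``."""

    subject_id: str
    phase: str
    timestamp: str
    values: Mapping[str, ScalarValue] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# validation


def _value_type_of(value: ScalarValue) -> str:
    if isinstance(value, bool):
        return "boolean"
    if isinstance(value, Decimal):
        return "number"
    if isinstance(value, date):
        return "date"
    if isinstance(value, str):
        return "text"
    return type(value).__name__


def _check_range_types(rng: ValueRange, datatype: str, loc: str,
                       out: list[Diagnostic]) -> None:
    def ok(v: ScalarValue) -> bool:
        return _value_type_of(v) == datatype

    if rng.kind == "interval":
        if datatype not in ("number", "date"):
            out.append(Diagnostic(loc, f"interval range over {datatype} KPI"))
        for bound, name in ((rng.lower, "lower"), (rng.upper, "upper")):
            if bound is not None and not ok(bound):
                out.append(Diagnostic(
                    loc, f"{name} bound {bound!r} is not a {datatype}"))
        if (rng.lower is not None and rng.upper is not None
                and _value_type_of(rng.lower) == _value_type_of(rng.upper)):
            if rng.lower > rng.upper:
                out.append(Diagnostic(loc, "interval lower bound exceeds upper bound"))
            elif rng.is_empty_interval():
                out.append(Diagnostic(
                    loc, "empty interval: equal bounds require both ends closed",
                    severity="warning"))
    elif rng.kind == "set":
        if not rng.members:
            out.append(Diagnostic(loc, "set range is empty"))
        for m in rng.members:
            if not ok(m):
                out.append(Diagnostic(loc, f"set member {m!r} is not a {datatype}"))
    elif rng.kind == "literal":
        if rng.literal is None or not ok(rng.literal):
            out.append(Diagnostic(
                loc, f"literal {rng.literal!r} is not a {datatype}"))
    else:
        out.append(Diagnostic(loc, f"unknown range kind {rng.kind!r}"))


_EXPR_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


def validate_spec(spec: RiskSpecification) -> list[Diagnostic]:
    """Check every model invariant; return one diagnostic per violation.

    Idempotent and side-effect free.  An empty list means the specification
    is valid.  Diagnostics of severity ``"warning"`` flag constructs that
    are well-formed but unsatisfiable (empty intervals).
    """
    out: list[Diagnostic] = []

    # phases
    seen_phases: set[str] = set()
    for i, p in enumerate(spec.phases):
        loc = f"phases[{i}]"
        if not p or not _IDENT_RE.match(p):
            out.append(Diagnostic(loc, f"invalid phase name {p!r}"))
        if p in seen_phases:
            out.append(Diagnostic(loc, f"duplicate phase {p!r}"))
        seen_phases.add(p)

    # severity scale
    if not spec.severity_scale:
        out.append(Diagnostic("severity_scale", "severity scale is empty"))
    elif len(set(spec.severity_scale)) != len(spec.severity_scale):
        out.append(Diagnostic("severity_scale", "severity scale has duplicates"))

    # constants
    for name, value in spec.constants.items():
        if not _IDENT_RE.match(name):
            out.append(Diagnostic(f"constants[{name}]", "invalid constant name"))
        if _value_type_of(value) not in DATATYPES:
            out.append(Diagnostic(
                f"constants[{name}]", f"unsupported constant value {value!r}"))

    # KPIs
    kpi_names: set[str] = set()
    for i, kpi in enumerate(spec.kpis):
        loc = f"kpis[{i}]({kpi.name})"
        if not kpi.name or not _IDENT_RE.match(kpi.name):
            out.append(Diagnostic(loc, f"invalid KPI name {kpi.name!r}"))
        if kpi.name in kpi_names:
            out.append(Diagnostic(loc, f"duplicate KPI name {kpi.name!r}"))
        kpi_names.add(kpi.name)
        if kpi.datatype not in DATATYPES:
            out.append(Diagnostic(loc, f"unknown datatype {kpi.datatype!r}"))
        for p in kpi.measurement_phases:
            if p not in seen_phases:
                out.append(Diagnostic(loc, f"undeclared measurement phase {p!r}"))

    kpis = spec.kpi_map()

    # conditions
    cond_ids: set[str] = set()
    for i, cond in enumerate(spec.conditions):
        loc = f"conditions[{i}]({cond.id})"
        if not cond.id or not _IDENT_RE.match(cond.id):
            out.append(Diagnostic(loc, f"invalid condition id {cond.id!r}"))
        if cond.id in cond_ids:
            out.append(Diagnostic(loc, f"duplicate condition id {cond.id!r}"))
        cond_ids.add(cond.id)
        if cond.operator not in OPERATORS:
            out.append(Diagnostic(loc, f"unknown operator {cond.operator!r}"))
            continue

        if cond.lhs_expression is not None:
            # every identifier in the expression must be a KPI or constant;
            # arithmetic left-hand sides are numeric by construction
            names = _EXPR_NAME_RE.findall(cond.lhs_expression)
            for n in names:
                if n not in kpis and n not in spec.constants:
                    out.append(Diagnostic(
                        loc, f"undeclared name {n!r} in arithmetic expression"))
            datatype = "number"
        elif cond.kpi not in kpis:
            out.append(Diagnostic(loc, f"undeclared KPI {cond.kpi!r}"))
            continue
        else:
            datatype = kpis[cond.kpi].datatype

        if cond.operator in ORDERING_OPERATORS and datatype not in ("number", "date"):
            out.append(Diagnostic(
                loc, f"ordering operator {cond.operator!r} on {datatype} KPI"))
        if cond.operator == "IN" and cond.range.kind == "literal":
            out.append(Diagnostic(loc, "IN requires an interval or set range"))
        if cond.operator != "IN" and cond.range.kind != "literal":
            out.append(Diagnostic(
                loc, f"comparison operator {cond.operator!r} requires a literal"))
        _check_range_types(cond.range, datatype, loc, out)

    # risks
    risk_names: set[str] = set()
    for i, risk in enumerate(spec.risks):
        loc = f"risks[{i}]({risk.name})"
        if not risk.name or not _IDENT_RE.match(risk.name):
            out.append(Diagnostic(loc, f"invalid risk name {risk.name!r}"))
        if risk.name in risk_names:
            out.append(Diagnostic(loc, f"duplicate risk name {risk.name!r}"))
        risk_names.add(risk.name)
        if risk.category not in CATEGORIES:
            out.append(Diagnostic(loc, f"unknown category {risk.category!r}"))
        if not risk.relevant_phases and not risk.is_cross_process():
            out.append(Diagnostic(
                loc, "empty phase list is permitted only for cross-process risks"))
        for p in risk.relevant_phases:
            if p not in seen_phases:
                out.append(Diagnostic(loc, f"undeclared phase {p!r}"))
        for cid in rule_condition_ids(risk.rule):
            if cid not in cond_ids:
                out.append(Diagnostic(loc, f"rule references undeclared condition {cid!r}"))
        out.extend(_check_rule_shape(risk.rule, loc))
        if not risk.adverse_links:
            out.append(Diagnostic(loc, "risk requires at least one adverse link"))
        for j, link in enumerate(risk.adverse_links):
            lloc = f"{loc}.adverse_links[{j}]"
            lo, hi = link.probability
            if not (Decimal(0) <= lo <= hi <= Decimal(1)):
                out.append(Diagnostic(
                    lloc, f"probability interval [{lo}, {hi}] not within [0, 1]"))
            if link.severity not in spec.severity_scale:
                out.append(Diagnostic(
                    lloc, f"severity {link.severity!r} not on the configured scale"))
            if not link.adverse_situation or not _IDENT_RE.match(link.adverse_situation):
                out.append(Diagnostic(
                    lloc, f"invalid adverse situation name {link.adverse_situation!r}"))

    return out


def _check_rule_shape(rule: RuleExpression, loc: str) -> list[Diagnostic]:
    out: list[Diagnostic] = []

    def walk(node: RuleExpression) -> None:
        if isinstance(node, (And, Or)):
            if len(node.children) < 2:
                kind = "AND" if isinstance(node, And) else "OR"
                out.append(Diagnostic(loc, f"{kind} node with fewer than 2 children"))
            for c in node.children:
                walk(c)
        elif isinstance(node, Not):
            walk(node.child)
        elif not isinstance(node, CondRef):
            out.append(Diagnostic(loc, f"unknown rule node {type(node).__name__}"))

    walk(rule)
    return out
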