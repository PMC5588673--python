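"""Compilation of risk specifications into a RIO-conformant OWL ontology.

For every condition a subclass of its KPI's class is generated, with an
anonymous equivalent class — a ``has_data_value`` property restriction
carrying the value range as datatype facets (number/date) or a value
enumeration (text/boolean).  For every risk a subclass of ``rio:Risk`` is
generated whose equivalent class is the structural translation of the rule
expression over ``has_part`` restrictions: AND becomes an intersection, OR
a union, NOT a complement.  Treatment phases become classes linked to the
KPIs and risks relevant in them, and adverse situations are attached to
risks as annotations, themselves annotated with the occurrence probability
(canonical decimal interval) and severity.

Arithmetic left-hand sides cannot be expressed as OWL datatype
restrictions; they are carried as an annotation on the condition class and
evaluated natively by the detection engine.

No description-logic reasoning is performed; the ontology is a faithful,
invertible carrier of the specification (:func:`extract_spec`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from datetime import date
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, OWL, XSD, URIRef
from rdflib.collection import Collection

from peririsk.risk_model import (
    AdverseSituationLink,
    And,
    CondRef,
    Condition,
    KPIDefinition,
    Not,
    Or,
    RiskDefinition,
    RiskSpecification,
    RuleExpression,
    ScalarValue,
    ValueRange,
)
from peririsk.spec_io import (
    format_probability_decimal,
    format_value,
    parse_constant_value,
    parse_probability_decimal,
)

__all__ = [
    "RIO",
    "RIOX",
    "DEFAULT_BASE_IRI",
    "OntologyModel",
    "generate_ontology",
    "extract_spec",
    "serialize_ontology",
    "load_ontology",
    "profile_check",
    "condition_class_name",
]

RIO = Namespace("https://w3id.org/peririsk/rio#")
RIOX = Namespace("https://w3id.org/peririsk/riox#")
DEFAULT_BASE_IRI = "https://w3id.org/peririsk/spec#"

_XSD_OF_DATATYPE = {"number": XSD.decimal, "date": XSD.date,
                    "boolean": XSD.boolean, "text": XSD.string}

_RESERVED = {"Risk", "KPI", "Treatment_phase", "Adverse_situation"}


@dataclass
class OntologyModel:
    """A generated (or loaded) ontology: an RDF graph plus its base IRI."""

    graph: Graph
    base_iri: str = DEFAULT_BASE_IRI

    def iri(self, name: str) -> URIRef:
        return URIRef(self.base_iri + name)


def condition_class_name(cond: Condition) -> str:
    """Deterministic class-naming scheme: ``<KPIName>_<conditionId>``."""
    return f"{cond.kpi}_{cond.id}"


def _vocab_graph() -> Graph:
    g = Graph()
    text = resources.files("peririsk").joinpath(
        "vocab/rio_stub.ttl").read_text(encoding="utf-8")
    g.parse(data=text, format="turtle")
    return g


class _Builder:
    """Accumulates the generated axioms; blank nodes get sequential labels
    so serialization is deterministic."""

    def __init__(self, base_iri: str):
        self.model = OntologyModel(graph=_vocab_graph(), base_iri=base_iri)
        g = self.model.graph
        g.bind("rio", RIO)
        g.bind("riox", RIOX)
        g.bind("spec", Namespace(base_iri))
        g.bind("owl", OWL)
        self._counter = itertools.count()

    def bnode(self) -> BNode:
        return BNode(f"n{next(self._counter):06d}")

    def rdf_list(self, items) -> BNode:
        head = self.bnode()
        Collection(self.model.graph, head, list(items))
        return head


def _typed_literal(value: ScalarValue) -> Literal:
    if isinstance(value, bool):
        return Literal(value)
    if isinstance(value, Decimal):
        return Literal(value, datatype=XSD.decimal)
    if isinstance(value, date):
        return Literal(value, datatype=XSD.date)
    return Literal(value)


def _facet_restriction(b: _Builder, rng: ValueRange, operator: str,
                       xsd_type: URIRef):
    """Datatype restriction (or plain datatype) for a numeric/date range."""
    g = b.model.graph
    facets: list[tuple[URIRef, ScalarValue]] = []
    if operator == "IN":
        if rng.lower is not None:
            facets.append((XSD.minInclusive if rng.lower_closed
                           else XSD.minExclusive, rng.lower))
        if rng.upper is not None:
            facets.append((XSD.maxInclusive if rng.upper_closed
                           else XSD.maxExclusive, rng.upper))
    elif operator == "<":
        facets.append((XSD.maxExclusive, rng.literal))
    elif operator == "<=":
        facets.append((XSD.maxInclusive, rng.literal))
    elif operator == ">":
        facets.append((XSD.minExclusive, rng.literal))
    elif operator == ">=":
        facets.append((XSD.minInclusive, rng.literal))
    else:
        raise ValueError(f"unsupported facet operator {operator!r}")
    if not facets:
        return xsd_type  # vacuous range: the raw datatype
    dr = b.bnode()
    g.add((dr, RDF.type, RDFS.Datatype))
    g.add((dr, OWL.onDatatype, xsd_type))
    facet_nodes = []
    for facet, value in facets:
        fn = b.bnode()
        g.add((fn, facet, _typed_literal(value)))
        facet_nodes.append(fn)
    g.add((dr, OWL.withRestrictions, b.rdf_list(facet_nodes)))
    return dr


def _one_of_datatype(b: _Builder, values) -> BNode:
    g = b.model.graph
    dr = b.bnode()
    g.add((dr, RDF.type, RDFS.Datatype))
    g.add((dr, OWL.oneOf, b.rdf_list([_typed_literal(v) for v in values])))
    return dr


def generate_condition_class(b: _Builder, cond: Condition,
                             datatype: str) -> URIRef:
    """Condition subclass of its KPI class plus the equivalent
    ``has_data_value`` restriction."""
    g = b.model.graph
    name = condition_class_name(cond)
    if name in _RESERVED:
        raise ValueError(f"condition class name {name!r} collides with core vocabulary")
    cls = b.model.iri(name)
    g.add((cls, RDF.type, OWL.Class))
    g.add((cls, RDFS.subClassOf, b.model.iri(cond.kpi)))
    g.add((cls, RIOX.condition_id, Literal(cond.id)))
    g.add((cls, RIOX.operator, Literal(cond.operator)))
    if cond.lhs_expression is not None:
        g.add((cls, RIOX.lhs_expression, Literal(cond.lhs_expression)))

    effective = "number" if cond.lhs_expression is not None else datatype
    rng = cond.range
    restriction = b.bnode()
    g.add((restriction, RDF.type, OWL.Restriction))
    g.add((restriction, OWL.onProperty, RIO.has_data_value))
    if cond.operator == "==":
        g.add((restriction, OWL.hasValue, _typed_literal(rng.literal)))
    elif cond.operator == "!=":
        comp = b.bnode()
        g.add((comp, RDF.type, RDFS.Datatype))
        g.add((comp, OWL.datatypeComplementOf,
               _one_of_datatype(b, [rng.literal])))
        g.add((restriction, OWL.someValuesFrom, comp))
    elif cond.operator == "IN" and rng.kind == "set":
        g.add((restriction, OWL.someValuesFrom,
               _one_of_datatype(b, rng.members)))
    else:
        g.add((restriction, OWL.someValuesFrom,
               _facet_restriction(b, rng, cond.operator,
                                  _XSD_OF_DATATYPE[effective])))
    g.add((cls, OWL.equivalentClass, restriction))
    return cls


def _rule_expression_node(b: _Builder, node: RuleExpression,
                          cond_class: dict[str, URIRef]):
    g = b.model.graph
    if isinstance(node, CondRef):
        r = b.bnode()
        g.add((r, RDF.type, OWL.Restriction))
        g.add((r, OWL.onProperty, RIO.has_part))
        g.add((r, OWL.someValuesFrom, cond_class[node.id]))
        return r
    if isinstance(node, Not):
        c = b.bnode()
        g.add((c, RDF.type, OWL.Class))
        g.add((c, OWL.complementOf,
               _rule_expression_node(b, node.child, cond_class)))
        return c
    if isinstance(node, (And, Or)):
        c = b.bnode()
        g.add((c, RDF.type, OWL.Class))
        prop = OWL.intersectionOf if isinstance(node, And) else OWL.unionOf
        children = [_rule_expression_node(b, ch, cond_class)
                    for ch in node.children]
        g.add((c, prop, b.rdf_list(children)))
        return c
    raise TypeError(f"unknown rule node {type(node).__name__}")


def generate_risk_class(b: _Builder, risk: RiskDefinition,
                        cond_class: dict[str, URIRef]) -> URIRef:
    """Risk subclass of ``rio:Risk`` plus the equivalent ``has_part``
    expression representing the rule."""
    g = b.model.graph
    if risk.name in _RESERVED:
        raise ValueError(f"risk name {risk.name!r} collides with core vocabulary")
    cls = b.model.iri(risk.name)
    g.add((cls, RDF.type, OWL.Class))
    g.add((cls, RDFS.subClassOf, RIO.Risk))
    g.add((cls, RIOX.category, Literal(risk.category)))
    g.add((cls, OWL.equivalentClass,
           _rule_expression_node(b, risk.rule, cond_class)))
    return cls


def generate_phase_links(b: _Builder, spec: RiskSpecification) -> None:
    """Phase classes plus ``risk_in_phase`` and ``kpi_in_phase`` links;
    cross-process risks are linked to every phase."""
    g = b.model.graph
    for order, phase in enumerate(spec.phases, start=1):
        cls = b.model.iri(phase)
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.subClassOf, RIO.Treatment_phase))
        g.add((cls, RIOX.phase_order, Literal(order)))
    for kpi in spec.kpis:
        for phase in kpi.measurement_phases:
            g.add((b.model.iri(kpi.name), RIO.kpi_in_phase, b.model.iri(phase)))
    for risk in spec.risks:
        for phase in spec.phases_of(risk):
            g.add((b.model.iri(risk.name), RIO.risk_in_phase, b.model.iri(phase)))


def annotate_adverse_links(b: _Builder, risk: RiskDefinition) -> None:
    """``risk_for_adverse_situation`` annotations, each reified and
    annotated with ``as_probability`` (canonical decimal interval) and the
    severity grade."""
    g = b.model.graph
    for idx, link in enumerate(risk.adverse_links):
        as_cls = b.model.iri(link.adverse_situation)
        if (as_cls, RDF.type, OWL.Class) not in g:
            g.add((as_cls, RDF.type, OWL.Class))
            g.add((as_cls, RDFS.subClassOf, RIO.Adverse_situation))
        risk_cls = b.model.iri(risk.name)
        g.add((risk_cls, RIO.risk_for_adverse_situation, as_cls))
        ax = b.bnode()
        g.add((ax, RDF.type, OWL.Axiom))
        g.add((ax, OWL.annotatedSource, risk_cls))
        g.add((ax, OWL.annotatedProperty, RIO.risk_for_adverse_situation))
        g.add((ax, OWL.annotatedTarget, as_cls))
        g.add((ax, RIO.as_probability,
               Literal(format_probability_decimal(link.probability))))
        g.add((ax, RIOX.severity, Literal(link.severity)))
        g.add((ax, RIOX["index"], Literal(idx)))


def generate_ontology(spec: RiskSpecification,
                      base_iri: str = DEFAULT_BASE_IRI) -> OntologyModel:
    """Compile a full specification into an :class:`OntologyModel`."""
    b = _Builder(base_iri)
    g = b.model.graph
    ont = URIRef(base_iri.rstrip("#/"))
    g.add((ont, RDF.type, OWL.Ontology))
    g.add((ont, RIOX.severity_scale, Literal(";".join(spec.severity_scale))))
    for name, value in spec.constants.items():
        datatype = ("boolean" if isinstance(value, bool) else
                    "number" if isinstance(value, Decimal) else
                    "date" if isinstance(value, date) else "text")
        raw = value if isinstance(value, str) else format_value(value)
        g.add((ont, RIOX.constant, Literal(f"{name}|{datatype}|{raw}")))

    kpi_types: dict[str, str] = {}
    for idx, kpi in enumerate(spec.kpis):
        cls = b.model.iri(kpi.name)
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.subClassOf, RIO.KPI))
        g.add((cls, RIOX.datatype, Literal(kpi.datatype)))
        g.add((cls, RIOX["index"], Literal(idx)))
        if kpi.unit:
            g.add((cls, RIOX.unit, Literal(kpi.unit)))
        if kpi.acquisition_source:
            g.add((cls, RIOX.acquisition_source, Literal(kpi.acquisition_source)))
        kpi_types[kpi.name] = kpi.datatype

    cond_class: dict[str, URIRef] = {}
    for idx, cond in enumerate(spec.conditions):
        cls = generate_condition_class(
            b, cond, kpi_types.get(cond.kpi, "number"))
        g.add((cls, RIOX["index"], Literal(idx)))
        cond_class[cond.id] = cls

    for idx, risk in enumerate(spec.risks):
        cls = generate_risk_class(b, risk, cond_class)
        g.add((cls, RIOX["index"], Literal(idx)))
        annotate_adverse_links(b, risk)

    generate_phase_links(b, spec)
    return b.model


# ---------------------------------------------------------------------------
# extraction (inverse of generation)


class ExtractionError(ValueError):
    """Non-conformant axiom shape in an ontology being extracted."""


def _literal_value(lit: Literal) -> ScalarValue:
    v = lit.toPython()
    if isinstance(v, bool) or isinstance(v, date):
        return v
    if isinstance(v, Decimal):
        return v
    if isinstance(v, (int, float)):
        return Decimal(str(v))
    return str(v)


def _extract_range(g: Graph, cls: URIRef, operator: str) -> ValueRange:
    restriction = g.value(cls, OWL.equivalentClass)
    if restriction is None:
        raise ExtractionError(f"{cls}: condition class without equivalent restriction")
    has_value = g.value(restriction, OWL.hasValue)
    if has_value is not None:
        return ValueRange(kind="literal", literal=_literal_value(has_value))
    some = g.value(restriction, OWL.someValuesFrom)
    if some is None:
        raise ExtractionError(f"{cls}: restriction has neither hasValue nor someValuesFrom")
    comp = g.value(some, OWL.datatypeComplementOf)
    if comp is not None:
        members = list(Collection(g, g.value(comp, OWL.oneOf)))
        return ValueRange(kind="literal", literal=_literal_value(members[0]))
    one_of = g.value(some, OWL.oneOf)
    if one_of is not None:
        return ValueRange(kind="set", members=tuple(
            _literal_value(m) for m in Collection(g, one_of)))
    if isinstance(some, URIRef):
        # vacuous facet: the raw datatype, i.e. the full range
        return (ValueRange(kind="interval", lower=None, upper=None)
                if operator == "IN"
                else ValueRange(kind="literal"))
    facets: dict[str, ScalarValue] = {}
    restrictions = g.value(some, OWL.withRestrictions)
    if restrictions is not None:
        for fn in Collection(g, restrictions):
            for facet in (XSD.minInclusive, XSD.minExclusive,
                          XSD.maxInclusive, XSD.maxExclusive):
                v = g.value(fn, facet)
                if v is not None:
                    facets[str(facet).rsplit("#")[-1]] = _literal_value(v)
    if operator == "IN":
        lower = facets.get("minInclusive", facets.get("minExclusive"))
        upper = facets.get("maxInclusive", facets.get("maxExclusive"))
        return ValueRange(
            kind="interval", lower=lower, upper=upper,
            lower_closed="minExclusive" not in facets,
            upper_closed="maxInclusive" in facets)
    value = next(iter(facets.values()), None)
    return ValueRange(kind="literal", literal=value)


def _extract_rule(g: Graph, node, cond_of_class: dict[URIRef, str]) -> RuleExpression:
    if (node, OWL.onProperty, RIO.has_part) in g:
        target = g.value(node, OWL.someValuesFrom)
        if target not in cond_of_class:
            raise ExtractionError(f"has_part restriction on unknown class {target}")
        return CondRef(cond_of_class[target])
    comp = g.value(node, OWL.complementOf)
    if comp is not None:
        return Not(_extract_rule(g, comp, cond_of_class))
    inter = g.value(node, OWL.intersectionOf)
    if inter is not None:
        return And(tuple(_extract_rule(g, c, cond_of_class)
                         for c in Collection(g, inter)))
    union = g.value(node, OWL.unionOf)
    if union is not None:
        return Or(tuple(_extract_rule(g, c, cond_of_class)
                        for c in Collection(g, union)))
    raise ExtractionError(f"unrecognized rule expression node {node}")


def _local(iri: URIRef, base: str) -> str:
    return str(iri)[len(base):]


def _index_of(g: Graph, cls) -> int:
    v = g.value(cls, RIOX["index"])
    return int(v.toPython()) if v is not None else 0


def extract_spec(model: OntologyModel) -> RiskSpecification:
    """Recover the specification from a generated (or structurally
    conformant) ontology; the inverse of :func:`generate_ontology` up to
    generated class names."""
    g = model.graph
    base = model.base_iri

    phase_classes = sorted(
        g.subjects(RDFS.subClassOf, RIO.Treatment_phase),
        key=lambda c: int(g.value(c, RIOX.phase_order).toPython()))
    phases = tuple(_local(c, base) for c in phase_classes)
    phase_rank = {c: i for i, c in enumerate(phase_classes)}

    kpi_classes = sorted(g.subjects(RDFS.subClassOf, RIO.KPI),
                         key=lambda c: _index_of(g, c))
    kpis = []
    for cls in kpi_classes:
        measured = sorted(g.objects(cls, RIO.kpi_in_phase),
                          key=lambda p: phase_rank.get(p, 0))
        dt = g.value(cls, RIOX.datatype)
        if dt is None:
            raise ExtractionError(f"{cls}: KPI class without datatype annotation")
        kpis.append(KPIDefinition(
            name=_local(cls, base),
            datatype=str(dt),
            unit=str(g.value(cls, RIOX.unit) or ""),
            measurement_phases=tuple(_local(p, base) for p in measured),
            acquisition_source=str(g.value(cls, RIOX.acquisition_source) or ""),
        ))

    cond_classes = []
    for kpi_cls in kpi_classes:
        for cls in g.subjects(RDFS.subClassOf, kpi_cls):
            if g.value(cls, RIOX.condition_id) is not None:
                cond_classes.append(cls)
    cond_classes.sort(key=lambda c: _index_of(g, c))
    conditions = []
    cond_of_class: dict[URIRef, str] = {}
    for cls in cond_classes:
        cid = str(g.value(cls, RIOX.condition_id))
        operator = str(g.value(cls, RIOX.operator))
        lhs = g.value(cls, RIOX.lhs_expression)
        kpi_cls = g.value(cls, RDFS.subClassOf)
        conditions.append(Condition(
            id=cid,
            kpi=_local(kpi_cls, base),
            operator=operator,
            range=_extract_range(g, cls, operator),
            lhs_expression=str(lhs) if lhs is not None else None,
        ))
        cond_of_class[cls] = cid

    risk_classes = sorted(g.subjects(RDFS.subClassOf, RIO.Risk),
                          key=lambda c: _index_of(g, c))
    risks = []
    for cls in risk_classes:
        category = str(g.value(cls, RIOX.category) or "medical")
        rule_node = g.value(cls, OWL.equivalentClass)
        if rule_node is None:
            raise ExtractionError(f"{cls}: risk class without equivalent expression")
        rule = _extract_rule(g, rule_node, cond_of_class)
        if category == "cross-process":
            relevant: tuple[str, ...] = ()
        else:
            linked = sorted(g.objects(cls, RIO.risk_in_phase),
                            key=lambda p: phase_rank.get(p, 0))
            relevant = tuple(_local(p, base) for p in linked)
        links = []
        axioms = [ax for ax in g.subjects(OWL.annotatedSource, cls)
                  if (ax, OWL.annotatedProperty,
                      RIO.risk_for_adverse_situation) in g]
        axioms.sort(key=lambda ax: _index_of(g, ax))
        for ax in axioms:
            target = g.value(ax, OWL.annotatedTarget)
            prob = g.value(ax, RIO.as_probability)
            links.append(AdverseSituationLink(
                adverse_situation=_local(target, base),
                probability=parse_probability_decimal(str(prob)),
                severity=str(g.value(ax, RIOX.severity) or ""),
            ))
        risks.append(RiskDefinition(
            name=_local(cls, base), category=category, rule=rule,
            relevant_phases=relevant, adverse_links=tuple(links)))

    ont = URIRef(base.rstrip("#/"))
    scale = g.value(ont, RIOX.severity_scale)
    constants: dict[str, ScalarValue] = {}
    for lit in sorted(g.objects(ont, RIOX.constant), key=str):
        name, datatype, raw = str(lit).split("|", 2)
        constants[name] = parse_constant_value(datatype, raw)

    from peririsk.risk_model import DEFAULT_SEVERITY_SCALE

    return RiskSpecification(
        phases=phases, kpis=tuple(kpis), conditions=tuple(conditions),
        risks=tuple(risks), constants=constants,
        severity_scale=tuple(str(scale).split(";")) if scale is not None
        else DEFAULT_SEVERITY_SCALE)


# ---------------------------------------------------------------------------
# serialization


def _serialize_functional(model: OntologyModel) -> str:
    """OWL functional-syntax rendering of the generated axiom shapes."""
    spec = extract_spec(model)
    base = model.base_iri
    out = [
        "Prefix(:=<%s>)" % base,
        "Prefix(rio:=<%s>)" % RIO,
        "Prefix(xsd:=<http://www.w3.org/2001/XMLSchema#>)",
        "",
        "Ontology(<%s>" % base.rstrip("#/"),
    ]

    def lit(v: ScalarValue) -> str:
        if isinstance(v, bool):
            return '"%s"^^xsd:boolean' % ("true" if v else "false")
        if isinstance(v, Decimal):
            return '"%s"^^xsd:decimal' % format_value(v)
        if isinstance(v, date):
            return '"%s"^^xsd:date' % v.isoformat()
        return '"%s"' % str(v).replace('"', '\\"')

    def data_range(cond: Condition, datatype: str) -> str:
        xsd_name = {"number": "xsd:decimal", "date": "xsd:date",
                    "boolean": "xsd:boolean", "text": "xsd:string"}[datatype]
        rng = cond.range
        if cond.operator == "==":
            return None  # hasValue handled by caller
        if cond.operator == "!=":
            return f"DataComplementOf(DataOneOf({lit(rng.literal)}))"
        if cond.operator == "IN" and rng.kind == "set":
            return "DataOneOf(%s)" % " ".join(lit(m) for m in rng.members)
        facets = []
        if cond.operator == "IN":
            if rng.lower is not None:
                facets.append(("xsd:minInclusive" if rng.lower_closed
                               else "xsd:minExclusive", rng.lower))
            if rng.upper is not None:
                facets.append(("xsd:maxInclusive" if rng.upper_closed
                               else "xsd:maxExclusive", rng.upper))
        else:
            facet = {"<": "xsd:maxExclusive", "<=": "xsd:maxInclusive",
                     ">": "xsd:minExclusive", ">=": "xsd:minInclusive"}[cond.operator]
            facets.append((facet, rng.literal))
        if not facets:
            return xsd_name
        return "DatatypeRestriction(%s %s)" % (
            xsd_name, " ".join(f"{f} {lit(v)}" for f, v in facets))

    def class_expr(node: RuleExpression, cond_cls: dict[str, str]) -> str:
        if isinstance(node, CondRef):
            return f"ObjectSomeValuesFrom(rio:has_part :{cond_cls[node.id]})"
        if isinstance(node, Not):
            return f"ObjectComplementOf({class_expr(node.child, cond_cls)})"
        if isinstance(node, And):
            return "ObjectIntersectionOf(%s)" % " ".join(
                class_expr(c, cond_cls) for c in node.children)
        return "ObjectUnionOf(%s)" % " ".join(
            class_expr(c, cond_cls) for c in node.children)

    for phase in spec.phases:
        out.append(f"Declaration(Class(:{phase}))")
        out.append(f"SubClassOf(:{phase} rio:Treatment_phase)")
    kpi_types = {}
    for kpi in spec.kpis:
        kpi_types[kpi.name] = kpi.datatype
        out.append(f"Declaration(Class(:{kpi.name}))")
        out.append(f"SubClassOf(:{kpi.name} rio:KPI)")
    cond_cls = {}
    for cond in spec.conditions:
        name = condition_class_name(cond)
        cond_cls[cond.id] = name
        out.append(f"Declaration(Class(:{name}))")
        out.append(f"SubClassOf(:{name} :{cond.kpi})")
        dt = "number" if cond.lhs_expression else kpi_types.get(cond.kpi, "number")
        if cond.operator == "==":
            out.append("EquivalentClasses(:%s DataHasValue(rio:has_data_value %s))"
                       % (name, lit(cond.range.literal)))
        else:
            out.append(
                "EquivalentClasses(:%s DataSomeValuesFrom(rio:has_data_value %s))"
                % (name, data_range(cond, dt)))
    for risk in spec.risks:
        out.append(f"Declaration(Class(:{risk.name}))")
        out.append(f"SubClassOf(:{risk.name} rio:Risk)")
        out.append("EquivalentClasses(:%s %s)"
                   % (risk.name, class_expr(risk.rule, cond_cls)))
        for link in risk.adverse_links:
            out.append(f"Declaration(Class(:{link.adverse_situation}))")
            out.append(f"SubClassOf(:{link.adverse_situation} rio:Adverse_situation)")
            out.append(
                'AnnotationAssertion(Annotation(rio:as_probability "%s") '
                "rio:risk_for_adverse_situation :%s :%s)"
                % (format_probability_decimal(link.probability),
                   risk.name, link.adverse_situation))
        for phase in spec.phases_of(risk):
            out.append(f"AnnotationAssertion(rio:risk_in_phase :{risk.name} :{phase})")
    out.append(")")
    # deduplicate declarations while preserving order
    seen = set()
    deduped = []
    for line in out:
        if line.startswith("Declaration(") and line in seen:
            continue
        seen.add(line)
        deduped.append(line)
    return "\n".join(deduped) + "\n"


def serialize_ontology(model: OntologyModel, path: Union[str, Path],
                       fmt: Optional[str] = None) -> Path:
    """Write the ontology as Turtle (``.ttl``), RDF/XML (``.owl``) or OWL
    functional syntax (``.ofn``); Turtle output is deterministic for a
    given specification."""
    path = Path(path)
    if fmt is None:
        fmt = {"ttl": "turtle", "owl": "rdfxml", "ofn": "ofn"}.get(
            path.suffix.lstrip("."), "turtle")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt in ("turtle", "ttl"):
        path.write_text(model.graph.serialize(format="turtle"), encoding="utf-8")
    elif fmt in ("rdfxml", "owl", "xml"):
        path.write_text(model.graph.serialize(format="xml"), encoding="utf-8")
    elif fmt == "ofn":
        path.write_text(_serialize_functional(model), encoding="utf-8")
    else:
        raise ValueError(f"unknown ontology format {fmt!r}")
    return path


def load_ontology(path: Union[str, Path],
                  base_iri: str = DEFAULT_BASE_IRI) -> OntologyModel:
    """Parse a Turtle or RDF/XML ontology file into an
    :class:`OntologyModel`."""
    g = Graph()
    path = Path(path)
    fmt = "turtle" if path.suffix == ".ttl" else "xml"
    g.parse(path.as_posix(), format=fmt)
    return OntologyModel(graph=g, base_iri=base_iri)


# ---------------------------------------------------------------------------
# structural profile check


def profile_check(model: OntologyModel) -> list[str]:
    """Structural conformance: no punning (no IRI that is both a class and
    an individual), every generated class has exactly one named superclass,
    and no orphan generated classes."""
    g = model.graph
    problems = []
    classes = set(g.subjects(RDF.type, OWL.Class))
    individuals = set(g.subjects(RDF.type, OWL.NamedIndividual))
    for iri in classes & individuals:
        problems.append(f"punning: {iri} is both a class and an individual")
    base = model.base_iri
    for cls in classes:
        if not isinstance(cls, URIRef) or not str(cls).startswith(base):
            continue
        supers = [s for s in g.objects(cls, RDFS.subClassOf)
                  if isinstance(s, URIRef)]
        if len(supers) == 0:
            problems.append(f"orphan class {cls}: no named superclass")
        elif len(supers) > 1:
            problems.append(f"class {cls} has {len(supers)} named superclasses")
    return problems
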