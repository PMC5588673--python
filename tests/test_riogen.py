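"""Ontology generation: axiom shapes, counts, and invertibility."""

from __future__ import annotations

import dataclasses

import pytest
from rdflib import Graph, Literal, OWL, RDF, RDFS, XSD
from rdflib.collection import Collection

from peririsk.fixtures import FixtureConfig, random_spec
from peririsk.riogen import (
    RIO,
    RIOX,
    extract_spec,
    generate_ontology,
    load_ontology,
    profile_check,
    serialize_ontology,
)


@pytest.fixture(scope="module")
def model(meningitis_spec):
    return generate_ontology(meningitis_spec)


def _facets(graph, cls):
    restriction = graph.value(cls, OWL.equivalentClass)
    some = graph.value(restriction, OWL.someValuesFrom)
    out = {}
    for fn in Collection(graph, graph.value(some, OWL.withRestrictions)):
        for facet in (XSD.minInclusive, XSD.minExclusive,
                      XSD.maxInclusive, XSD.maxExclusive):
            v = graph.value(fn, facet)
            if v is not None:
                out[facet] = v.toPython()
    return out


class TestConditionClasses:
    def test_age_condition_becomes_facetted_datatype_restriction(self, model):
        cls = model.iri("Age_in_months_c1")
        g = model.graph
        assert (cls, RDFS.subClassOf, model.iri("Age_in_months")) in g
        restriction = g.value(cls, OWL.equivalentClass)
        assert g.value(restriction, OWL.onProperty) == RIO.has_data_value
        facets = _facets(g, cls)
        assert facets == {XSD.minInclusive: 0, XSD.maxExclusive: 5}

    def test_text_equality_becomes_has_value(self, model):
        cls = model.iri("Vaccination_status_c4")
        restriction = model.graph.value(cls, OWL.equivalentClass)
        assert model.graph.value(restriction, OWL.hasValue) == Literal("no")

    def test_vacuous_range_falls_back_to_raw_datatype(self, meningitis_spec):
        from decimal import Decimal

        from peririsk.risk_model import Condition, ValueRange

        cond = Condition("c7", "Age_in_months", "IN",
                         ValueRange("interval", lower=None, upper=None))
        spec = dataclasses.replace(
            meningitis_spec, conditions=meningitis_spec.conditions + (cond,))
        m = generate_ontology(spec)
        restriction = m.graph.value(m.iri("Age_in_months_c7"),
                                    OWL.equivalentClass)
        assert m.graph.value(restriction, OWL.someValuesFrom) == XSD.decimal


class TestRiskClasses:
    def test_rule_becomes_union_of_intersections_of_has_part(self, model):
        g = model.graph
        cls = model.iri("Infection_Risk_001")
        assert (cls, RDFS.subClassOf, RIO.Risk) in g
        expr = g.value(cls, OWL.equivalentClass)
        branches = list(Collection(g, g.value(expr, OWL.unionOf)))
        assert len(branches) == 2
        for branch, expected in zip(branches, (("c1", "c4", "c6"),
                                               ("c3", "c5", "c6"))):
            parts = list(Collection(g, g.value(branch, OWL.intersectionOf)))
            assert len(parts) == 3
            targets = [g.value(p, OWL.someValuesFrom) for p in parts]
            ids = [str(g.value(t, RIOX.condition_id)) for t in targets]
            assert tuple(ids) == expected
            for p in parts:
                assert g.value(p, OWL.onProperty) == RIO.has_part

    def test_single_condition_rule_is_plain_restriction(self, meningitis_spec):
        from peririsk.risk_model import CondRef

        risk = dataclasses.replace(meningitis_spec.risks[0],
                                   rule=CondRef("c1"))
        m = generate_ontology(dataclasses.replace(meningitis_spec,
                                                  risks=(risk,)))
        expr = m.graph.value(m.iri("Infection_Risk_001"), OWL.equivalentClass)
        assert m.graph.value(expr, OWL.onProperty) == RIO.has_part
        assert m.graph.value(expr, OWL.someValuesFrom) == \
            m.iri("Age_in_months_c1")


class TestPhaseAndAdverseLinks:
    def test_risk_in_phase_assertions(self, model, meningitis_spec):
        g = model.graph
        cls = model.iri("Infection_Risk_001")
        phases = set(g.objects(cls, RIO.risk_in_phase))
        assert phases == {model.iri("indication"), model.iri("preoperative")}

    def test_cross_process_risk_links_to_every_phase(self, meningitis_spec):
        risk = dataclasses.replace(meningitis_spec.risks[0],
                                   category="cross-process",
                                   relevant_phases=())
        m = generate_ontology(dataclasses.replace(meningitis_spec,
                                                  risks=(risk,)))
        links = list(m.graph.objects(m.iri("Infection_Risk_001"),
                                     RIO.risk_in_phase))
        assert len(links) == len(meningitis_spec.phases)

    def test_probability_annotation_is_nested_on_adverse_link(self, model):
        g = model.graph
        axioms = [ax for ax in g.subjects(RDF.type, OWL.Axiom)
                  if g.value(ax, OWL.annotatedProperty)
                  == RIO.risk_for_adverse_situation]
        assert len(axioms) == 1
        ax = axioms[0]
        assert g.value(ax, OWL.annotatedTarget) == model.iri("Meningitis")
        assert str(g.value(ax, RIO.as_probability)) == "0.05–0.09"
        assert str(g.value(ax, RIOX.severity)) == "major"


class TestAxiomCountLaws:
    @pytest.mark.parametrize("seed", range(8))
    def test_counts_match_specification(self, seed):
        spec = random_spec(FixtureConfig(seed=seed))
        m = generate_ontology(spec)
        g = m.graph
        n_conditions = sum(
            1 for c in g.subjects(RIOX.condition_id, None))
        assert n_conditions == len(spec.conditions)
        risk_classes = set(g.subjects(RDFS.subClassOf, RIO.Risk))
        assert len(risk_classes) == len(spec.risks)
        n_links = sum(1 for _ in g.triples((None, RIO.risk_in_phase, None)))
        assert n_links == sum(len(spec.phases_of(r)) for r in spec.risks)


class TestRoundTrip:
    def test_extraction_inverts_generation_on_random_specs(self):
        for seed in range(50):
            spec = random_spec(FixtureConfig(seed=seed,
                                             arithmetic_probability=0.2))
            assert extract_spec(generate_ontology(spec)) == spec

    def test_turtle_serialization_reloads_and_extracts(self, tmp_path,
                                                       meningitis_spec, model):
        path = serialize_ontology(model, tmp_path / "m.ttl")
        reloaded = load_ontology(path)
        assert extract_spec(reloaded) == meningitis_spec

    def test_rdfxml_serialization_reloads_and_extracts(self, tmp_path,
                                                       meningitis_spec, model):
        path = serialize_ontology(model, tmp_path / "m.owl")
        assert extract_spec(load_ontology(path)) == meningitis_spec

    def test_functional_syntax_carries_rule_and_facets(self, tmp_path, model):
        path = serialize_ontology(model, tmp_path / "m.ofn")
        text = path.read_text()
        assert ("EquivalentClasses(:Age_in_months_c1 DataSomeValuesFrom("
                "rio:has_data_value DatatypeRestriction(xsd:decimal "
                'xsd:minInclusive "0"^^xsd:decimal '
                'xsd:maxExclusive "5"^^xsd:decimal)))') in text
        assert "ObjectUnionOf(ObjectIntersectionOf(" in text

    def test_turtle_output_is_deterministic(self, tmp_path, meningitis_spec):
        a = generate_ontology(meningitis_spec).graph.serialize(format="turtle")
        b = generate_ontology(meningitis_spec).graph.serialize(format="turtle")
        assert a == b

    def test_regeneration_from_extracted_spec_is_isomorphic(self):
        from rdflib.compare import isomorphic

        for seed in range(10):
            spec = random_spec(FixtureConfig(seed=seed))
            m1 = generate_ontology(spec)
            m2 = generate_ontology(extract_spec(m1))
            assert isomorphic(m1.graph, m2.graph)


class TestProfile:
    def test_generated_ontology_is_structurally_clean(self, model):
        assert profile_check(model) == []

    def test_generated_turtle_parses_in_fresh_graph(self, tmp_path, model):
        path = serialize_ontology(model, tmp_path / "m.ttl")
        g = Graph()
        g.parse(path.as_posix(), format="turtle")
        assert len(g) == len(model.graph)

    def test_empty_spec_yields_vocabulary_stub_only(self):
        from peririsk.risk_model import RiskSpecification

        m = generate_ontology(RiskSpecification())
        assert profile_check(m) == []
        assert not list(m.graph.subjects(RDFS.subClassOf, RIO.Risk))
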