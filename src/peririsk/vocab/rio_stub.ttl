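@prefix rio: <https://w3id.org/peririsk/rio#> .
@prefix riox: <https://w3id.org/peririsk/riox#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

# Minimal risk-identification vocabulary: the core classes and properties
# the generated ontologies build on.

rio:Risk a owl:Class ;
    rdfs:comment "A composite risk property over single condition properties." .

rio:KPI a owl:Class ;
    rdfs:comment "A risk-relevant key performance indicator." .

rio:Treatment_phase a owl:Class ;
    rdfs:comment "A phase of the perioperative treatment process." .

rio:Adverse_situation a owl:Class ;
    rdfs:comment "A situation containing an adverse event." .

rio:has_part a owl:ObjectProperty ;
    rdfs:comment "Composition of a composite property from single properties." .

rio:has_data_value a owl:DatatypeProperty ;
    rdfs:comment "The current value of a KPI." .

rio:risk_in_phase a owl:AnnotationProperty ;
    rdfs:comment "A risk is relevant in a treatment phase." .

rio:kpi_in_phase a owl:AnnotationProperty ;
    rdfs:comment "A KPI is measured in a treatment phase." .

rio:risk_for_adverse_situation a owl:AnnotationProperty ;
    rdfs:comment "Adverse situation possibly evolving from a risk." .

rio:as_probability a owl:AnnotationProperty ;
    rdfs:comment "Occurrence probability of the adverse situation (decimal interval)." .

riox:severity a owl:AnnotationProperty .
riox:category a owl:AnnotationProperty .
riox:condition_id a owl:AnnotationProperty .
riox:operator a owl:AnnotationProperty .
riox:lhs_expression a owl:AnnotationProperty .
riox:datatype a owl:AnnotationProperty .
riox:unit a owl:AnnotationProperty .
riox:acquisition_source a owl:AnnotationProperty .
riox:index a owl:AnnotationProperty .
riox:phase_order a owl:AnnotationProperty .
riox:constant a owl:AnnotationProperty .
riox:severity_scale a owl:AnnotationProperty .
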