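# peririsk

Ontology-based specification and detection of perioperative risks.

`peririsk` is a toolkit for clinical decision support teams who maintain
catalogues of perioperative risks — medical, organizational, technical,
human, or cross-process — and want to detect them automatically in patient
data. It implements a complete pipeline:

1. **Specify** risks in a typed tabular template: treatment phases, KPIs
   (key performance indicators: typed, risk-relevant parameters such as
   `Age_in_months` or `Antibiotic_prevention`), conditions over KPI value
   ranges, and boolean risk rules with linked adverse situations
   (occurrence probability and ordinal severity).
2. **Generate** a RIO-conformant OWL ontology from the specification:
   each condition becomes a subclass of its KPI class with an equivalent
   `has_data_value` datatype restriction; each risk becomes a subclass of
   `rio:Risk` whose equivalent class is the `has_part` translation of its
   rule (AND → intersection, OR → union, NOT → complement); phases and
   adverse-situation annotations (with nested `as_probability`) complete
   the model. Generation is invertible: the detector can run from the
   ontology alone.
3. **Detect** risks in a patient KPI snapshot (a *potential risk
   situation* at a point in time of risk detection). Each rule is
   normalized to disjunctive normal form by De Morgan's laws and
   distributivity; every satisfied conjunction is reported as one
   explanation. Missing KPIs propagate as *unknown* under Kleene
   three-valued logic, giving a trichotomy: **risk** (≥ 1 rule satisfied),
   **non-risk** (all rules false), **indeterminate** (no rule true, some
   unknown — the missing KPIs are listed).
4. **Report** findings ordered by severity (ties broken by probability
   upper bound), as plain text and as a FHIR-RiskAssessment-style JSON
   document (`basis` ← input KPIs, one `prediction` per adverse outcome
   with probability interval and explanation rationale).

## The model

A risk is a *composite property* `CP = SP1 ∧ … ∧ SPn` of a treatment
situation, composed of single condition properties `SPi : KPI op range`
(e.g. `c1: Age_in_months IN [0, 5)`). A situation possessing at least one
risk is a *risk situation*; each risk links to the adverse situations it
may evolve into, with an occurrence probability interval on [0, 1] and a
severity grade on a configurable ordinal scale. A rule in DNF
`C1 ∨ C2 ∨ …` is detected satisfied when some conjunction `Ck` holds; that
conjunction — its conditions, the patient's current values, and the
specified ranges — *is* the explanation shown to clinical staff. No
description-logic reasoner is used: rules with arithmetic expressions and
named constants are evaluated natively with exact rational arithmetic.

## Worked example

The bundled fixture models the meningitis risk of cochlear implantation in
infants: an infant younger than 5 months (skull bone thickness mostly
below 2 mm), without pneumococcus/meningococcus/haemophilus vaccination
and without antibiotic prevention, has an increased risk of bacterial dura
mater infection, with an occurrence probability of 5–9%.

```sh
peririsk fixture --seed 0 --out fixtures
peririsk detect --spec fixtures/meningitis_spec \
    --record fixtures/meningitis_records.json
```

For the positive record (`Age_in_months = 3`, `Vaccination_status = "no"`,
`Antibiotic_prevention = false`) the detector prints:

```
Subject: positive
Phase: indication    Time: 2016-03-01T09:00:00
Classification: risk situation

Risk: Infection_Risk_001 [medical]
  Relevant phases: indication, preoperative
  Explanation: Age_in_months IN [0, 5) and Vaccination_status == "no" and Antibiotic_prevention == false
  Adverse situation: Meningitis (probability 0.05–0.09, severity major)
```

and exits with code 2 (risk detected; 0 = non-risk, 3 = indeterminate,
1 = usage/validation error). The explanation is the one satisfied
conjunction of the rule
`(c1 AND c4 AND c6) OR (c3 AND c5 AND c6)`; the probability interval
0.05–0.09 is the 5–9% occurrence probability of meningitis carried on the
risk's adverse-situation link. A record with `Age_in_months = 5` is a
non-risk situation — 5 lies outside the half-open interval `[0, 5)` — and
a record missing `Age_in_months` is indeterminate, naming the missing KPI.

The same specification can be compiled to OWL and used directly:

```sh
peririsk generate --spec fixtures/meningitis_spec --out rio_spec.ttl
peririsk detect --ontology rio_spec.ttl --record fixtures/meningitis_records.json
peririsk phases --spec fixtures/meningitis_spec --phase indication
```

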