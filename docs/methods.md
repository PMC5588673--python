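# Methods

## The risk model

A risk is modeled as a composite property of a treatment situation: a
boolean rule over *conditions*, each constraining one KPI (or an
arithmetic expression over KPIs and named constants) with an operator from
`{IN, ==, !=, <, <=, >, >=}` and a value range (interval with per-bound
openness, finite set, or single literal). KPIs are typed (`boolean`,
`text`, `date`, `number`) and carry measurement phases and an acquisition
source. Each risk belongs to a category (`medical`, `organizational`,
`technical`, `human`, `cross-process`), is relevant in a set of treatment
phases, and links to at least one adverse situation with an occurrence
probability interval on [0, 1] and an ordinal severity grade.

Design choices where the design was genuinely open:

- **Severity scale is data, not code.** Severity vocabularies differ
  between institutions, so the scale is a configurable ordered list,
  default `negligible < minor < moderate < major < catastrophic`. The
  meningitis fixture grades meningitis `major` — a serious, treatable
  infection — as the package's own choice.
- **Probabilities are closed intervals.** Published risk probabilities
  are often ranges ("5–9%"); point values are stored as degenerate
  intervals. Percent strings (`5–9%`, `5-9%`, `5 to 9%`, `7%`) are
  converted to decimal intervals on parse; the canonical machine form is
  the decimal interval string `0.05–0.09`.
- **Cross-process risks** carry an empty phase list and are treated as
  relevant in every phase.
- **Dates are absolute ISO-8601 calendar dates**; age-like quantities are
  number KPIs (`Age_in_months`), and derived quantities go through
  arithmetic left-hand sides, not date arithmetic.
- **Text comparison** is exact and case-sensitive after whitespace trim;
  parsing is locale-independent (decimal point only).

## The tabular template ("RIO-spec v1")

A specification is five tables — `PHASES(name, order)`,
`KPIS(name, datatype, unit, phases, source)`, `CONDITIONS(id, expression)`,
`RISKS(name, category, rule, phases, adverse_situation, probability,
severity)` (one row per adverse link), `CONSTANTS(name, datatype, value)` —
stored as an XLSX workbook or a directory of CSV/TSV files. Condition
expressions follow `<id> ':' <lhs> <op> <range>`; rules combine condition
ids with `NOT > AND > OR` precedence, n-ary after flattening. Both
grammars are small hand-written recursive-descent parsers; the writers are
exact inverses (`read(write(spec)) == spec`, and a second write is
byte-stable). Unbounded interval ends serialize as `*` (e.g. `[18, *)`).

## Ontology generation and extraction

Generation emits, per condition, a subclass of the KPI's class named
`<KPIName>_<conditionId>` with one equivalent `has_data_value`
restriction: interval and comparison ranges become OWL datatype facets
(`xsd:minInclusive`/`minExclusive`/`maxInclusive`/`maxExclusive` on
`xsd:decimal` or `xsd:date`), equalities become `owl:hasValue`,
inequalities a datatype complement of a one-element enumeration, sets a
`DataOneOf`. The full range `(-∞, ∞)` degenerates to the raw datatype.
Risk classes are subclasses of `rio:Risk` with one equivalent class built
structurally from the rule (`has_part` restrictions under
intersection/union/complement). Phase links (`risk_in_phase`,
`kpi_in_phase`) and adverse-situation links
(`risk_for_adverse_situation`, annotated with `as_probability` and
severity via OWL axiom reification) are *annotation* properties between
class IRIs — object properties would pun the classes as individuals,
which the structural profile check forbids.

Extraction inverts generation. Bounds, set members and literals are
recovered structurally from the facets; a small `operator` annotation
disambiguates representations that are semantically identical but
syntactically distinct in the source (`< 5` versus `IN [*, 5)`).
Bookkeeping annotations (declaration order, category, condition id,
arithmetic expression, constants, severity scale) make the inverse exact
up to generated class names. Arithmetic left-hand sides cannot be
expressed as OWL datatype restrictions; they ride as annotations and are
evaluated only by the detection engine. No DL reasoning is performed
anywhere — the engine implements exactly the operations the detection
problem needs.

Serialization: Turtle and RDF/XML via rdflib (blank nodes are labelled
sequentially, so Turtle output is deterministic per specification), plus a
purpose-built OWL functional-syntax writer for the generated axiom shapes.

## Detection semantics

Each rule is normalized to DNF: negation normal form by De Morgan, then
distribution of AND over OR. Contradictory conjunctions (`c ∧ ¬c`) are
dropped, duplicates removed, and subsumed conjunctions (strict supersets
of another conjunction) pruned, so every surviving conjunction is a
minimal explanation. Conjunction order follows source order. A
configurable literal bound (default 10,000) converts pathological
blow-ups into a diagnosable error; clinical rules are small.

Conditions evaluate under Kleene three-valued logic: a missing KPI yields
*unknown*; `false` dominates `unknown` dominates `true` in conjunctions;
negation maps unknown to unknown. Arithmetic left-hand sides are
evaluated with exact rational arithmetic (`Fraction`), so `(x / 3) * 3`
compares exactly equal to `x`. Values are compared as exact decimals and
calendar dates — no floating point enters any comparison.

**A deliberate semantic refinement.** Removing a contradictory
conjunction preserves two-valued equivalence but not pure Kleene
semantics: when the contradicted condition is unknown, Kleene assigns the
conjunction *unknown* while the pruned DNF yields *false*. The pruned DNF
is therefore a *sound refinement* of Kleene evaluation — it may return
false where Kleene returns unknown, precisely when no completion of the
missing KPIs could satisfy the rule (a contradictory conjunction can
never become true), and it never disagrees about true. The engine
classifies situations by evaluating the *source rule* under pure Kleene
logic, so missing data propagates exactly as written, and uses the DNF
only to enumerate explanations — pruning cannot change which conjunctions
are true. Tests assert exhaustive two-valued agreement with the oracle
and the refinement relation on three-valued states.

Classification is a trichotomy: `risk` when at least one relevant rule is
satisfied, `non-risk` when all are false, `indeterminate` otherwise (with
the missing KPIs listed). With a complete record, `indeterminate` cannot
occur. A phase filter restricts evaluation to risks relevant in that
phase; cross-process risks are always included. Treating missing data as
unknown rather than silently false is a safety choice for a clinical
alerting context: an alert suppressed by an absent value is reported as
indeterminate, not as reassurance.

## Reporting

Findings are ordered by descending maximum severity over a finding's
adverse outcomes; ties break by the descending probability upper bound
among the outcomes attaining that severity, then by risk name — full
determinism is preferred over elegance, and identical inputs produce
byte-identical reports. The JSON document follows the FHIR RiskAssessment
field vocabulary (`basis`, `prediction.outcome`,
`prediction.probabilityRange`, `prediction.rationale`) without claiming
conformance to a specific FHIR release; severity rides in an extension
entry since the named prediction fields have no slot for it. Decimals are
serialized as strings so documents round-trip exactly; a bundled JSON
schema (enforced by an internal structural validator) pins the document
shape.

## Synthetic data and what passing tests show

The generators emulate the *structure* of clinical risk specifications —
typed KPIs with a realistic datatype mix (half numeric), conditions whose
ranges actually bite (record values are drawn near condition boundaries),
rules of bounded depth/fan-out with optional negation and occasional
arithmetic, one to two adverse links per risk, and missingness injected
at a configurable rate (0.2 in the soundness suites). Defaults: 4 phases,
8 KPIs, 10 conditions, 4 risks, 10 records per specification; the
property suites run 100–500 seeded instances each, sized so the whole
suite verifies exhaustive truth tables (`2^n` for n ≤ 10, `3^n` for
n ≤ 8) in seconds.

Ground-truth labels are computed by an oracle that shares no code with
the engine: direct rank-based three-valued recursion over the AST, a
naive set-product DNF, and condition checks via plain comparisons (with
`eval` over rationals for arithmetic). Agreement is therefore evidence,
not tautology. What passing does **not** show: the generators do not
emulate correlated clinical variables, realistic missingness mechanisms,
measurement error, or the content of any institution's risk catalogue —
the synthetic suite validates the *machinery* (parsing, generation,
normalization, evaluation, reporting), not clinical validity of any
particular specification.

In the meningitis fixture, conditions c1 (`Age_in_months IN [0, 5)`), c4
(`Vaccination_status == "no"`) and c6 (`Antibiotic_prevention == false`)
follow the published example; c2 (low weight), c3 (bone thickness below
2 mm) and c5 (inner-ear malformation) are plausible reconstructions,
flagged in `MENINGITIS_RECONSTRUCTED`.

## Known limitations

- Only specified risks can be detected, and only from KPIs present in the
  record; the system cannot surface unanticipated risks.
- No probabilistic aggregation across risks, no temporal reasoning across
  successive detection points, no learning.
- The ontology is an invertible carrier of the specification, not a
  reasoning substrate: consistency checking and classification are out of
  scope by design.
- Extraction requires the bookkeeping annotations the generator emits;
  arbitrary hand-authored OWL is supported only insofar as it is
  structurally conformant.
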