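"""Severity-ordered risk reports and the RiskAssessment-style JSON form.

Detection results are carried as a :class:`RiskReport` — the situation
classification plus one :class:`RiskFinding` per recognized risk — and can
be rendered as human-readable text or as a FHIR-RiskAssessment-*style*
JSON document: input KPIs under ``basis``, one ``prediction`` per
(finding, adverse outcome) with the outcome, the probability interval and
the explanation rationale, and severity carried as an extension entry.
The document follows the RiskAssessment field vocabulary but is not
claimed conformant to a specific FHIR release; decimals are serialized as
strings so values round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources
from typing import Mapping, Optional, Sequence

from peririsk.risk_model import (
    AdverseSituationLink,
    DEFAULT_SEVERITY_SCALE,
    ScalarValue,
)

__all__ = [
    "RiskFinding",
    "RiskReport",
    "order_findings",
    "to_risk_assessment_json",
    "from_risk_assessment_json",
    "dumps_report",
    "loads_report",
    "render_text",
    "validate_document",
    "load_schema",
]

_EXT_BASE = "urn:peririsk:extension:"

CLASSIFICATIONS = ("risk", "non-risk", "indeterminate")


@dataclass(frozen=True)
class RiskFinding:
    """One recognized risk: its explanations (satisfied conjunctions),
    adverse outcomes with probability and severity, and relevant phases."""

    risk_name: str
    category: str
    explanations: tuple  # of ontoride.Explanation
    adverse_links: tuple[AdverseSituationLink, ...]
    relevant_phases: tuple[str, ...] = ()


@dataclass(frozen=True)
class RiskReport:
    """Classification of one potential risk situation with all findings,
    the input KPI map, and — when indeterminate — the missing KPIs."""

    subject_id: str
    timestamp: str
    phase: str
    classification: str
    findings: tuple[RiskFinding, ...] = ()
    kpi_values: Mapping[str, ScalarValue] = field(default_factory=dict)
    missing_kpis: tuple[str, ...] = ()


def _severity_rank(severity: str, scale: Sequence[str]) -> int:
    try:
        return list(scale).index(severity)
    except ValueError:
        return -1


def _sort_key(finding: RiskFinding, scale: Sequence[str]):
    sev = max((_severity_rank(l.severity, scale) for l in finding.adverse_links),
              default=-1)
    upper = max((l.probability[1] for l in finding.adverse_links
                 if _severity_rank(l.severity, scale) == sev),
                default=Decimal(0))
    return (-sev, -upper, finding.risk_name)


def order_findings(findings: Sequence[RiskFinding],
                   severity_scale: Sequence[str] = DEFAULT_SEVERITY_SCALE
                   ) -> list[RiskFinding]:
    """Order findings by descending maximum severity of their adverse
    outcomes; ties broken by descending probability upper bound, then by
    risk name.  A permutation: no finding is added or dropped."""
    return sorted(findings, key=lambda f: _sort_key(f, severity_scale))


# ---------------------------------------------------------------------------
# JSON document


def _value_entry(name: str, value: ScalarValue) -> dict:
    from peririsk.spec_io import format_value

    if isinstance(value, bool):
        return {"kpi": name, "datatype": "boolean", "value": value}
    if isinstance(value, Decimal):
        return {"kpi": name, "datatype": "number", "value": format_value(value)}
    if isinstance(value, str):
        return {"kpi": name, "datatype": "text", "value": value}
    return {"kpi": name, "datatype": "date", "value": value.isoformat()}


def to_risk_assessment_json(report: RiskReport) -> dict:
    """Map a report onto a RiskAssessment-style document.

    ``basis`` carries the input KPI name/value pairs; each (finding,
    adverse outcome) pair becomes one prediction with ``outcome``,
    ``probabilityRange`` (decimal strings), ``rationale`` (the rendered
    explanation sentences) and severity as an extension entry.
    """
    from peririsk.spec_io import format_number

    predictions = []
    for finding in report.findings:
        rationale = "; ".join(e.sentence for e in finding.explanations)
        explanations = [
            {
                "conjunctionIndex": e.conjunction_index,
                "sentence": e.sentence,
                "literals": [
                    {"condition": cid, "kpi": kpi, "value": value,
                     "range": rng, "positive": positive}
                    for cid, kpi, value, rng, positive in e.literals
                ],
            }
            for e in finding.explanations
        ]
        for link in finding.adverse_links:
            predictions.append({
                "outcome": {"text": link.adverse_situation},
                "probabilityRange": {
                    "low": format_number(link.probability[0]),
                    "high": format_number(link.probability[1]),
                },
                "rationale": rationale,
                "extension": [
                    {"url": _EXT_BASE + "severity", "valueString": link.severity},
                    {"url": _EXT_BASE + "risk", "valueString": finding.risk_name},
                    {"url": _EXT_BASE + "category",
                     "valueString": finding.category},
                    {"url": _EXT_BASE + "phases",
                     "valueString": ";".join(finding.relevant_phases)},
                    {"url": _EXT_BASE + "explanations",
                     "valueExplanations": explanations},
                ],
            })

    doc = {
        "resourceType": "RiskAssessment",
        "status": "final",
        "subject": {"reference": f"Patient/{report.subject_id}"},
        "occurrenceDateTime": report.timestamp,
        "extension": [
            {"url": _EXT_BASE + "classification",
             "valueString": report.classification},
            {"url": _EXT_BASE + "phase", "valueString": report.phase},
            {"url": _EXT_BASE + "missing-kpis",
             "valueString": ";".join(report.missing_kpis)},
        ],
        "basis": [_value_entry(k, v) for k, v in report.kpi_values.items()],
        "prediction": predictions,
    }
    problems = validate_document(doc)
    if problems:  # pragma: no cover - internal consistency bug
        raise ValueError("generated document violates schema: "
                         + "; ".join(problems))
    return doc


def _ext_value(extensions: list, suffix: str, key: str = "valueString"):
    for e in extensions:
        if e.get("url") == _EXT_BASE + suffix:
            return e.get(key)
    return None


def from_risk_assessment_json(doc: dict) -> RiskReport:
    """Inverse of :func:`to_risk_assessment_json`."""
    from datetime import date

    from peririsk.ontoride import Explanation

    values: dict[str, ScalarValue] = {}
    for entry in doc.get("basis", []):
        dt, raw = entry["datatype"], entry["value"]
        if dt == "number":
            values[entry["kpi"]] = Decimal(raw)
        elif dt == "date":
            values[entry["kpi"]] = date.fromisoformat(raw)
        else:
            values[entry["kpi"]] = raw

    grouped: dict[str, dict] = {}
    order: list[str] = []
    for pred in doc.get("prediction", []):
        ext = pred.get("extension", [])
        risk_name = _ext_value(ext, "risk") or ""
        link = AdverseSituationLink(
            adverse_situation=pred["outcome"]["text"],
            probability=(Decimal(pred["probabilityRange"]["low"]),
                         Decimal(pred["probabilityRange"]["high"])),
            severity=_ext_value(ext, "severity") or "",
        )
        if risk_name not in grouped:
            order.append(risk_name)
            phases_raw = _ext_value(ext, "phases") or ""
            explanations = tuple(
                Explanation(
                    risk_name=risk_name,
                    conjunction_index=e["conjunctionIndex"],
                    literals=tuple(
                        (l["condition"], l["kpi"], l["value"], l["range"],
                         l["positive"])
                        for l in e["literals"]),
                    sentence=e["sentence"],
                )
                for e in (_ext_value(ext, "explanations",
                                     "valueExplanations") or []))
            grouped[risk_name] = {
                "category": _ext_value(ext, "category") or "",
                "phases": tuple(p for p in phases_raw.split(";") if p),
                "explanations": explanations,
                "links": [link],
            }
        else:
            grouped[risk_name]["links"].append(link)

    findings = tuple(
        RiskFinding(
            risk_name=name,
            category=grouped[name]["category"],
            explanations=grouped[name]["explanations"],
            adverse_links=tuple(grouped[name]["links"]),
            relevant_phases=grouped[name]["phases"],
        )
        for name in order)

    ext = doc.get("extension", [])
    missing_raw = _ext_value(ext, "missing-kpis") or ""
    subject = doc.get("subject", {}).get("reference", "")
    return RiskReport(
        subject_id=subject.removeprefix("Patient/"),
        timestamp=doc.get("occurrenceDateTime", ""),
        phase=_ext_value(ext, "phase") or "",
        classification=_ext_value(ext, "classification") or "",
        findings=findings,
        kpi_values=values,
        missing_kpis=tuple(m for m in missing_raw.split(";") if m),
    )


def dumps_report(report: RiskReport) -> str:
    """UTF-8 JSON text with stable key order (insertion order)."""
    return json.dumps(to_risk_assessment_json(report), indent=2,
                      ensure_ascii=False) + "\n"


def loads_report(text: str) -> RiskReport:
    return from_risk_assessment_json(json.loads(text))


# ---------------------------------------------------------------------------
# plain-text rendering


def render_text(report: RiskReport) -> str:
    """Human-readable summary: one block per finding with the risk name,
    phases, explanation sentences, and adverse outcomes with probability
    and severity."""
    from peririsk.spec_io import format_probability_decimal

    lines = [
        f"Subject: {report.subject_id}",
        f"Phase: {report.phase}    Time: {report.timestamp}",
        f"Classification: {report.classification} situation",
    ]
    if report.missing_kpis:
        lines.append("Missing KPIs: " + ", ".join(report.missing_kpis))
    for finding in report.findings:
        lines.append("")
        lines.append(f"Risk: {finding.risk_name} [{finding.category}]")
        if finding.relevant_phases:
            lines.append("  Relevant phases: " + ", ".join(finding.relevant_phases))
        for e in finding.explanations:
            lines.append(f"  Explanation: {e.sentence}")
        for link in finding.adverse_links:
            lines.append(
                f"  Adverse situation: {link.adverse_situation} "
                f"(probability {format_probability_decimal(link.probability)}, "
                f"severity {link.severity})")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# schema validation (structural subset of JSON Schema)


def load_schema() -> dict:
    """The bundled RiskAssessment-style document schema."""
    text = resources.files("peririsk").joinpath(
        "schemas/risk_assessment.schema.json").read_text(encoding="utf-8")
    return json.loads(text)


def _check(instance, schema: dict, path: str, out: list[str]) -> None:
    t = schema.get("type")
    if t:
        ok = {
            "object": lambda v: isinstance(v, dict),
            "array": lambda v: isinstance(v, list),
            "string": lambda v: isinstance(v, str),
            "boolean": lambda v: isinstance(v, bool),
            "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
        }[t](instance)
        if not ok:
            out.append(f"{path}: expected {t}, got {type(instance).__name__}")
            return
    if "enum" in schema and instance not in schema["enum"]:
        out.append(f"{path}: {instance!r} not in {schema['enum']}")
    if "const" in schema and instance != schema["const"]:
        out.append(f"{path}: expected {schema['const']!r}")
    if "pattern" in schema and isinstance(instance, str):
        import re

        if not re.fullmatch(schema["pattern"], instance):
            out.append(f"{path}: {instance!r} does not match {schema['pattern']!r}")
    if t == "object":
        for req in schema.get("required", []):
            if req not in instance:
                out.append(f"{path}: missing required property {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}", out)
    if t == "array" and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{path}[{i}]", out)


def validate_document(doc: dict, schema: Optional[dict] = None) -> list[str]:
    """Validate a document against the bundled schema; returns a list of
    problems (empty when valid).  Covers the subset of JSON Schema the
    bundled schema uses: type, required, properties, items, enum, const,
    pattern."""
    problems: list[str] = []
    _check(doc, schema or load_schema(), "$", problems)
    return problems
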