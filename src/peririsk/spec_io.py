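"""Reading and writing the tabular risk-specification template.

The canonical machine layout — the "RIO-spec v1" template — is five named
tables: PHASES(name, order), KPIS(name, datatype, unit, phases, source),
CONDITIONS(id, expression), RISKS(name, category, rule, phases,
adverse_situation, probability, severity) and CONSTANTS(name, datatype,
value).  A specification is stored either as an XLSX workbook with those
five sheets or as a directory of CSV/TSV files named after them.  RISKS has
one row per (risk, adverse-situation) link; rows of the same risk repeat
the category, rule and phases columns verbatim.

Condition expressions follow the grammar ``<id> ':' <lhs> <op> <range>``
(e.g. ``c1: Age_in_months IN [0, 5)``); rule expressions combine condition
ids with NOT/AND/OR, with precedence NOT > AND > OR.  Parsing is
locale-independent: decimal point only, dates ISO 8601 only; text
comparison is exact and case-sensitive after whitespace trim.
"""

from __future__ import annotations

import csv
import io
import json
import re
from datetime import date
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from peririsk.risk_model import (
    DATATYPES,
    DEFAULT_SEVERITY_SCALE,
    AdverseSituationLink,
    And,
    CondRef,
    Condition,
    Diagnostic,
    KPIDefinition,
    KPIRecord,
    Not,
    Or,
    RiskDefinition,
    RiskSpecification,
    RuleExpression,
    ScalarValue,
    ValueRange,
    validate_spec,
)

__all__ = [
    "ExprSyntaxError",
    "SpecLayoutError",
    "SpecValidationError",
    "parse_condition_expr",
    "parse_rule_expr",
    "format_condition",
    "format_rule",
    "format_number",
    "format_value",
    "parse_probability",
    "format_probability",
    "read_spec",
    "write_spec",
    "read_records",
    "write_records",
]

SHEETS = ("PHASES", "KPIS", "CONDITIONS", "RISKS", "CONSTANTS")

HEADERS = {
    "PHASES": ["name", "order"],
    "KPIS": ["name", "datatype", "unit", "phases", "source"],
    "CONDITIONS": ["id", "expression"],
    "RISKS": ["name", "category", "rule", "phases",
              "adverse_situation", "probability", "severity"],
    "CONSTANTS": ["name", "datatype", "value"],
}


class ExprSyntaxError(ValueError):
    """Syntax error in a condition or rule expression, with column offset."""

    def __init__(self, message: str, text: str, column: int):
        super().__init__(f"{message} (column {column}): {text!r}")
        self.column = column
        self.text = text


class SpecLayoutError(ValueError):
    """Structural error in a specification file, naming sheet and row."""


class SpecValidationError(ValueError):
    """A parsed specification violated model invariants."""

    def __init__(self, diagnostics: Sequence[Diagnostic]):
        super().__init__(
            "; ".join(str(d) for d in diagnostics) or "invalid specification")
        self.diagnostics = list(diagnostics)


# ---------------------------------------------------------------------------
# tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>\d+(?:\.\d+)?)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op><=|>=|==|!=|<|>)
  | (?P<punct>[:\[\](){},*+\-/])
    """,
    re.VERBOSE,
)

_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


class _Token:
    __slots__ = ("kind", "value", "pos")

    def __init__(self, kind: str, value: str, pos: int):
        self.kind = kind
        self.value = value
        self.pos = pos


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ExprSyntaxError("unexpected character", text, pos)
        kind = m.lastgroup or ""
        if kind != "ws":
            tokens.append(_Token(kind, m.group(), pos))
        pos = m.end()
    tokens.append(_Token("eof", "", len(text)))
    return tokens


class _Cursor:
    def __init__(self, tokens: list[_Token], text: str):
        self.tokens = tokens
        self.text = text
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str, value: Optional[str] = None) -> _Token:
        tok = self.cur
        if tok.kind != kind or (value is not None and tok.value != value):
            want = value or kind
            raise ExprSyntaxError(f"expected {want!r}", self.text, tok.pos)
        return self.advance()

    def fail(self, message: str) -> ExprSyntaxError:
        return ExprSyntaxError(message, self.text, self.cur.pos)


# ---------------------------------------------------------------------------
# condition expressions


def _unescape(raw: str) -> str:
    return raw[1:-1].replace('\\"', '"').replace("\\\\", "\\")


def _escape(value: str) -> str:
    return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _parse_literal(cur: _Cursor, datatype: str, *,
                   bool_yes_no: bool = False) -> ScalarValue:
    tok = cur.cur
    if datatype == "number":
        sign = ""
        if tok.kind == "punct" and tok.value == "-":
            sign = "-"
            cur.advance()
            tok = cur.cur
        if tok.kind != "number":
            raise cur.fail("expected a number literal")
        cur.advance()
        return Decimal(sign + tok.value)
    if datatype == "date":
        if tok.kind == "string" and _DATE_RE.match(_unescape(tok.value)):
            cur.advance()
            return date.fromisoformat(_unescape(tok.value))
        # bare ISO date: three number/punct tokens 2015 - 06 - 01
        m = _DATE_RE.match(cur.text[tok.pos:tok.pos + 10])
        if m:
            text = cur.text
            end = tok.pos + 10
            while cur.cur.pos < end and cur.cur.kind != "eof":
                cur.advance()
            return date.fromisoformat(text[tok.pos:end])
        raise cur.fail("expected an ISO 8601 date")
    if datatype == "boolean":
        if tok.kind == "name" and tok.value.lower() in ("true", "false"):
            cur.advance()
            return tok.value.lower() == "true"
        if bool_yes_no and tok.kind == "string" and _unescape(tok.value) in ("yes", "no"):
            cur.advance()
            return _unescape(tok.value) == "yes"
        raise cur.fail("expected a boolean literal (true/false)")
    if datatype == "text":
        if tok.kind != "string":
            raise cur.fail("expected a quoted string literal")
        cur.advance()
        return _unescape(tok.value)
    raise cur.fail(f"unsupported datatype {datatype!r}")


def _parse_bound(cur: _Cursor, datatype: str):
    if cur.cur.kind == "punct" and cur.cur.value == "*":
        cur.advance()
        return None
    if cur.cur.kind == "punct" and cur.cur.value == "-":
        # allow "-*" for minus infinity
        nxt = cur.tokens[cur.i + 1]
        if nxt.kind == "punct" and nxt.value == "*":
            cur.advance()
            cur.advance()
            return None
    return _parse_literal(cur, datatype)


def _parse_range(cur: _Cursor, operator: str, datatype: str, *,
                 bool_yes_no: bool = False) -> ValueRange:
    tok = cur.cur
    if operator == "IN":
        if tok.kind == "punct" and tok.value in "[(":
            if datatype not in ("number", "date"):
                raise cur.fail(f"interval range over {datatype} KPI")
            lower_closed = tok.value == "["
            cur.advance()
            lower = _parse_bound(cur, datatype)
            cur.expect("punct", ",")
            upper = _parse_bound(cur, datatype)
            close = cur.cur
            if close.kind != "punct" or close.value not in ")]":
                raise cur.fail("expected ')' or ']'")
            cur.advance()
            return ValueRange(
                kind="interval", lower=lower, upper=upper,
                lower_closed=lower_closed, upper_closed=close.value == "]")
        if tok.kind == "punct" and tok.value == "{":
            cur.advance()
            members = [_parse_literal(cur, datatype, bool_yes_no=bool_yes_no)]
            while cur.cur.kind == "punct" and cur.cur.value == ",":
                cur.advance()
                members.append(_parse_literal(cur, datatype, bool_yes_no=bool_yes_no))
            cur.expect("punct", "}")
            return ValueRange(kind="set", members=tuple(members))
        raise cur.fail("IN requires an interval or a {...} set")
    return ValueRange(
        kind="literal",
        literal=_parse_literal(cur, datatype, bool_yes_no=bool_yes_no))


_ARITH_OPS = set("+-*/")


def _parse_lhs(cur: _Cursor, kpis: Mapping[str, str],
               constants: Mapping[str, ScalarValue]) -> tuple[str, Optional[str]]:
    """Parse the left-hand side: a bare KPI name, or an arithmetic
    expression over KPI/constant names; returns (kpi, lhs_expression)."""
    start = cur.cur.pos
    depth = 0
    names: list[str] = []
    arithmetic = False
    last_end = start
    while True:
        tok = cur.cur
        if tok.kind == "eof":
            break
        if tok.kind == "op":
            break
        if tok.kind == "name":
            if tok.value in ("IN",):
                break
            names.append(tok.value)
        elif tok.kind == "number":
            arithmetic = True
        elif tok.kind == "punct" and tok.value in "()":
            if tok.value == "(":
                depth += 1
            else:
                if depth == 0:
                    break
                depth -= 1
            arithmetic = True
        elif tok.kind == "punct" and tok.value in _ARITH_OPS:
            arithmetic = True
        else:
            raise cur.fail("unexpected token in left-hand side")
        last_end = tok.pos + len(tok.value)
        cur.advance()
    if not names:
        raise cur.fail("left-hand side references no KPI")
    for n in names:
        if n not in kpis and n not in constants:
            raise ExprSyntaxError(f"unknown KPI or constant {n!r}", cur.text, start)
    primary = next((n for n in names if n in kpis), names[0])
    if not arithmetic and len(names) == 1 and names[0] in kpis:
        return names[0], None
    expr = re.sub(r"\s+", " ", cur.text[start:last_end].strip())
    return primary, expr


def parse_condition_expr(text: str, kpis: Mapping[str, str],
                         constants: Optional[Mapping[str, ScalarValue]] = None,
                         *, bool_yes_no: bool = False) -> Condition:
    """Parse ``<id> ':' <lhs> <op> <range>`` into a :class:`Condition`.

    Parameters
    ----------
    text:
        The condition string, e.g. ``c1: Age_in_months IN [0, 5)``.
    kpis:
        Mapping of declared KPI name to its datatype.
    constants:
        Mapping of declared constant names to typed values; names usable in
        arithmetic left-hand sides.
    bool_yes_no:
        When true, ``"yes"``/``"no"`` literals are accepted for boolean
        KPIs and mapped to true/false.
    """
    constants = constants or {}
    cur = _Cursor(_tokenize(text), text)
    ident = cur.expect("name")
    cur.expect("punct", ":")
    kpi, lhs_expr = _parse_lhs(cur, kpis, constants)
    tok = cur.cur
    if tok.kind == "name" and tok.value == "IN":
        operator = "IN"
        cur.advance()
    elif tok.kind == "op":
        operator = tok.value
        cur.advance()
    else:
        raise cur.fail("expected an operator (IN, ==, !=, <, <=, >, >=)")
    datatype = "number" if lhs_expr is not None else kpis[kpi]
    rng = _parse_range(cur, operator, datatype, bool_yes_no=bool_yes_no)
    if cur.cur.kind != "eof":
        raise cur.fail("trailing input after condition")
    return Condition(id=ident.value, kpi=kpi, operator=operator,
                     range=rng, lhs_expression=lhs_expr)


# ---------------------------------------------------------------------------
# rule expressions


def parse_rule_expr(text: str,
                    condition_ids: Optional[Sequence[str]] = None) -> RuleExpression:
    """Parse a boolean rule over condition ids into an AST.

    Precedence NOT > AND > OR; AND/OR are left-associative and flattened to
    n-ary nodes, preserving source order of children.  When
    ``condition_ids`` is given, unknown ids raise :class:`ExprSyntaxError`.
    """
    known = set(condition_ids) if condition_ids is not None else None
    cur = _Cursor(_tokenize(text), text)

    def parse_or() -> RuleExpression:
        children = [parse_and()]
        while cur.cur.kind == "name" and cur.cur.value == "OR":
            cur.advance()
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        flat: list[RuleExpression] = []
        for c in children:
            flat.extend(c.children if isinstance(c, Or) else (c,))
        return Or(tuple(flat))

    def parse_and() -> RuleExpression:
        children = [parse_unary()]
        while cur.cur.kind == "name" and cur.cur.value == "AND":
            cur.advance()
            children.append(parse_unary())
        if len(children) == 1:
            return children[0]
        flat: list[RuleExpression] = []
        for c in children:
            flat.extend(c.children if isinstance(c, And) else (c,))
        return And(tuple(flat))

    def parse_unary() -> RuleExpression:
        tok = cur.cur
        if tok.kind == "name" and tok.value == "NOT":
            cur.advance()
            return Not(parse_unary())
        if tok.kind == "punct" and tok.value == "(":
            cur.advance()
            inner = parse_or()
            cur.expect("punct", ")")
            return inner
        if tok.kind == "name":
            if tok.value in ("AND", "OR", "NOT"):
                raise cur.fail("expected a condition id")
            if known is not None and tok.value not in known:
                raise cur.fail(f"unknown condition id {tok.value!r}")
            cur.advance()
            return CondRef(tok.value)
        raise cur.fail("expected a condition id, NOT, or '('")

    root = parse_or()
    if cur.cur.kind != "eof":
        raise cur.fail("trailing input after rule")
    return root


# ---------------------------------------------------------------------------
# printers (exact inverses of the parsers)


def format_number(value: Decimal) -> str:
    """Plain decimal rendering, no exponent (``0.05`` not ``5E-2``)."""
    return format(value, "f")


def format_value(value: ScalarValue) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, Decimal):
        return format_number(value)
    if isinstance(value, date):
        return value.isoformat()
    return _escape(value)


def _format_bound(value, closed_char: str) -> str:
    return "*" if value is None else format_value(value)


def format_range(operator: str, rng: ValueRange) -> str:
    if rng.kind == "interval":
        lo = "*" if rng.lower is None else format_value(rng.lower)
        hi = "*" if rng.upper is None else format_value(rng.upper)
        return "%s%s, %s%s" % ("[" if rng.lower_closed else "(", lo, hi,
                               "]" if rng.upper_closed else ")")
    if rng.kind == "set":
        return "{" + ", ".join(format_value(m) for m in rng.members) + "}"
    return format_value(rng.literal)


def format_condition(cond: Condition, *, with_id: bool = True) -> str:
    """Render a condition back to its source form, e.g.
    ``c1: Age_in_months IN [0, 5)``."""
    lhs = cond.lhs_expression if cond.lhs_expression is not None else cond.kpi
    body = f"{lhs} {cond.operator} {format_range(cond.operator, cond.range)}"
    return f"{cond.id}: {body}" if with_id else body


def format_rule(rule: RuleExpression) -> str:
    """Render a rule AST back to its source form with minimal parentheses."""

    def render(node: RuleExpression, parent: str) -> str:
        if isinstance(node, CondRef):
            return node.id
        if isinstance(node, Not):
            inner = render(node.child, "NOT")
            if isinstance(node.child, (And, Or)):
                inner = f"({inner})"
            return f"NOT {inner}"
        if isinstance(node, And):
            parts = []
            for c in node.children:
                s = render(c, "AND")
                if isinstance(c, Or):
                    s = f"({s})"
                parts.append(s)
            text = " AND ".join(parts)
            return text
        if isinstance(node, Or):
            text = " OR ".join(render(c, "OR") for c in node.children)
            if parent in ("AND", "NOT"):
                return text  # caller adds parentheses
            return text
        raise TypeError(f"unknown rule node {type(node).__name__}")

    return render(rule, "")


# ---------------------------------------------------------------------------
# probabilities

_PERCENT_RE = re.compile(
    r"^\s*(?P<lo>\d+(?:\.\d+)?)\s*%?\s*(?:(?:–|-|—|\bto\b)\s*(?P<hi>\d+(?:\.\d+)?)\s*)?%\s*$")


def parse_probability(text: str) -> tuple[Decimal, Decimal]:
    """Parse ``"5–9%"``, ``"5-9%"``, ``"5 to 9%"`` or ``"7%"`` into a
    closed probability interval on [0, 1]."""
    m = _PERCENT_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse probability {text!r}")
    lo = Decimal(m.group("lo")) / 100
    hi = Decimal(m.group("hi")) / 100 if m.group("hi") else lo
    return lo, hi


def _percent(value: Decimal) -> str:
    return format((value * 100).normalize(), "f")


def format_probability(prob: tuple[Decimal, Decimal]) -> str:
    """Canonical percent rendering: ``5–9%`` (en dash) or ``7%``."""
    lo, hi = prob
    if lo == hi:
        return f"{_percent(lo)}%"
    return f"{_percent(lo)}–{_percent(hi)}%"


def format_probability_decimal(prob: tuple[Decimal, Decimal]) -> str:
    """Canonical decimal-interval rendering used in ontology annotations
    and reports: ``0.05–0.09`` or ``0.07``."""
    lo, hi = prob
    if lo == hi:
        return format_number(lo)
    return f"{format_number(lo)}–{format_number(hi)}"


def parse_probability_decimal(text: str) -> tuple[Decimal, Decimal]:
    parts = text.split("–")
    if len(parts) == 1:
        v = Decimal(parts[0])
        return v, v
    return Decimal(parts[0]), Decimal(parts[1])


# ---------------------------------------------------------------------------
# tabular I/O

_FORMATS = ("csv", "tsv", "xlsx")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    if path.suffix.lower() == ".xlsx":
        return "xlsx"
    if path.is_dir():
        if any(path.glob("*.tsv")):
            return "tsv"
        return "csv"
    return "csv"


def _read_tables(path: Path, fmt: str) -> dict[str, list[list[str]]]:
    tables: dict[str, list[list[str]]] = {}
    if fmt == "xlsx":
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True)
        for name in SHEETS:
            if name in wb.sheetnames:
                rows = []
                for row in wb[name].iter_rows(values_only=True):
                    rows.append(["" if v is None else str(v) for v in row])
                tables[name] = rows
        wb.close()
    else:
        delim = "\t" if fmt == "tsv" else ","
        ext = ".tsv" if fmt == "tsv" else ".csv"
        if not path.is_dir():
            raise SpecLayoutError(
                f"{path}: {fmt} specifications are directories of sheet files")
        for name in SHEETS:
            f = path / f"{name}{ext}"
            if f.exists():
                with open(f, newline="", encoding="utf-8") as fh:
                    tables[name] = [list(r) for r in csv.reader(fh, delimiter=delim)]
    return tables


def _check_header(sheet: str, rows: list[list[str]]) -> list[list[str]]:
    if not rows or [c.strip() for c in rows[0]] != HEADERS[sheet]:
        raise SpecLayoutError(
            f"sheet {sheet}: expected header {HEADERS[sheet]}, "
            f"got {rows[0] if rows else 'nothing'}")
    return [r for r in rows[1:] if any(c.strip() for c in r)]


def _cell(row: list[str], idx: int) -> str:
    return row[idx].strip() if idx < len(row) else ""


def parse_constant_value(datatype: str, raw: str) -> ScalarValue:
    if datatype == "number":
        return Decimal(raw)
    if datatype == "date":
        return date.fromisoformat(raw)
    if datatype == "boolean":
        if raw.lower() not in ("true", "false"):
            raise ValueError(f"not a boolean: {raw!r}")
        return raw.lower() == "true"
    if datatype == "text":
        return raw
    raise ValueError(f"unknown datatype {datatype!r}")


def read_spec(path: Union[str, Path], fmt: Optional[str] = None, *,
              severity_scale: Sequence[str] = DEFAULT_SEVERITY_SCALE,
              bool_yes_no: bool = False) -> RiskSpecification:
    """Read a risk specification from an XLSX workbook or a CSV/TSV sheet
    directory; percent probability strings are converted to decimal
    intervals.  Any validation diagnostic of severity ``error`` is promoted
    to :class:`SpecValidationError`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    tables = _read_tables(path, fmt)
    if "PHASES" not in tables:
        raise SpecLayoutError(f"{path}: missing PHASES sheet")
    if "KPIS" not in tables:
        raise SpecLayoutError(f"{path}: missing KPIS sheet")

    phase_rows = _check_header("PHASES", tables["PHASES"])
    try:
        phase_rows.sort(key=lambda r: int(_cell(r, 1)))
    except ValueError as exc:
        raise SpecLayoutError(f"sheet PHASES: non-integer order column: {exc}")
    phases = tuple(_cell(r, 0) for r in phase_rows)

    kpis = []
    for i, row in enumerate(_check_header("KPIS", tables["KPIS"]), start=2):
        phases_cell = _cell(row, 3)
        kpis.append(KPIDefinition(
            name=_cell(row, 0),
            datatype=_cell(row, 1),
            unit=_cell(row, 2),
            measurement_phases=tuple(
                p.strip() for p in phases_cell.split(";") if p.strip()),
            acquisition_source=_cell(row, 4),
        ))
    kpi_types = {k.name: k.datatype for k in kpis}

    constants: dict[str, ScalarValue] = {}
    if "CONSTANTS" in tables:
        for i, row in enumerate(_check_header("CONSTANTS", tables["CONSTANTS"]),
                                start=2):
            try:
                constants[_cell(row, 0)] = parse_constant_value(
                    _cell(row, 1), _cell(row, 2))
            except (ValueError, InvalidOperation) as exc:
                raise SpecLayoutError(f"sheet CONSTANTS row {i}: {exc}")

    conditions = []
    if "CONDITIONS" in tables:
        for i, row in enumerate(_check_header("CONDITIONS", tables["CONDITIONS"]),
                                start=2):
            text = f"{_cell(row, 0)}: {_cell(row, 1)}"
            try:
                conditions.append(parse_condition_expr(
                    text, kpi_types, constants, bool_yes_no=bool_yes_no))
            except ExprSyntaxError as exc:
                raise SpecLayoutError(f"sheet CONDITIONS row {i}: {exc}")

    risks: list[RiskDefinition] = []
    if "RISKS" in tables:
        cond_ids = [c.id for c in conditions]
        grouped: dict[str, dict] = {}
        order: list[str] = []
        for i, row in enumerate(_check_header("RISKS", tables["RISKS"]), start=2):
            name = _cell(row, 0)
            try:
                link = AdverseSituationLink(
                    adverse_situation=_cell(row, 4),
                    probability=parse_probability(_cell(row, 5)),
                    severity=_cell(row, 6),
                )
            except ValueError as exc:
                raise SpecLayoutError(f"sheet RISKS row {i}: {exc}")
            fields = (_cell(row, 1), _cell(row, 2), _cell(row, 3))
            if name not in grouped:
                order.append(name)
                grouped[name] = {"fields": fields, "links": [link], "row": i}
            else:
                if grouped[name]["fields"] != fields:
                    raise SpecLayoutError(
                        f"sheet RISKS row {i}: rows of risk {name!r} disagree "
                        "on category/rule/phases")
                grouped[name]["links"].append(link)
        for name in order:
            category, rule_text, phases_cell = grouped[name]["fields"]
            try:
                rule = parse_rule_expr(rule_text, cond_ids)
            except ExprSyntaxError as exc:
                raise SpecLayoutError(
                    f"sheet RISKS row {grouped[name]['row']}: {exc}")
            risks.append(RiskDefinition(
                name=name,
                category=category,
                rule=rule,
                relevant_phases=tuple(
                    p.strip() for p in phases_cell.split(";") if p.strip()),
                adverse_links=tuple(grouped[name]["links"]),
            ))

    spec = RiskSpecification(
        phases=phases, kpis=tuple(kpis), conditions=tuple(conditions),
        risks=tuple(risks), constants=constants,
        severity_scale=tuple(severity_scale))
    errors = [d for d in validate_spec(spec) if d.severity == "error"]
    if errors:
        raise SpecValidationError(errors)
    return spec


def _spec_tables(spec: RiskSpecification) -> dict[str, list[list[str]]]:
    tables: dict[str, list[list[str]]] = {}
    tables["PHASES"] = [HEADERS["PHASES"]] + [
        [p, str(i)] for i, p in enumerate(spec.phases, start=1)]
    tables["KPIS"] = [HEADERS["KPIS"]] + [
        [k.name, k.datatype, k.unit, ";".join(k.measurement_phases),
         k.acquisition_source]
        for k in spec.kpis]
    tables["CONDITIONS"] = [HEADERS["CONDITIONS"]] + [
        [c.id, format_condition(c, with_id=False)] for c in spec.conditions]
    risk_rows = []
    for r in spec.risks:
        for link in r.adverse_links:
            risk_rows.append([
                r.name, r.category, format_rule(r.rule),
                ";".join(r.relevant_phases), link.adverse_situation,
                format_probability(link.probability), link.severity])
    tables["RISKS"] = [HEADERS["RISKS"]] + risk_rows
    tables["CONSTANTS"] = [HEADERS["CONSTANTS"]] + [
        [name,
         "boolean" if isinstance(v, bool) else
         "number" if isinstance(v, Decimal) else
         "date" if isinstance(v, date) else "text",
         format_value(v) if isinstance(v, bool) or not isinstance(v, str) else v]
        for name, v in spec.constants.items()]
    return tables


def write_spec(spec: RiskSpecification, path: Union[str, Path],
               fmt: Optional[str] = None) -> Path:
    """Write a specification so that :func:`read_spec` inverts it exactly.

    For ``csv``/``tsv`` the path is a directory receiving one file per
    sheet; for ``xlsx`` a single workbook."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    tables = _spec_tables(spec)
    if fmt == "xlsx":
        import openpyxl

        wb = openpyxl.Workbook()
        wb.remove(wb.active)
        for name in SHEETS:
            ws = wb.create_sheet(name)
            for row in tables[name]:
                ws.append(row)
        path.parent.mkdir(parents=True, exist_ok=True)
        wb.save(path)
    else:
        delim = "\t" if fmt == "tsv" else ","
        ext = ".tsv" if fmt == "tsv" else ".csv"
        path.mkdir(parents=True, exist_ok=True)
        for name in SHEETS:
            with open(path / f"{name}{ext}", "w", newline="",
                      encoding="utf-8") as fh:
                csv.writer(fh, delimiter=delim, lineterminator="\n").writerows(
                    tables[name])
    return path


# ---------------------------------------------------------------------------
# patient KPI records (JSON)


def _record_value_to_json(value: ScalarValue):
    if isinstance(value, bool):
        return value
    if isinstance(value, Decimal):
        return format_number(value)
    if isinstance(value, date):
        return value.isoformat()
    return value


def _record_value_from_json(datatype: str, raw) -> ScalarValue:
    if datatype == "boolean":
        if isinstance(raw, bool):
            return raw
        raise ValueError(f"expected JSON boolean, got {raw!r}")
    if datatype == "number":
        return Decimal(str(raw))
    if datatype == "date":
        return date.fromisoformat(str(raw))
    return str(raw)


def records_to_json(records: Sequence[KPIRecord]) -> list[dict]:
    return [
        {
            "subject_id": r.subject_id,
            "phase": r.phase,
            "timestamp": r.timestamp,
            "values": {k: _record_value_to_json(v) for k, v in r.values.items()},
        }
        for r in records
    ]


def records_from_json(data, spec: RiskSpecification) -> list[KPIRecord]:
    kpi_types = {k.name: k.datatype for k in spec.kpis}
    if isinstance(data, dict):
        data = [data]
    out = []
    for i, obj in enumerate(data):
        values = {}
        for name, raw in obj.get("values", {}).items():
            if name not in kpi_types:
                raise ValueError(f"record {i}: undeclared KPI {name!r}")
            values[name] = _record_value_from_json(kpi_types[name], raw)
        out.append(KPIRecord(
            subject_id=str(obj.get("subject_id", "")),
            phase=str(obj.get("phase", "")),
            timestamp=str(obj.get("timestamp", "")),
            values=values,
        ))
    return out


def read_records(path: Union[str, Path], spec: RiskSpecification) -> list[KPIRecord]:
    """Read patient KPI snapshot records from a JSON file (one object or a
    list), typing each value against the KPI's declared datatype."""
    with open(path, encoding="utf-8") as fh:
        return records_from_json(json.load(fh), spec)


def write_records(records: Sequence[KPIRecord], path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records_to_json(records), fh, indent=2, ensure_ascii=False)
        fh.write("\n")
    return path
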