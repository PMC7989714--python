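"""Specification worksheets: the declarative model driving all recoding.

Two CSV worksheets describe a harmonization project:

``variables.csv``
    one row per harmonized variable — its name, labels, subject,
    section, type and units.

``variable_details.csv``
    one row per recode rule — which survey cycles it applies to, the
    cycle-specific raw column names, the source value or interval it
    matches, and the harmonized target (a category code, ``copy``, a
    tagged-missing token, or a ``Func::`` tag naming a derived-variable
    function).

Worksheet dialect
-----------------
* UTF-8, comma-delimited, RFC-4180 quoting.
* ``databaseStart``: comma-separated cycle identifiers inside one cell.
* ``variableStart``: comma-separated ``cycle::RAWNAME`` entries plus one
  bracketed default ``[RAWNAME]``; a derived-variable row instead uses
  ``DerivedVar::[input1, input2, ...]`` listing its harmonized inputs.
* ``recStart``: a bare category code (``2``), a closed interval
  (``[1,15]``), the keyword ``else`` (catch-all), or ``NA`` (matches an
  empty source cell).
* ``recEnd``: a category code, ``copy`` (pass the source value through),
  ``NA::a`` / ``NA::b`` (tagged missing), or ``Func::<name>``.

A specific rule always wins over ``else``; ``else`` applies only to
values matched by no other rule, so rule order never matters.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .missing import TaggedMissing

VARIABLES_HEADER = [
    "variable", "label", "labelLong", "subject", "section",
    "variableType", "units", "notes",
]
DETAILS_HEADER = [
    "variable", "typeEnd", "typeStart", "databaseStart", "variableStart",
    "recEnd", "recStart", "catLabel", "catLabelLong", "units", "notes",
]

#: The ten public-use cycles of the demonstration worksheet set,
#: 2001 through 2014 (releases alternate 2-year and 1-year spans).
DEMO_CYCLES: Tuple[str, ...] = (
    "cchs2001_p", "cchs2003_p", "cchs2005_p", "cchs2007_2008_p",
    "cchs2009_2010_p", "cchs2010_p", "cchs2011_2012_p", "cchs2012_p",
    "cchs2013_2014_p", "cchs2014_p",
)


class WorksheetError(ValueError):
    """Schema or validation failure while reading a worksheet."""


# ---------------------------------------------------------------------------
# value model


def _format_number(x: float) -> str:
    if isinstance(x, float) and x.is_integer():
        return str(int(x))
    return repr(x)


_INTERVAL_RE = re.compile(
    r"^\[\s*([+-]?\d+(?:\.\d+)?)\s*,\s*([+-]?\d+(?:\.\d+)?)\s*\]$"
)
_NUMBER_RE = re.compile(r"^[+-]?\d+(?:\.\d+)?$")


@dataclass(frozen=True)
class SourceSpec:
    """Parsed ``recStart``: what raw values a rule matches."""

    kind: str  # "code" | "interval" | "else" | "na"
    code: Optional[float] = None
    lo: Optional[float] = None
    hi: Optional[float] = None

    @classmethod
    def parse(cls, text: str) -> "SourceSpec":
        text = text.strip()
        if text == "else":
            return cls("else")
        if text == "NA":
            return cls("na")
        m = _INTERVAL_RE.match(text)
        if m:
            lo, hi = float(m.group(1)), float(m.group(2))
            if lo > hi:
                raise WorksheetError(f"interval bounds reversed: {text!r}")
            return cls("interval", lo=lo, hi=hi)
        if _NUMBER_RE.match(text):
            return cls("code", code=float(text))
        raise WorksheetError(f"cannot parse recStart: {text!r}")

    def serialize(self) -> str:
        if self.kind == "else":
            return "else"
        if self.kind == "na":
            return "NA"
        if self.kind == "code":
            return _format_number(self.code)
        return f"[{_format_number(self.lo)},{_format_number(self.hi)}]"

    def matches(self, value: float) -> bool:
        """Whether a (finite or NaN) raw value matches this source spec.

        ``else`` matches anything; NaN matches only ``na`` and ``else``.
        """
        if self.kind == "else":
            return True
        isnan = isinstance(value, float) and math.isnan(value)
        if self.kind == "na":
            return isnan
        if isnan:
            return False
        if self.kind == "code":
            return math.isclose(value, self.code, rel_tol=0.0, abs_tol=1e-9)
        return self.lo - 1e-9 <= value <= self.hi + 1e-9

    def overlaps(self, other: "SourceSpec") -> bool:
        """Whether two non-else specs can match a common value."""
        if "else" in (self.kind, other.kind):
            return False
        if self.kind == "na" or other.kind == "na":
            return self.kind == other.kind
        a_lo = self.code if self.kind == "code" else self.lo
        a_hi = self.code if self.kind == "code" else self.hi
        b_lo = other.code if other.kind == "code" else other.lo
        b_hi = other.code if other.kind == "code" else other.hi
        return a_lo <= b_hi + 1e-9 and b_lo <= a_hi + 1e-9


@dataclass(frozen=True)
class TargetSpec:
    """Parsed ``recEnd``: what a matching rule produces."""

    kind: str  # "code" | "copy" | "missing" | "func"
    code: Optional[float] = None
    tag: Optional[TaggedMissing] = None
    func: Optional[str] = None

    @classmethod
    def parse(cls, text: str) -> "TargetSpec":
        text = text.strip()
        if text == "copy":
            return cls("copy")
        if TaggedMissing.is_token(text):
            return cls("missing", tag=TaggedMissing.from_token(text))
        if text.startswith("Func::"):
            name = text[len("Func::"):].strip()
            if not name:
                raise WorksheetError("empty Func:: tag")
            return cls("func", func=name)
        if _NUMBER_RE.match(text):
            return cls("code", code=float(text))
        raise WorksheetError(f"cannot parse recEnd: {text!r}")

    def serialize(self) -> str:
        if self.kind == "copy":
            return "copy"
        if self.kind == "missing":
            return self.tag.token
        if self.kind == "func":
            return f"Func::{self.func}"
        return _format_number(self.code)


# ---------------------------------------------------------------------------
# row models


@dataclass(frozen=True)
class VariableIndexRow:
    """One harmonized variable's identity in ``variables.csv``."""

    variable: str
    label: str = ""
    label_long: str = ""
    subject: str = ""
    section: str = ""
    variable_type: str = "Categorical"
    units: str = "N/A"
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.variable:
            raise WorksheetError("variable name must be non-empty")
        if self.variable_type not in ("Categorical", "Continuous"):
            raise WorksheetError(
                f"variableType must be Categorical or Continuous, "
                f"got {self.variable_type!r} for {self.variable}"
            )


@dataclass(frozen=True)
class RecodeRule:
    """One mapping row of ``variable_details.csv``."""

    variable: str
    type_end: str  # "cat" | "cont"
    type_start: str
    database_start: Tuple[str, ...]
    variable_start: Tuple[Tuple[str, str], ...]  # (cycle, raw name) pairs
    default_start: Optional[str]
    derived_inputs: Optional[Tuple[str, ...]]  # for DerivedVar:: rows
    rec_start: SourceSpec
    rec_end: TargetSpec
    cat_label: str = ""
    cat_label_long: str = ""
    units: str = ""
    notes: str = ""
    row_number: int = 0  # 1-based data-row position in the CSV

    @property
    def is_derived(self) -> bool:
        return self.rec_end.kind == "func"

    def raw_name(self, cycle: str) -> Optional[str]:
        """Resolve the raw source column name for ``cycle``."""
        for cyc, name in self.variable_start:
            if cyc == cycle:
                return name
        return self.default_start

    def applies_to(self, cycle: str) -> bool:
        return cycle in self.database_start


@dataclass
class WorksheetSet:
    """A parsed pair of worksheets plus the declared cycle universe."""

    index: List[VariableIndexRow]
    rules: List[RecodeRule]
    cycle_universe: Tuple[str, ...]
    _by_variable: Dict[str, List[RecodeRule]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if len(set(self.cycle_universe)) != len(self.cycle_universe):
            raise WorksheetError("cycle universe contains duplicates")
        self._by_variable = {}
        for rule in self.rules:
            self._by_variable.setdefault(rule.variable, []).append(rule)

    @property
    def variable_names(self) -> List[str]:
        return [row.variable for row in self.index]

    def index_row(self, variable: str) -> VariableIndexRow:
        for row in self.index:
            if row.variable == variable:
                return row
        raise KeyError(variable)

    def rules_for(self, variable: str, cycle: Optional[str] = None
                  ) -> List[RecodeRule]:
        rules = self._by_variable.get(variable, [])
        if cycle is None:
            return list(rules)
        return [r for r in rules if r.applies_to(cycle)]

    def is_derived(self, variable: str) -> bool:
        return any(r.is_derived for r in self._by_variable.get(variable, []))

    def derived_inputs(self, variable: str) -> Tuple[str, ...]:
        for r in self._by_variable.get(variable, []):
            if r.is_derived and r.derived_inputs:
                return r.derived_inputs
        return ()

    def applicable_variables(self, cycle: str) -> List[str]:
        """Harmonized variables with at least one rule for ``cycle``."""
        return [v for v in self.variable_names if self.rules_for(v, cycle)]


# ---------------------------------------------------------------------------
# parsing


def _read_csv_rows(csv_path: Union[str, Path], expected_header: Sequence[str]
                   ) -> List[Dict[str, str]]:
    path = Path(csv_path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise WorksheetError(f"{path}: empty file")
        missing = [c for c in expected_header if c not in reader.fieldnames]
        if missing:
            raise WorksheetError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        return [
            {k: (v or "").strip() for k, v in row.items() if k is not None}
            for row in reader
        ]


def parse_variables(csv_path: Union[str, Path]) -> List[VariableIndexRow]:
    """Parse ``variables.csv`` into index rows, preserving order."""
    rows = _read_csv_rows(csv_path, VARIABLES_HEADER)
    out: List[VariableIndexRow] = []
    for row in rows:
        out.append(VariableIndexRow(
            variable=row["variable"],
            label=row["label"],
            label_long=row["labelLong"],
            subject=row["subject"],
            section=row["section"],
            variable_type=row["variableType"],
            units=row["units"],
            notes=row["notes"],
        ))
    seen: Dict[str, int] = {}
    for r in out:
        seen[r.variable] = seen.get(r.variable, 0) + 1
    dupes = sorted(v for v, n in seen.items() if n > 1)
    if dupes:
        raise WorksheetError(
            f"duplicate variable name(s) in index: {', '.join(dupes)}"
        )
    return out


def _parse_variable_start(cell: str, row_number: int
                          ) -> Tuple[Tuple[Tuple[str, str], ...],
                                     Optional[str],
                                     Optional[Tuple[str, ...]]]:
    """Split a variableStart cell into (per-cycle, default, derived-inputs)."""
    cell = cell.strip()
    if cell.startswith("DerivedVar::"):
        body = cell[len("DerivedVar::"):].strip()
        if not (body.startswith("[") and body.endswith("]")):
            raise WorksheetError(
                f"row {row_number}: DerivedVar:: inputs must be bracketed"
            )
        inputs = tuple(
            s.strip() for s in body[1:-1].split(",") if s.strip()
        )
        if not inputs:
            raise WorksheetError(f"row {row_number}: DerivedVar:: has no inputs")
        return (), None, inputs

    entries: List[Tuple[str, str]] = []
    default: Optional[str] = None
    for part in (p.strip() for p in cell.split(",")):
        if not part:
            continue
        if part.startswith("[") and part.endswith("]"):
            if default is not None:
                raise WorksheetError(
                    f"row {row_number}: more than one default raw name"
                )
            default = part[1:-1].strip()
        elif "::" in part:
            cyc, name = part.split("::", 1)
            entries.append((cyc.strip(), name.strip()))
        else:
            raise WorksheetError(
                f"row {row_number}: cannot parse variableStart entry {part!r}"
            )
    return tuple(entries), default, None


def parse_variable_details(csv_path: Union[str, Path]) -> List[RecodeRule]:
    """Parse ``variable_details.csv`` into recode rules, preserving order."""
    rows = _read_csv_rows(csv_path, DETAILS_HEADER)
    out: List[RecodeRule] = []
    for i, row in enumerate(rows, start=1):
        try:
            per_cycle, default, derived = _parse_variable_start(
                row["variableStart"], i
            )
            rule = RecodeRule(
                variable=row["variable"],
                type_end=row["typeEnd"],
                type_start=row["typeStart"],
                database_start=tuple(
                    s.strip() for s in row["databaseStart"].split(",")
                    if s.strip()
                ),
                variable_start=per_cycle,
                default_start=default,
                derived_inputs=derived,
                rec_start=SourceSpec.parse(row["recStart"]),
                rec_end=TargetSpec.parse(row["recEnd"]),
                cat_label=row["catLabel"],
                cat_label_long=row["catLabelLong"],
                units=row["units"],
                notes=row["notes"],
                row_number=i,
            )
        except WorksheetError as exc:
            raise WorksheetError(f"{csv_path} row {i}: {exc}") from exc
        if not rule.database_start:
            raise WorksheetError(f"{csv_path} row {i}: empty databaseStart")
        out.append(rule)
    return out


def load_worksheets(variables_csv: Union[str, Path],
                    details_csv: Union[str, Path],
                    cycle_universe: Optional[Sequence[str]] = None
                    ) -> WorksheetSet:
    """Parse both worksheets into a :class:`WorksheetSet`.

    When ``cycle_universe`` is not given it is taken as the ordered union
    of ``databaseStart`` entries across the rules.
    """
    index = parse_variables(variables_csv)
    rules = parse_variable_details(details_csv)
    if cycle_universe is None:
        seen: List[str] = []
        for rule in rules:
            for cyc in rule.database_start:
                if cyc not in seen:
                    seen.append(cyc)
        cycle_universe = seen
    return WorksheetSet(index=index, rules=rules,
                        cycle_universe=tuple(cycle_universe))


def load_demo_worksheets() -> WorksheetSet:
    """Load the packaged demonstration worksheet set (10 cycles, 2001–2014)."""
    data = resources.files("surveyharm") / "data"
    return load_worksheets(
        data / "demo_variables.csv",
        data / "demo_variable_details.csv",
        cycle_universe=DEMO_CYCLES,
    )


# ---------------------------------------------------------------------------
# serialization (round-trip support)


def write_variables(index: Sequence[VariableIndexRow],
                    csv_path: Union[str, Path]) -> None:
    with Path(csv_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(VARIABLES_HEADER)
        for row in index:
            writer.writerow([
                row.variable, row.label, row.label_long, row.subject,
                row.section, row.variable_type, row.units, row.notes,
            ])


def _serialize_variable_start(rule: RecodeRule) -> str:
    if rule.derived_inputs is not None:
        return "DerivedVar::[" + ", ".join(rule.derived_inputs) + "]"
    parts = [f"{cyc}::{name}" for cyc, name in rule.variable_start]
    if rule.default_start is not None:
        parts.append(f"[{rule.default_start}]")
    return ", ".join(parts)


def write_variable_details(rules: Sequence[RecodeRule],
                           csv_path: Union[str, Path]) -> None:
    with Path(csv_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DETAILS_HEADER)
        for rule in rules:
            writer.writerow([
                rule.variable, rule.type_end, rule.type_start,
                ", ".join(rule.database_start),
                _serialize_variable_start(rule),
                rule.rec_end.serialize(), rule.rec_start.serialize(),
                rule.cat_label, rule.cat_label_long, rule.units, rule.notes,
            ])


def write_worksheets(worksheets: WorksheetSet, directory: Union[str, Path],
                     variables_name: str = "variables.csv",
                     details_name: str = "variable_details.csv") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_variables(worksheets.index, directory / variables_name)
    write_variable_details(worksheets.rules, directory / details_name)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``rows`` are 1-based detail-sheet rows."""

    kind: str
    variable: str
    cycle: Optional[str]
    message: str
    rows: Tuple[int, ...] = ()


def validate_worksheets(index: Sequence[VariableIndexRow],
                        rules: Sequence[RecodeRule],
                        cycle_universe: Sequence[str],
                        registry: Optional[Dict[str, object]] = None
                        ) -> List[Finding]:
    """Cross-check the two worksheets; an empty report means well-formed.

    Checks, per variable and cycle: rules referencing variables missing
    from the index, cycles outside the universe, unresolvable raw names,
    overlapping source specs, duplicated ``else`` rules, continuous
    domains left without a catch-all, unregistered ``Func::`` tags (when
    a registry is supplied), and cycles among derived dependencies.
    """
    findings: List[Finding] = []
    index_names = {row.variable for row in index}
    universe = set(cycle_universe)

    for rule in rules:
        if rule.variable not in index_names:
            findings.append(Finding(
                "dangling-variable", rule.variable, None,
                f"rule references variable {rule.variable!r} absent from "
                f"the index", (rule.row_number,),
            ))
        bad = [c for c in rule.database_start if c not in universe]
        if bad:
            findings.append(Finding(
                "unknown-cycle", rule.variable, bad[0],
                f"databaseStart cycle(s) outside the universe: "
                f"{', '.join(bad)}", (rule.row_number,),
            ))
        if rule.derived_inputs is None:
            unresolved = [c for c in rule.database_start
                          if rule.raw_name(c) is None]
            if unresolved:
                findings.append(Finding(
                    "unresolved-raw-name", rule.variable, unresolved[0],
                    "no raw column name (explicit or default) for cycle(s): "
                    + ", ".join(unresolved), (rule.row_number,),
                ))
        if registry is not None and rule.rec_end.kind == "func":
            if rule.rec_end.func not in registry:
                findings.append(Finding(
                    "unknown-function", rule.variable, None,
                    f"Func::{rule.rec_end.func} is not registered",
                    (rule.row_number,),
                ))

    # per (variable, cycle): overlap, duplicate else, coverage
    by_var: Dict[str, List[RecodeRule]] = {}
    for rule in rules:
        by_var.setdefault(rule.variable, []).append(rule)
    type_of = {row.variable: row.variable_type for row in index}

    for variable, var_rules in by_var.items():
        for cycle in cycle_universe:
            active = [r for r in var_rules if r.applies_to(cycle)]
            if not active or any(r.is_derived for r in active):
                continue
            specific = [r for r in active if r.rec_start.kind != "else"]
            else_rules = [r for r in active if r.rec_start.kind == "else"]
            if len(else_rules) > 1:
                findings.append(Finding(
                    "duplicate-else", variable, cycle,
                    "more than one else rule",
                    tuple(r.row_number for r in else_rules),
                ))
            for i, a in enumerate(specific):
                for b in specific[i + 1:]:
                    if a.rec_start.overlaps(b.rec_start):
                        findings.append(Finding(
                            "overlap", variable, cycle,
                            f"source specs {a.rec_start.serialize()} and "
                            f"{b.rec_start.serialize()} overlap",
                            (a.row_number, b.row_number),
                        ))
            if (not else_rules
                    and type_of.get(variable) == "Continuous"):
                findings.append(Finding(
                    "uncovered-domain", variable, cycle,
                    "continuous variable without an else catch-all: "
                    "gaps in the source domain are possible",
                    tuple(r.row_number for r in specific),
                ))

    # derived dependency graph must be acyclic
    derived = {v: rs for v, rs in by_var.items()
               if any(r.is_derived for r in rs)}
    deps = {}
    for v, rs in derived.items():
        for r in rs:
            if r.derived_inputs:
                deps[v] = [d for d in r.derived_inputs if d in derived]
    state: Dict[str, int] = {}

    def visit(node: str, stack: List[str]) -> None:
        state[node] = 1
        for nxt in deps.get(node, []):
            if state.get(nxt) == 1:
                findings.append(Finding(
                    "dependency-cycle", node, None,
                    "derived variables form a cycle: "
                    + " -> ".join(stack + [nxt]),
                ))
            elif state.get(nxt) is None:
                visit(nxt, stack + [nxt])
        state[node] = 2

    for v in deps:
        if state.get(v) is None:
            visit(v, [v])

    return findings


def source_category_count(worksheets: WorksheetSet, variable: str,
                          cycle: str) -> int:
    """Number of distinct source categories a rule set declares.

    Counts specific (non-else) rules mapping a source code or interval
    to a harmonized category code — i.e. the declared category structure
    of the raw variable in that cycle, excluding reserved missing codes.
    """
    return sum(
        1 for r in worksheets.rules_for(variable, cycle)
        if r.rec_start.kind in ("code", "interval")
        and r.rec_end.kind == "code"
    )


def worksheet_equal(a: WorksheetSet, b: WorksheetSet) -> bool:
    """Field-identical comparison, ignoring bookkeeping row numbers."""
    if a.index != b.index or a.cycle_universe != b.cycle_universe:
        return False
    if len(a.rules) != len(b.rules):
        return False
    return all(
        replace(ra, row_number=0) == replace(rb, row_number=0)
        for ra, rb in zip(a.rules, b.rules)
    )
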