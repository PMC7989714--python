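"""Recode engine: transform one cycle's raw table into harmonized form.

The central operation is :func:`recode_with_table` — "recode with
table": it takes one survey cycle's raw respondent table and the parsed
specification worksheets, applies every applicable recode rule, then
computes derived variables in dependency order. The output keeps exactly
one row per respondent and carries label metadata, transformation notes
and tagged missing values.

Matching semantics: a specific rule (code, interval or ``NA``) always
wins over ``else``; rules are validated to be non-overlapping, so their
order is irrelevant. A raw value matched by no rule is an error in
strict mode; in lenient mode (the default) it becomes ``NA::b`` with a
warning, since real survey files occasionally contain undocumented
codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import (Callable, Dict, List, Optional, Sequence, Tuple, Union)

import numpy as np
import pandas as pd

from .derived import REGISTRY, Value
from .missing import TaggedMissing, is_tagged
from .worksheet import RecodeRule, WorksheetSet


class RecodeError(ValueError):
    """Unrecoverable problem while transforming a cycle."""


class UnmatchedValueError(RecodeError):
    """A raw value matched no rule while strict mode was on."""

    def __init__(self, variable: str, cycle: str, raw_value: float):
        self.variable = variable
        self.cycle = cycle
        self.raw_value = raw_value
        super().__init__(
            f"unmatched raw value {raw_value!r} for variable {variable!r} "
            f"in cycle {cycle!r} (strict mode)"
        )


@dataclass
class CycleTable:
    """Raw rectangular respondent data for one survey cycle."""

    cycle_id: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        if self.rows.columns.duplicated().any():
            dupes = self.rows.columns[self.rows.columns.duplicated()]
            raise RecodeError(f"duplicate raw columns: {list(dupes)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class HarmonizedTable:
    """Transformed respondent data with harmonized names and metadata.

    ``rows`` holds object-dtype columns mixing numeric values and
    :class:`TaggedMissing` markers. ``labels`` maps each variable to its
    label, units and per-category labels; ``notes`` collects the
    worksheet notes emitted during the transformation, once per
    (variable, note).
    """

    cycle_id: str
    rows: pd.DataFrame
    labels: Dict[str, Dict[str, object]] = field(default_factory=dict)
    notes: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# scalar rule application


def apply_rules_to_value(raw: Value, rules: Sequence[RecodeRule],
                         strict: bool = False) -> Value:
    """Recode a single raw value under a variable/cycle rule set.

    A specific rule wins over ``else``; ``copy`` passes the raw value
    through; tagged-missing targets return the corresponding marker.
    Unmatched values raise in strict mode and fall to ``NA::b``
    otherwise.
    """
    if not rules:
        raise RecodeError("empty rule list")
    if is_tagged(raw):
        return raw
    value = float(raw) if raw is not None else float("nan")
    else_rule: Optional[RecodeRule] = None
    match: Optional[RecodeRule] = None
    for rule in rules:
        if rule.rec_start.kind == "else":
            else_rule = rule
        elif match is None and rule.rec_start.matches(value):
            match = rule
    if match is None:
        match = else_rule
    if match is None:
        if strict:
            raise UnmatchedValueError(rules[0].variable,
                                      "/".join(rules[0].database_start), raw)
        warnings.warn(
            f"unmatched raw value {raw!r} for {rules[0].variable!r}; "
            f"recoded to NA::b", stacklevel=2,
        )
        return TaggedMissing.NA_B
    return _target_value(match, raw)


def _target_value(rule: RecodeRule, raw: Value) -> Value:
    target = rule.rec_end
    if target.kind == "copy":
        return raw
    if target.kind == "missing":
        return target.tag
    if target.kind == "code":
        code = target.code
        return int(code) if float(code).is_integer() else code
    raise RecodeError(f"Func:: rule cannot be applied per-value "
                      f"({rule.variable})")


# ---------------------------------------------------------------------------
# vectorized recode of one variable for one cycle


def _recode_column(raw: pd.Series, rules: Sequence[RecodeRule],
                   variable: str, cycle: str, strict: bool
                   ) -> Tuple[np.ndarray, int]:
    """Vectorized recode; returns (object array, n unmatched->NA::b)."""
    values = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    n = len(values)
    out = np.empty(n, dtype=object)
    assigned = np.zeros(n, dtype=bool)
    isnan = np.isnan(values)

    else_rule: Optional[RecodeRule] = None
    for rule in rules:
        spec = rule.rec_start
        if spec.kind == "else":
            else_rule = rule
            continue
        if spec.kind == "na":
            mask = ~assigned & isnan
        elif spec.kind == "code":
            mask = ~assigned & ~isnan & np.isclose(
                values, spec.code, rtol=0.0, atol=1e-9)
        else:  # interval
            mask = (~assigned & ~isnan
                    & (values >= spec.lo - 1e-9)
                    & (values <= spec.hi + 1e-9))
        if mask.any():
            _assign(out, mask, rule, values)
            assigned |= mask

    if else_rule is not None:
        mask = ~assigned
        if mask.any():
            _assign(out, mask, else_rule, values)
            assigned |= mask

    unmatched = int((~assigned).sum())
    if unmatched:
        if strict:
            first = values[~assigned][0]
            raise UnmatchedValueError(variable, cycle, first)
        out[~assigned] = TaggedMissing.NA_B
        warnings.warn(
            f"{unmatched} unmatched raw value(s) for {variable!r} in "
            f"{cycle!r}; recoded to NA::b", stacklevel=2,
        )
    return out, unmatched


def _assign(out: np.ndarray, mask: np.ndarray, rule: RecodeRule,
            values: np.ndarray) -> None:
    target = rule.rec_end
    if target.kind == "copy":
        idx = np.flatnonzero(mask)
        nanmask = np.isnan(values[idx])
        for i, bad in zip(idx, nanmask):
            out[i] = TaggedMissing.NA_B if bad else float(values[i])
    elif target.kind == "missing":
        out[mask] = target.tag
    elif target.kind == "code":
        code = target.code
        out[mask] = int(code) if float(code).is_integer() else code
    else:
        raise RecodeError(f"Func:: rule in row-recode path ({rule.variable})")


# ---------------------------------------------------------------------------
# full-table transformation


def _topo_order(worksheets: WorksheetSet, derived: Sequence[str]
                ) -> List[str]:
    """Topological order of derived variables by their input dependencies."""
    derived_set = set(derived)
    order: List[str] = []
    state: Dict[str, int] = {}

    def visit(v: str) -> None:
        state[v] = 1
        for dep in worksheets.derived_inputs(v):
            if dep in derived_set:
                if state.get(dep) == 1:
                    raise RecodeError(
                        f"derived-variable dependency cycle at {v!r}")
                if state.get(dep) is None:
                    visit(dep)
        state[v] = 2
        order.append(v)

    for v in derived:
        if state.get(v) is None:
            visit(v)
    return order


def recode_with_table(
    data: CycleTable,
    worksheets: WorksheetSet,
    variables: Optional[Sequence[str]] = None,
    print_notes: bool = True,
    log_sink: Optional[Callable[[str, str, str], None]] = None,
    strict: bool = False,
    registry: Optional[Dict[str, Callable[..., Value]]] = None,
) -> HarmonizedTable:
    """Transform one cycle's raw table into harmonized variables.

    Parameters
    ----------
    data
        Raw respondent table for one cycle.
    worksheets
        Parsed specification worksheets.
    variables
        Harmonized variables to produce; all applicable variables when
        omitted. Derived variables pull in their inputs automatically.
    print_notes
        Emit every rule's ``notes`` text (once per variable and cycle)
        to ``log_sink``; on by default.
    log_sink
        Receiver called as ``log_sink(variable, cycle, note)``; defaults
        to ``print``.
    strict
        Raise on raw values matched by no rule instead of recoding them
        to ``NA::b`` with a warning.
    registry
        ``Func::`` tag registry; defaults to the built-in one.

    Variables whose rules do not cover this cycle are omitted with a
    note rather than an error, since not every variable is collected in
    every cycle.
    """
    cycle = data.cycle_id
    if cycle not in worksheets.cycle_universe:
        raise RecodeError(f"cycle {cycle!r} not in the worksheet universe")
    funcs = REGISTRY if registry is None else registry

    if variables is None:
        requested = list(worksheets.variable_names)
        explicit = False
    else:
        unknown = [v for v in variables if v not in worksheets.variable_names]
        if unknown:
            raise RecodeError(
                f"variable(s) not in the worksheet index: {', '.join(unknown)}"
            )
        requested = list(variables)
        explicit = True

    notes: List[Tuple[str, str]] = []
    emitted = set()

    def emit(variable: str, note: str) -> None:
        if not note or (variable, note) in emitted:
            return
        emitted.add((variable, note))
        notes.append((variable, note))
        if print_notes:
            sink = log_sink if log_sink is not None else (
                lambda v, c, n: print(f"[{c}] {v}: {n}"))
            sink(variable, cycle, note)

    # expand derived dependencies, then split plain/derived
    selected: List[str] = []

    def add(v: str) -> None:
        if v in selected:
            return
        if worksheets.is_derived(v):
            for dep in worksheets.derived_inputs(v):
                if dep in worksheets.variable_names:
                    add(dep)
        selected.append(v)

    for v in requested:
        add(v)

    applicable = [v for v in selected if worksheets.rules_for(v, cycle)]
    for v in selected:
        if v not in applicable:
            emit(v, f"variable not collected in cycle {cycle}; omitted")
            if explicit and v in requested:
                pass  # omission is noted, not fatal
    plain = [v for v in applicable if not worksheets.is_derived(v)]
    derived = [v for v in applicable if worksheets.is_derived(v)]

    out = pd.DataFrame(index=data.rows.index)

    for variable in plain:
        rules = worksheets.rules_for(variable, cycle)
        raw_names = {r.raw_name(cycle) for r in rules}
        raw_names.discard(None)
        if len(raw_names) != 1:
            raise RecodeError(
                f"variable {variable!r}: expected one raw source column for "
                f"cycle {cycle!r}, resolved {sorted(raw_names)}")
        raw_name = raw_names.pop()
        if raw_name not in data.rows.columns:
            raise RecodeError(
                f"variable {variable!r}: raw column {raw_name!r} expected "
                f"for cycle {cycle!r} is missing from the input data")
        column, _ = _recode_column(data.rows[raw_name], rules, variable,
                                   cycle, strict)
        out[variable] = column
        for rule in rules:
            emit(variable, rule.notes)

    for variable in _topo_order(worksheets, derived):
        rule = next(r for r in worksheets.rules_for(variable, cycle)
                    if r.is_derived)
        if rule.rec_end.func not in funcs:
            raise RecodeError(
                f"Func::{rule.rec_end.func} (variable {variable!r}) is not "
                f"registered")
        func = funcs[rule.rec_end.func]
        inputs = rule.derived_inputs or ()
        missing_inputs = [i for i in inputs if i not in out.columns]
        if missing_inputs:
            raise RecodeError(
                f"derived variable {variable!r}: input(s) "
                f"{', '.join(missing_inputs)} unavailable in cycle {cycle!r}")
        cols = [out[i].to_numpy(dtype=object) for i in inputs]
        result = np.empty(len(out), dtype=object)
        for i in range(len(out)):
            result[i] = func(*(c[i] for c in cols))
        out[variable] = result
        emit(variable, rule.notes)

    # an explicit subset keeps the requested variables plus any derived
    # dependencies that had to be computed anyway
    if explicit:
        closure = set(requested) | {
            d for v in requested for d in _dependency_closure([v], worksheets)
        }
        out = out[[v for v in out.columns if v in closure]]

    table = HarmonizedTable(cycle_id=cycle, rows=out, notes=notes)
    return attach_labels(table, worksheets)


def _dependency_closure(requested: Sequence[str], worksheets: WorksheetSet
                        ) -> List[str]:
    closure: List[str] = []

    def add(v: str) -> None:
        if v in closure:
            return
        closure.append(v)
        for dep in worksheets.derived_inputs(v):
            add(dep)

    for v in requested:
        add(v)
    return closure


def attach_labels(table: HarmonizedTable, worksheets: WorksheetSet
                  ) -> HarmonizedTable:
    """Populate label metadata for every output variable (idempotent)."""
    labels: Dict[str, Dict[str, object]] = {}
    for variable in table.rows.columns:
        try:
            row = worksheets.index_row(variable)
        except KeyError:
            continue
        categories: Dict[object, str] = {}
        for rule in worksheets.rules_for(variable, table.cycle_id):
            if rule.rec_end.kind == "code" and rule.cat_label:
                code = rule.rec_end.code
                key = int(code) if float(code).is_integer() else code
                categories[key] = rule.cat_label
        entry: Dict[str, object] = {
            "label": row.label,
            "units": row.units,
        }
        if categories:
            entry["categories"] = categories
        labels[variable] = entry
    table.labels = labels
    return table
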