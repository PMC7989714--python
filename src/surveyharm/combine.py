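"""Stack transformed survey cycles into one pooled dataset.

Once every cycle has been transformed against the same worksheet set,
the harmonized tables can be stacked into a single table spanning all
cycles. A reserved ``survey_cycle`` provenance column records each
row's cycle of origin. Variables not collected in a cycle are filled
with ``NA::a`` for that cycle's rows: their absence is a design feature
of the cycle (structurally not applicable), not respondent nonresponse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .engine import HarmonizedTable
from .missing import TaggedMissing

#: Reserved name of the cycle provenance column.
CYCLE_COLUMN = "survey_cycle"


class CombineError(ValueError):
    """Tables cannot be merged into one pooled dataset."""


@dataclass
class CombinedTable:
    """Pooled rows over the union of harmonized variables."""

    rows: pd.DataFrame
    per_cycle_counts: Dict[str, int]
    labels: Dict[str, Dict[str, object]] = field(default_factory=dict)
    notes: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def filter_cycle(self, cycle_id: str) -> pd.DataFrame:
        """Rows of one cycle, restricted to the variables it collected.

        Columns that are pure ``NA::a`` fill for this cycle (variable
        absent by design) are dropped, so the result matches the
        cycle's own harmonized table.
        """
        if cycle_id not in self.per_cycle_counts:
            raise KeyError(cycle_id)
        sub = self.rows[self.rows[CYCLE_COLUMN] == cycle_id]
        sub = sub.drop(columns=[CYCLE_COLUMN])
        keep = list(self._collected.get(cycle_id, sub.columns))
        return sub[keep].reset_index(drop=True)

    _collected: Dict[str, Tuple[str, ...]] = field(default_factory=dict,
                                                   repr=False)


def combine_cycles(tables: Sequence[HarmonizedTable]) -> CombinedTable:
    """Concatenate harmonized cycle tables into one pooled table.

    Row order is the input order of the tables, then each table's own
    row order; every row count is conserved. Label metadata is merged
    and checked for conflicts: the same harmonized category code must
    carry the same label in every cycle.
    """
    if not tables:
        raise CombineError("no tables to combine")
    seen: List[str] = []
    for t in tables:
        if t.cycle_id in seen:
            raise CombineError(f"duplicate cycle id: {t.cycle_id!r}")
        seen.append(t.cycle_id)
        if CYCLE_COLUMN in t.rows.columns:
            raise CombineError(
                f"cycle {t.cycle_id!r} already contains the reserved "
                f"column {CYCLE_COLUMN!r}")

    # column union, preserving first-seen order
    columns: List[str] = []
    for t in tables:
        for c in t.rows.columns:
            if c not in columns:
                columns.append(c)

    merged_labels: Dict[str, Dict[str, object]] = {}
    for t in tables:
        for var, meta in t.labels.items():
            if var not in merged_labels:
                merged_labels[var] = {k: (dict(v) if isinstance(v, dict)
                                          else v)
                                      for k, v in meta.items()}
                continue
            base = merged_labels[var]
            for key in ("label", "units"):
                if meta.get(key) and base.get(key) and meta[key] != base[key]:
                    raise CombineError(
                        f"conflicting {key} for variable {var!r}: "
                        f"{base[key]!r} vs {meta[key]!r}")
            cats = meta.get("categories") or {}
            base_cats = base.setdefault("categories", {}) if cats else \
                base.get("categories", {})
            for code, label in cats.items():
                if code in base_cats and base_cats[code] != label:
                    raise CombineError(
                        f"conflicting category label for variable {var!r} "
                        f"code {code!r}: {base_cats[code]!r} vs {label!r}")
                base_cats[code] = label

    parts: List[pd.DataFrame] = []
    counts: Dict[str, int] = {}
    collected: Dict[str, Tuple[str, ...]] = {}
    for t in tables:
        part = t.rows.copy()
        part.insert(0, CYCLE_COLUMN, t.cycle_id)
        for c in columns:
            if c not in part.columns:
                part[c] = TaggedMissing.NA_A
        parts.append(part[[CYCLE_COLUMN] + columns])
        counts[t.cycle_id] = len(part)
        collected[t.cycle_id] = tuple(t.rows.columns)

    notes = [note for t in tables for note in t.notes]
    combined = CombinedTable(
        rows=pd.concat(parts, ignore_index=True),
        per_cycle_counts=counts,
        labels=merged_labels,
        notes=notes,
    )
    combined._collected = collected
    return combined
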