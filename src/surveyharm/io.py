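"""Reading raw cycle CSVs and writing harmonized output + sidecar.

Plain CSV has no notion of a tagged missing value, so two renderings
are offered:

* text (default): tagged values appear literally as ``NA(a)`` / ``NA(b)``
  in the value column;
* numeric (``numeric=True``): each column ``V`` stays purely numeric
  (tagged cells empty) and a companion column ``V__na`` holds the tag
  letter (``a``/``b``) or is empty.

Both render bit-exactly and round-trip through
:func:`read_harmonized_csv`. A JSON sidecar carries labels, notes and
provenance (cycle id, worksheet checksums, engine version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import pandas as pd

from . import __version__
from .combine import CYCLE_COLUMN, CombinedTable
from .engine import CycleTable, HarmonizedTable
from .missing import TaggedMissing, is_tagged

NA_SUFFIX = "__na"


def read_cycle_csv(path: Union[str, Path], cycle_id: str) -> CycleTable:
    """Load one cycle's raw respondent CSV (header = raw variable names)."""
    return CycleTable(cycle_id=cycle_id, rows=pd.read_csv(path))


def write_cycle_csv(table: CycleTable, path: Union[str, Path]) -> None:
    table.rows.to_csv(path, index=False)


def _cell_text(value: object) -> object:
    return value.render() if is_tagged(value) else value


def _frame_to_text(df: pd.DataFrame) -> pd.DataFrame:
    return df.map(_cell_text)


def _frame_to_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        series = df[col]
        if series.map(is_tagged).any():
            out[col] = series.map(lambda v: None if is_tagged(v) else v)
            out[col + NA_SUFFIX] = series.map(
                lambda v: v.value if is_tagged(v) else "")
        else:
            out[col] = series
    return out


def file_checksum(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sidecar(labels: Dict, notes: Iterable, cycle_id: Optional[str],
             worksheet_paths: Optional[Iterable[Union[str, Path]]],
             extra: Optional[Dict] = None) -> Dict:
    doc: Dict[str, object] = {
        "engine": {"name": "surveyharm", "version": __version__},
        "labels": labels,
        "notes": [list(n) for n in notes],
    }
    if cycle_id is not None:
        doc["cycle_id"] = cycle_id
    if worksheet_paths:
        doc["worksheet_checksums"] = {
            Path(p).name: file_checksum(p) for p in worksheet_paths
        }
    if extra:
        doc.update(extra)
    return doc


def _jsonable_labels(labels: Dict) -> Dict:
    out = {}
    for var, meta in labels.items():
        entry = dict(meta)
        if "categories" in entry:
            entry["categories"] = {str(k): v
                                   for k, v in entry["categories"].items()}
        out[var] = entry
    return out


def write_harmonized_csv(
    table: Union[HarmonizedTable, CombinedTable],
    csv_path: Union[str, Path],
    numeric: bool = False,
    worksheet_paths: Optional[Iterable[Union[str, Path]]] = None,
) -> Path:
    """Write a harmonized or combined table as CSV + JSON sidecar.

    Returns the sidecar path (``<csv>.meta.json``).
    """
    csv_path = Path(csv_path)
    df = table.rows
    rendered = _frame_to_numeric(df) if numeric else _frame_to_text(df)
    rendered.to_csv(csv_path, index=False)

    extra: Dict[str, object] = {"rendering": "numeric" if numeric else "text"}
    cycle_id = getattr(table, "cycle_id", None)
    if isinstance(table, CombinedTable):
        extra["per_cycle_counts"] = table.per_cycle_counts
        extra["collected"] = {c: list(v)
                              for c, v in table._collected.items()}
    sidecar_path = csv_path.with_suffix(csv_path.suffix + ".meta.json")
    sidecar_path.write_text(json.dumps(
        _sidecar(_jsonable_labels(table.labels), table.notes, cycle_id,
                 worksheet_paths, extra),
        indent=2) + "\n", encoding="utf-8")
    return sidecar_path


def _parse_rendered_frame(df: pd.DataFrame, numeric: bool) -> pd.DataFrame:
    if numeric:
        out = pd.DataFrame(index=df.index)
        value_cols = [c for c in df.columns if not c.endswith(NA_SUFFIX)]
        for col in value_cols:
            na_col = col + NA_SUFFIX
            series = df[col].astype(object)
            if na_col in df.columns:
                tags = df[na_col].fillna("")
                series = series.where(tags == "", None)
                series = [
                    TaggedMissing(t) if t else v
                    for v, t in zip(series, tags)
                ]
                out[col] = pd.Series(series, index=df.index, dtype=object)
            else:
                out[col] = series
        return out

    def parse_cell(v: object) -> object:
        if isinstance(v, str):
            tag = TaggedMissing.from_render(v)
            if tag is not None:
                return tag
            try:
                return float(v) if "." in v else int(v)
            except ValueError:
                return v
        return v

    return df.astype(object).map(parse_cell)


def read_harmonized_csv(csv_path: Union[str, Path]
                        ) -> Union[HarmonizedTable, CombinedTable]:
    """Re-load a harmonized (or combined) CSV written by this package.

    Requires the JSON sidecar next to the CSV to recover labels, notes,
    the rendering mode and — for combined tables — per-cycle counts.
    """
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(csv_path.suffix + ".meta.json")
    meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
    raw = pd.read_csv(csv_path)
    numeric = meta.get("rendering") == "numeric"
    # the provenance column holds cycle-id strings; keep it out of parsing
    provenance = None
    if CYCLE_COLUMN in raw.columns:
        provenance = raw[CYCLE_COLUMN]
        raw = raw.drop(columns=[CYCLE_COLUMN])
    rows = _parse_rendered_frame(raw, numeric)
    labels = meta.get("labels", {})
    notes = [tuple(n) for n in meta.get("notes", [])]
    if "per_cycle_counts" in meta:
        rows.insert(0, CYCLE_COLUMN, provenance)
        combined = CombinedTable(rows=rows,
                                 per_cycle_counts=meta["per_cycle_counts"],
                                 labels=labels, notes=notes)
        combined._collected = {c: tuple(v)
                               for c, v in meta.get("collected", {}).items()}
        return combined
    return HarmonizedTable(cycle_id=meta.get("cycle_id", ""), rows=rows,
                           labels=labels, notes=notes)
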