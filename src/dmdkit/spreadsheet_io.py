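"""Workbook generation and reading.

The entry workbook is the researcher-facing artefact: one worksheet per
property set plus a leading ``_scheme`` identity sheet.  Each data sheet
carries four header rows —

    row 1   property names
    row 2   descriptions
    row 3   "type" or "type:required"
    row 4   vocabulary, rendered "allowed:a|b" or "suggested:a|b"

— and data starts in row 5.  Reading is deliberately schema-light: every
cell comes back verbatim as a string (empty string = missing), unknown
sheets and columns are retained, and all semantic checking is left to the
validation stage.

A plain-text twin representation (a directory of CSV files plus a JSON
identity file) is provided for diff-friendly storage; the two round-trip
identically.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import json
import os
import zipfile
from pathlib import Path

import openpyxl

from .errors import SchemeDefinitionError, WorkbookFormatError
from .scheme_model import (
    MetadataSet,
    Property,
    Scheme,
    check_scheme_definition,
)

HEADER_ROWS = 4
DATA_START_ROW = 5
ID_SHEET = "_scheme"

# fixed document timestamp so identical content yields identical bytes
_EPOCH = _dt.datetime(2000, 1, 1)
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


def _normalize_workbook_zip(path) -> None:
    """Rewrite the xlsx container with fixed member timestamps.

    An xlsx file is a zip archive; the default member timestamps make two
    otherwise identical saves differ byte-wise.  Determinism of fixture
    and template bytes is part of this package's contract, so the archive
    is rewritten with a constant timestamp and fixed compression.
    """
    with zipfile.ZipFile(path, "r") as zf:
        members = [(info.filename, zf.read(info.filename)) for info in zf.infolist()]
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name, data in members:
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o600 << 16
            zf.writestr(info, data)
    Path(path).write_bytes(buf.getvalue())


def _vocab_cell(p: Property) -> str:
    if p.allowed_values:
        return "allowed:" + "|".join(p.allowed_values)
    if p.suggested_values:
        return "suggested:" + "|".join(p.suggested_values)
    return ""


def _type_cell(p: Property) -> str:
    return f"{p.type}:required" if p.required else p.type


def _new_workbook(scheme: Scheme) -> openpyxl.Workbook:
    wb = openpyxl.Workbook()
    wb.properties.created = _EPOCH
    wb.properties.modified = _EPOCH
    wb.properties.creator = "dmdkit"
    wb.properties.lastModifiedBy = "dmdkit"

    ws = wb.active
    ws.title = ID_SHEET
    ws.append(["scheme", scheme.name])
    ws.append(["version", scheme.version])
    ws.append(["description", scheme.description])
    for ps in scheme.property_sets:
        ws.append(["sheet", ps.name, ps.cardinality])

    for ps in scheme.property_sets:
        ws = wb.create_sheet(title=ps.name)
        ws.append([p.name for p in ps.properties])
        ws.append([p.description for p in ps.properties])
        ws.append([_type_cell(p) for p in ps.properties])
        ws.append([_vocab_cell(p) for p in ps.properties])
    return wb


def write_template_workbook(scheme: Scheme, path) -> None:
    """Write the empty entry workbook for ``scheme`` to ``path``."""
    problems = check_scheme_definition(scheme)
    if problems:
        raise SchemeDefinitionError(
            "scheme is not well-formed: " + "; ".join(problems)
        )
    wb = _new_workbook(scheme)
    wb.save(path)
    _normalize_workbook_zip(path)


def _sheet_columns(scheme: Scheme, meta: MetadataSet, set_name: str) -> list[str]:
    """Column order: scheme order first, then extra keys by first appearance."""
    cols: list[str] = []
    try:
        cols = list(scheme.property_set(set_name).property_names())
    except KeyError:
        pass
    for row in meta.tables.get(set_name, ()):
        for key in row:
            if key not in cols:
                cols.append(key)
    return cols


def write_filled_workbook(scheme: Scheme, meta: MetadataSet, path) -> None:
    """Write a workbook with ``meta``'s rows filled in under the template headers.

    Tables and columns unknown to the scheme are written too (an extra
    sheet gets a bare one-row header), so that structurally faulty
    metadata survives a write/read cycle and can be reported by
    validation.
    """
    problems = check_scheme_definition(scheme)
    if problems:
        raise SchemeDefinitionError(
            "scheme is not well-formed: " + "; ".join(problems)
        )
    wb = _new_workbook(scheme)
    known = set(scheme.set_names())
    for set_name in scheme.set_names():
        ws = wb[set_name]
        cols = _sheet_columns(scheme, meta, set_name)
        n_scheme_cols = len(scheme.property_set(set_name).property_names())
        # headers for extra (unknown) columns so reading preserves them
        for j, col in enumerate(cols[n_scheme_cols:], start=n_scheme_cols + 1):
            ws.cell(row=1, column=j, value=col)
        for row in meta.tables.get(set_name, ()):
            ws.append([row.get(c, "") for c in cols])
    for set_name, rows in meta.tables.items():
        if set_name in known:
            continue
        ws = wb.create_sheet(title=set_name)
        cols = _sheet_columns(scheme, meta, set_name)
        ws.append(cols)
        ws.append([])  # rows 2-4 left blank to keep the layout uniform
        ws.append([])
        ws.append([])
        for row in rows:
            ws.append([row.get(c, "") for c in cols])
    wb.save(path)
    _normalize_workbook_zip(path)


def _cell_str(value) -> str:
    if value is None:
        return ""
    if isinstance(value, _dt.datetime):
        if value.time() == _dt.time(0, 0):
            return value.date().isoformat()
        return value.isoformat()
    if isinstance(value, _dt.date):
        return value.isoformat()
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value).strip()


def _read_id_sheet(ws) -> tuple[str, str]:
    name = version = None
    for row in ws.iter_rows(values_only=True):
        if not row:
            continue
        key = _cell_str(row[0])
        val = _cell_str(row[1]) if len(row) > 1 else ""
        if key == "scheme":
            name = val
        elif key == "version":
            version = val
    if not name or not version:
        raise WorkbookFormatError(
            "corrupted '_scheme' sheet: scheme name/version not found"
        )
    return name, version


def detect_scheme_id(path) -> tuple[str, str]:
    """Return (scheme name, version) from a workbook without reading data sheets."""
    wb = _load_workbook(path)
    try:
        if ID_SHEET not in wb.sheetnames:
            raise WorkbookFormatError(f"{path}: missing {ID_SHEET!r} sheet")
        return _read_id_sheet(wb[ID_SHEET])
    finally:
        wb.close()


def _load_workbook(path):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        return openpyxl.load_workbook(path, data_only=True)
    except Exception as exc:  # zip/XML level corruption
        raise WorkbookFormatError(f"{path}: not a readable workbook ({exc})") from exc


def read_metadata_workbook(path) -> MetadataSet:
    """Read a filled workbook back into a :class:`MetadataSet`.

    All cell values are captured verbatim as (whitespace-stripped) strings;
    trailing all-empty rows are dropped; unknown sheets and columns are
    kept for validation to report.
    """
    wb = _load_workbook(path)
    try:
        if ID_SHEET not in wb.sheetnames:
            raise WorkbookFormatError(f"{path}: missing {ID_SHEET!r} sheet")
        name, version = _read_id_sheet(wb[ID_SHEET])
        tables: dict[str, list[dict[str, str]]] = {}
        for sheet in wb.sheetnames:
            if sheet == ID_SHEET:
                continue
            ws = wb[sheet]
            rows_iter = ws.iter_rows(values_only=True)
            header = next(rows_iter, None) or ()
            cols = [(_cell_str(c), j) for j, c in enumerate(header)]
            cols = [(c, j) for c, j in cols if c]
            rows: list[dict[str, str]] = []
            for i, raw in enumerate(rows_iter, start=2):
                if i < DATA_START_ROW:
                    continue
                row = {
                    c: _cell_str(raw[j]) if j < len(raw) else ""
                    for c, j in cols
                }
                rows.append(row)
            while rows and all(v == "" for v in rows[-1].values()):
                rows.pop()
            tables[sheet] = rows
        return MetadataSet(scheme_name=name, scheme_version=version, tables=tables)
    finally:
        wb.close()


# ---------------------------------------------------------------------------
# plain-text twin: one CSV per property set + JSON identity file


def write_metadata_dir(meta: MetadataSet, dirpath, scheme: Scheme | None = None) -> None:
    """Write ``meta`` as a directory of CSV files plus ``_scheme.json``."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    identity = {"scheme": meta.scheme_name, "version": meta.scheme_version,
                "sheets": list(meta.tables)}
    (d / "_scheme.json").write_text(
        json.dumps(identity, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    for set_name, rows in meta.tables.items():
        cols = _sheet_columns(scheme, meta, set_name) if scheme else []
        if not cols:
            seen: list[str] = []
            for row in rows:
                for k in row:
                    if k not in seen:
                        seen.append(k)
            cols = seen
        with open(d / f"{set_name}.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for row in rows:
                w.writerow([row.get(c, "") for c in cols])


def read_metadata_dir(dirpath) -> MetadataSet:
    """Inverse of :func:`write_metadata_dir`."""
    d = Path(dirpath)
    id_path = d / "_scheme.json"
    if not id_path.exists():
        raise WorkbookFormatError(f"{dirpath}: missing _scheme.json identity file")
    try:
        identity = json.loads(id_path.read_text(encoding="utf-8"))
        name, version = identity["scheme"], identity["version"]
        sheet_order = identity.get("sheets")
    except (json.JSONDecodeError, KeyError) as exc:
        raise WorkbookFormatError(f"{dirpath}: corrupt _scheme.json ({exc})") from exc
    tables: dict[str, list[dict[str, str]]] = {}
    csv_names = sorted(p.stem for p in d.glob("*.csv"))
    order = [s for s in (sheet_order or csv_names) if s in csv_names]
    order += [s for s in csv_names if s not in order]
    for set_name in order:
        with open(d / f"{set_name}.csv", newline="", encoding="utf-8") as fh:
            r = csv.reader(fh)
            header = next(r, [])
            rows = [
                {c: (row[j].strip() if j < len(row) else "") for j, c in enumerate(header) if c}
                for row in r
            ]
        while rows and all(v == "" for v in rows[-1].values()):
            rows.pop()
        tables[set_name] = rows
    return MetadataSet(scheme_name=name, scheme_version=version, tables=tables)
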