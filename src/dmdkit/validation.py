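"""Three-stage validation of filled metadata, plus report rendering.

Stages, run in order by :func:`validate_all`:

1. **structure** — does the metadata have the sheets/columns/row counts the
   scheme demands?
2. **values** — does every cell parse under its declared type, satisfy the
   required flag, the closed (``allowed``) or open (``suggested``)
   vocabulary, and the numeric range?
3. **consistency** — do cross-references resolve within the metadata, are
   keys unique, and does each data file carry exactly one measurement and
   extraction method?
4. **data_files** (optional) — do the declared files, columns and column
   types match the delimited files actually on disk?

Findings are :class:`ValidationIssue` values with a severity (``error`` >
``warning`` > ``note``) and a stable rule code from :data:`RULES`.  A
closed vocabulary violation is an error; an open vocabulary deviation is
only a note.  Error-level *structure* problems suppress the later checks
for the affected table only, to avoid cascading noise.
"""

from __future__ import annotations

import csv
import datetime as _dt
import html as _html
import os
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Optional

from .errors import UsageError
from .scheme_model import MetadataSet, Scheme, parse_typed

STAGES = ("structure", "values", "consistency", "data_files")


class Severity(IntEnum):
    """Total severity ordering: error > warning > note."""

    NOTE = 1
    WARNING = 2
    ERROR = 3

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name.lower()


#: rule registry: code -> (severity, description)
RULES: dict[str, tuple[Severity, str]] = {
    "STRUCT_SCHEME_MISMATCH": (Severity.ERROR, "metadata declares a different scheme name or version"),
    "STRUCT_MISSING_SET": (Severity.ERROR, "a property set required by the scheme has no sheet"),
    "STRUCT_UNKNOWN_SET": (Severity.WARNING, "a sheet is not part of the scheme"),
    "STRUCT_MISSING_PROPERTY": (Severity.ERROR, "a property column is missing from its sheet"),
    "STRUCT_UNKNOWN_PROPERTY": (Severity.WARNING, "a column is not part of the property set"),
    "STRUCT_ROW_COUNT": (Severity.ERROR, "an exactly-one-row set has zero or extra data rows"),
    "VAL_REQUIRED_MISSING": (Severity.ERROR, "a required value is missing"),
    "VAL_TYPE": (Severity.ERROR, "a value does not parse under the declared type"),
    "VAL_NOT_ALLOWED": (Severity.ERROR, "a value is not in the closed list of allowed values"),
    "VAL_NOT_SUGGESTED": (Severity.NOTE, "a value is not in the open list of suggested values"),
    "VAL_RANGE": (Severity.ERROR, "a numeric value lies outside its declared range"),
    "CONS_DANGLING_REF": (Severity.ERROR, "a cross-reference names a value absent from its target"),
    "CONS_DUPLICATE_KEY": (Severity.WARNING, "a key value occurs in more than one row"),
    "CONS_MULTIPLE_METHODS": (Severity.ERROR, "a data file is listed with more than one measurement/extraction"),
    "DATA_FILE_MISSING": (Severity.ERROR, "a declared data file is absent from the data directory"),
    "DATA_FILE_UNDECLARED": (Severity.WARNING, "a file in the data directory is not declared"),
    "DATA_COLUMN_MISSING": (Severity.ERROR, "a declared column is absent from the file header"),
    "DATA_COLUMN_UNDECLARED": (Severity.WARNING, "a header column is not declared"),
    "DATA_COLUMN_TYPE": (Severity.ERROR, "a column value violates the declared column type"),
}


@dataclass(frozen=True)
class ValidationIssue:
    """One finding: severity, stable rule code, location, message.

    ``location`` is (propertySetName, propertyName or "", rowIndex or 0);
    row indices are 1-based data-row positions within the table.
    """

    severity: Severity
    code: str
    location: tuple[str, str, int]
    message: str


def issue(code: str, location: tuple[str, str, int], message: str) -> ValidationIssue:
    severity, _ = RULES[code]
    return ValidationIssue(severity, code, location, message)


@dataclass(eq=False)
class ValidationReport:
    """Issues grouped by stage; worst severity derived, not stored.

    Equality ignores the timestamp so identical inputs validate to equal
    reports.
    """

    scheme_id: tuple[str, str]
    stages: dict[str, list[ValidationIssue]] = field(default_factory=dict)
    timestamp: _dt.datetime = field(default_factory=_dt.datetime.now)

    @property
    def issues(self) -> list[ValidationIssue]:
        return [i for stage in STAGES for i in self.stages.get(stage, [])]

    @property
    def worst_severity(self) -> str:
        all_issues = self.issues
        if not all_issues:
            return "success"
        return str(max(i.severity for i in all_issues))

    def counts(self) -> dict[str, int]:
        out = {"error": 0, "warning": 0, "note": 0}
        for i in self.issues:
            out[str(i.severity)] += 1
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ValidationReport):
            return NotImplemented
        return self.scheme_id == other.scheme_id and self.stages == other.stages


# ---------------------------------------------------------------------------
# stage 1: structure


def _table_columns(rows: list[dict[str, str]]) -> list[str]:
    cols: list[str] = []
    for row in rows:
        for k in row:
            if k not in cols:
                cols.append(k)
    return cols


def validate_structure(meta: MetadataSet, scheme: Scheme) -> list[ValidationIssue]:
    """Check sheets, columns and row counts against the scheme."""
    issues: list[ValidationIssue] = []
    if meta.scheme_name != scheme.name:
        issues.append(issue(
            "STRUCT_SCHEME_MISMATCH", ("", "", 0),
            f"metadata declares scheme {meta.scheme_name!r}, expected {scheme.name!r}",
        ))
    if meta.scheme_version != scheme.version:
        issues.append(issue(
            "STRUCT_SCHEME_MISMATCH", ("", "", 0),
            f"metadata declares version {meta.scheme_version!r}, "
            f"expected {scheme.version!r}",
        ))

    known = set(scheme.set_names())
    for ps in scheme.property_sets:
        if ps.name not in meta.tables:
            issues.append(issue(
                "STRUCT_MISSING_SET", (ps.name, "", 0),
                f"property set {ps.name!r} is missing from the metadata",
            ))
            continue
        rows = meta.tables[ps.name]
        if rows:
            cols = _table_columns(rows)
            for name in ps.property_names():
                if name not in cols:
                    issues.append(issue(
                        "STRUCT_MISSING_PROPERTY", (ps.name, name, 0),
                        f"column {name!r} is missing from sheet {ps.name!r}",
                    ))
            for col in cols:
                if col not in ps.property_names():
                    issues.append(issue(
                        "STRUCT_UNKNOWN_PROPERTY", (ps.name, col, 0),
                        f"sheet {ps.name!r} has a column {col!r} not in the scheme",
                    ))
        if ps.cardinality == "exactly-one-row":
            if len(rows) == 0:
                issues.append(issue(
                    "STRUCT_ROW_COUNT", (ps.name, "", 0),
                    f"sheet {ps.name!r} must have exactly one data row, found none",
                ))
            else:
                for idx in range(2, len(rows) + 1):
                    issues.append(issue(
                        "STRUCT_ROW_COUNT", (ps.name, "", idx),
                        f"sheet {ps.name!r} must have exactly one data row; "
                        f"row {idx} is extra",
                    ))
    for name in meta.tables:
        if name not in known:
            issues.append(issue(
                "STRUCT_UNKNOWN_SET", (name, "", 0),
                f"sheet {name!r} is not part of scheme {scheme.name!r}",
            ))
    return issues


def suppressed_tables(structure_issues: list[ValidationIssue]) -> set[str]:
    """Tables whose later-stage checks are suppressed by structure errors."""
    return {
        i.location[0]
        for i in structure_issues
        if i.severity is Severity.ERROR and i.location[0]
    }


# ---------------------------------------------------------------------------
# stage 2: values


def validate_values(
    meta: MetadataSet,
    scheme: Scheme,
    suppressed: Optional[set[str]] = None,
) -> list[ValidationIssue]:
    """Per-cell checks: required, type, allowed/suggested vocabulary, range."""
    if suppressed is None:
        suppressed = suppressed_tables(validate_structure(meta, scheme))
    issues: list[ValidationIssue] = []
    for ps in scheme.property_sets:
        if ps.name in suppressed or ps.name not in meta.tables:
            continue
        for ridx, row in enumerate(meta.tables[ps.name], start=1):
            for p in ps.properties:
                raw = row.get(p.name, "")
                loc = (ps.name, p.name, ridx)
                if raw == "":
                    if p.required:
                        issues.append(issue(
                            "VAL_REQUIRED_MISSING", loc,
                            f"required value {ps.name}.{p.name} is missing in row {ridx}",
                        ))
                    continue
                try:
                    value = parse_typed(raw, p.type)
                except ValueError:
                    issues.append(issue(
                        "VAL_TYPE", loc,
                        f"value {raw!r} does not parse as {p.type}",
                    ))
                    continue
                if p.allowed_values and raw not in p.allowed_values:
                    issues.append(issue(
                        "VAL_NOT_ALLOWED", loc,
                        f"value {raw!r} is not in the allowed values of "
                        f"{ps.name}.{p.name}",
                    ))
                elif p.suggested_values and raw not in p.suggested_values:
                    issues.append(issue(
                        "VAL_NOT_SUGGESTED", loc,
                        f"value {raw!r} is not among the suggested values of "
                        f"{ps.name}.{p.name}",
                    ))
                if p.type in ("integer", "real"):
                    if (p.min_value is not None and value < p.min_value) or (
                        p.max_value is not None and value > p.max_value
                    ):
                        lo = "-inf" if p.min_value is None else p.min_value
                        hi = "inf" if p.max_value is None else p.max_value
                        issues.append(issue(
                            "VAL_RANGE", loc,
                            f"value {raw!r} outside range [{lo}, {hi}]",
                        ))
    return issues


# ---------------------------------------------------------------------------
# stage 3: internal consistency


def validate_consistency(
    meta: MetadataSet,
    scheme: Scheme,
    suppressed: Optional[set[str]] = None,
) -> list[ValidationIssue]:
    """Cross-reference resolution, key uniqueness, one method per data file."""
    if suppressed is None:
        suppressed = suppressed_tables(validate_structure(meta, scheme))
    issues: list[ValidationIssue] = []

    def usable(set_name: str) -> bool:
        return set_name in meta.tables and set_name not in suppressed

    # cross-references: every non-empty value must occur in the target column
    for ps in scheme.property_sets:
        if not usable(ps.name):
            continue
        for p in ps.properties:
            if p.refers_to is None:
                continue
            tgt_set, tgt_prop = p.refers_to
            if not usable(tgt_set):
                continue  # the structural error is already reported
            targets = {
                row.get(tgt_prop, "")
                for row in meta.tables[tgt_set]
                if row.get(tgt_prop, "")
            }
            for ridx, row in enumerate(meta.tables[ps.name], start=1):
                v = row.get(p.name, "")
                if v and v not in targets:
                    issues.append(issue(
                        "CONS_DANGLING_REF", (ps.name, p.name, ridx),
                        f"{ps.name}.{p.name} row {ridx} references {v!r}, "
                        f"absent from {tgt_set}.{tgt_prop}",
                    ))

    d = scheme.data_files
    file_set = d.file_set if d else None
    column_set = d.column_set if d else None

    # duplicate keys, keyed by the first property of the set; the designated
    # data-file set is covered by the stronger one-method rule below, and the
    # column set is keyed by the (file, column) pair instead
    for ps in scheme.property_sets:
        if not usable(ps.name) or not ps.properties:
            continue
        if ps.name == file_set:
            continue
        if ps.name == column_set and d is not None:
            seen_pairs: set[tuple[str, str]] = set()
            for ridx, row in enumerate(meta.tables[ps.name], start=1):
                pair = (
                    row.get(d.column_file_property, ""),
                    row.get(d.column_name_property, ""),
                )
                if all(pair) and pair in seen_pairs:
                    issues.append(issue(
                        "CONS_DUPLICATE_KEY",
                        (ps.name, d.column_name_property, ridx),
                        f"column {pair[1]!r} of file {pair[0]!r} is declared twice",
                    ))
                seen_pairs.add(pair)
            continue
        key = ps.properties[0].name
        seen: set[str] = set()
        for ridx, row in enumerate(meta.tables[ps.name], start=1):
            v = row.get(key, "")
            if v and v in seen:
                issues.append(issue(
                    "CONS_DUPLICATE_KEY", (ps.name, key, ridx),
                    f"key value {v!r} occurs more than once in {ps.name}.{key}",
                ))
            seen.add(v)

    # one measurement and extraction method per data file: a file name may
    # appear in only one row of the data-file set
    if d is not None and usable(d.file_set):
        seen_files: set[str] = set()
        for ridx, row in enumerate(meta.tables[d.file_set], start=1):
            v = row.get(d.file_property, "")
            if v and v in seen_files:
                issues.append(issue(
                    "CONS_MULTIPLE_METHODS", (d.file_set, d.file_property, ridx),
                    f"data file {v!r} is listed in more than one row of "
                    f"{d.file_set}; only one measurement and extraction "
                    f"method per data file is allowed",
                ))
            seen_files.add(v)
    return issues


# ---------------------------------------------------------------------------
# stage 4: structural metadata vs the actual data files


def _sniff_delimiter(path: Path, override: Optional[str]) -> str:
    if override:
        return override
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def validate_data_files(
    meta: MetadataSet,
    scheme: Scheme,
    data_dir,
    delimiter: Optional[str] = None,
    max_rows: Optional[int] = None,
    suppressed: Optional[set[str]] = None,
) -> list[ValidationIssue]:
    """Check declared files/columns/types against the files on disk.

    ``max_rows`` caps how many data rows per file are type-checked (all
    rows by default; the files are desk-scale).
    """
    d = scheme.data_files
    if d is None:
        return []
    if suppressed is None:
        suppressed = suppressed_tables(validate_structure(meta, scheme))
    if (
        d.file_set in suppressed
        or d.column_set in suppressed
        or d.file_set not in meta.tables
        or d.column_set not in meta.tables
    ):
        return []  # the structural problem is already reported
    data_dir = Path(data_dir)
    if not data_dir.is_dir():
        raise IOError(f"data directory not readable: {data_dir}")

    issues: list[ValidationIssue] = []
    declared: dict[str, int] = {}
    for ridx, row in enumerate(meta.tables[d.file_set], start=1):
        name = row.get(d.file_property, "")
        if name and name not in declared:
            declared[name] = ridx

    present = sorted(p.name for p in data_dir.iterdir() if p.is_file())
    for fname in present:
        if fname not in declared:
            issues.append(issue(
                "DATA_FILE_UNDECLARED", (d.file_set, d.file_property, 0),
                f"file {fname!r} is present in {data_dir} but not declared",
            ))

    # declared columns: file -> list of (column name, column type, declaring row)
    columns: dict[str, list[tuple[str, str, int]]] = {}
    for ridx, row in enumerate(meta.tables[d.column_set], start=1):
        fname = row.get(d.column_file_property, "")
        cname = row.get(d.column_name_property, "")
        ctype = row.get(d.column_type_property, "")
        if fname and cname:
            columns.setdefault(fname, []).append((cname, ctype, ridx))

    for fname, decl_row in declared.items():
        fpath = data_dir / fname
        if not fpath.is_file():
            issues.append(issue(
                "DATA_FILE_MISSING", (d.file_set, d.file_property, decl_row),
                f"declared data file {fname!r} is missing from {data_dir}",
            ))
            continue
        sep = _sniff_delimiter(fpath, delimiter)
        with open(fpath, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter=sep)
            header = next(reader, [])
            body = list(reader)
        if max_rows is not None:
            body = body[:max_rows]
        decl_cols = columns.get(fname, [])
        decl_names = [c for c, _, _ in decl_cols]
        for cname, ctype, crow in decl_cols:
            if cname not in header:
                issues.append(issue(
                    "DATA_COLUMN_MISSING", (d.column_set, d.column_name_property, crow),
                    f"declared column {cname!r} is absent from the header of {fname!r}",
                ))
        for col in header:
            if col not in decl_names:
                issues.append(issue(
                    "DATA_COLUMN_UNDECLARED", (d.column_set, d.column_name_property, 0),
                    f"header column {col!r} of {fname!r} is not declared",
                ))
        for cname, ctype, crow in decl_cols:
            if cname not in header or ctype not in ("integer", "real", "logical", "date"):
                continue  # character always passes; bad ctype is a value-stage issue
            j = header.index(cname)
            for row in body:
                v = row[j].strip() if j < len(row) else ""
                if v == "":
                    continue
                try:
                    parse_typed(v, ctype)
                except ValueError:
                    issues.append(issue(
                        "DATA_COLUMN_TYPE", (d.column_set, d.column_type_property, crow),
                        f"column {cname!r} of {fname!r} declared {ctype} but "
                        f"holds {v!r}",
                    ))
                    break
    return issues


# ---------------------------------------------------------------------------
# the pipeline and the report renderer


def validate_all(
    meta: MetadataSet,
    scheme: Scheme,
    data_dir=None,
    delimiter: Optional[str] = None,
    max_rows: Optional[int] = None,
) -> ValidationReport:
    """Run all stages in order and assemble the report.

    The data-file stage is skipped when ``data_dir`` is None.
    """
    structure = validate_structure(meta, scheme)
    skip = suppressed_tables(structure)
    stages = {
        "structure": structure,
        "values": validate_values(meta, scheme, suppressed=skip),
        "consistency": validate_consistency(meta, scheme, suppressed=skip),
    }
    if data_dir is not None:
        stages["data_files"] = validate_data_files(
            meta, scheme, data_dir, delimiter=delimiter,
            max_rows=max_rows, suppressed=skip,
        )
    return ValidationReport(
        scheme_id=(meta.scheme_name, meta.scheme_version), stages=stages
    )


_STAGE_TITLES = {
    "structure": "Structure",
    "values": "Values",
    "consistency": "Consistency",
    "data_files": "Data files",
}


def _sections(report: ValidationReport):
    """(stage, propertySet, issues) triples in stable order."""
    for stage in STAGES:
        stage_issues = report.stages.get(stage)
        if stage_issues is None:
            continue
        by_set: dict[str, list[ValidationIssue]] = {}
        for i in stage_issues:
            by_set.setdefault(i.location[0] or "(scheme)", []).append(i)
        yield stage, by_set


def render_report(report: ValidationReport, format: str = "markdown") -> str:
    """Render the report as a markdown or HTML document (deterministic)."""
    if format not in ("markdown", "html"):
        raise UsageError(f"unsupported report format: {format!r}")
    c = report.counts()
    summary = f"{c['error']} errors / {c['warning']} warnings / {c['note']} notes"
    name, version = report.scheme_id

    if format == "markdown":
        lines = [
            f"# Validation report — {name} {version}",
            "",
            f"**Result:** {report.worst_severity}",
            "",
            f"**Summary:** {summary}",
            "",
        ]
        for stage, by_set in _sections(report):
            lines.append(f"## {_STAGE_TITLES[stage]}")
            lines.append("")
            if not by_set:
                lines.append("No issues.")
                lines.append("")
                continue
            for set_name, items in by_set.items():
                lines.append(f"### {set_name}")
                lines.append("")
                for i in items:
                    ps, prop, ridx = i.location
                    where = ".".join(x for x in (ps, prop) if x)
                    if ridx:
                        where += f" (row {ridx})"
                    lines.append(
                        f"- **{i.severity}** `{i.code}` {where}: {i.message}"
                    )
                lines.append("")
        return "\n".join(lines)

    esc = _html.escape
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>Validation report — {esc(name)} {esc(version)}</title>",
        "</head><body>",
        f"<h1>Validation report — {esc(name)} {esc(version)}</h1>",
        f"<p><strong>Result:</strong> {esc(report.worst_severity)}</p>",
        f"<p><strong>Summary:</strong> {esc(summary)}</p>",
    ]
    for stage, by_set in _sections(report):
        parts.append(f"<h2>{esc(_STAGE_TITLES[stage])}</h2>")
        if not by_set:
            parts.append("<p>No issues.</p>")
            continue
        for set_name, items in by_set.items():
            parts.append(f"<h3>{esc(set_name)}</h3><ul>")
            for i in items:
                ps, prop, ridx = i.location
                where = ".".join(x for x in (ps, prop) if x)
                if ridx:
                    where += f" (row {ridx})"
                parts.append(
                    f"<li><span class='{i.severity}'><strong>{i.severity}"
                    f"</strong></span> <code>{esc(i.code)}</code> "
                    f"{esc(where)}: {esc(i.message)}</li>"
                )
            parts.append("</ul>")
    parts.append("</body></html>")
    return "\n".join(parts)
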