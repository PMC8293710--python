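"""XML serialization of validated metadata.

Export is gated on validation: any error-level issue refuses the export
(notes and warnings are tolerated).  Two shapes are produced:

* a single combined document — one element per property set, rows as
  repeated ``<row>`` elements, properties as leaf elements; and
* one document per data file, with the experiment-level (exactly-one-row)
  sets replicated into each document and the rows of multi-row sets
  narrowed to the records that concern that file, following the declared
  cross-reference chains outward from the data-file set.  Records that
  reference no data file at all are included in every document, so each
  per-file document is self-contained.

Documents are UTF-8, two-space indented, attributes sorted — byte-stable
for a given metadata set.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional

from .errors import ExportRefusedError, XmlFormatError
from .scheme_model import MetadataSet, Scheme
from .validation import validate_all

NAMESPACE_PREFIX = "urn:dmdscheme:"


def namespace_uri(scheme: Scheme) -> str:
    return f"{NAMESPACE_PREFIX}{scheme.name}:{scheme.version}"


def _check_gate(meta: MetadataSet, scheme: Scheme, data_dir) -> None:
    report = validate_all(meta, scheme, data_dir=data_dir)
    n_errors = report.counts()["error"]
    if n_errors:
        raise ExportRefusedError(
            f"validation found {n_errors} error(s); export refused until the "
            f"metadata validates without errors"
        )


def _build_element(
    meta: MetadataSet,
    scheme: Scheme,
    row_filter: Optional[dict[str, list[int]]] = None,
) -> ET.Element:
    """Build the document tree; ``row_filter`` maps set name -> kept row
    indices (0-based); sets absent from the filter keep all rows."""
    root = ET.Element(scheme.name)
    # attribute insertion in sorted order keeps serialization stable
    root.set("schemeNamespace", namespace_uri(scheme))
    root.set("schemeVersion", scheme.version)
    for ps in scheme.property_sets:
        set_el = ET.SubElement(root, ps.name)
        rows = meta.tables.get(ps.name, [])
        keep = None if row_filter is None else row_filter.get(ps.name)
        for idx, row in enumerate(rows):
            if keep is not None and idx not in keep:
                continue
            row_el = ET.SubElement(set_el, "row")
            for p in ps.properties:
                v = row.get(p.name, "")
                if v != "":  # missing values are absent elements
                    ET.SubElement(row_el, p.name).text = v
    return root


def _serialize(root: ET.Element) -> bytes:
    tree = ET.ElementTree(root)
    ET.indent(tree, space="  ")
    import io

    buf = io.BytesIO()
    tree.write(buf, encoding="utf-8", xml_declaration=True)
    return buf.getvalue() + b"\n"


def export_xml(meta: MetadataSet, scheme: Scheme, data_dir=None) -> bytes:
    """Serialize the full metadata set to one combined XML document.

    Refuses (raises :class:`ExportRefusedError`) when validation reports
    any error-level issue.
    """
    _check_gate(meta, scheme, data_dir)
    return _serialize(_build_element(meta, scheme))


def read_xml(source) -> MetadataSet:
    """Inverse of :func:`export_xml` (up to the missing-value convention).

    ``source`` may be bytes, an XML string, or a path to a document
    produced by :func:`export_xml`.
    """
    if isinstance(source, bytes):
        text = source
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        text = source
    else:
        text = Path(source).read_bytes()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise XmlFormatError(f"malformed XML: {exc}") from exc
    ns = root.get("schemeNamespace", "")
    version = root.get("schemeVersion")
    if version is None or not ns.startswith(NAMESPACE_PREFIX):
        raise XmlFormatError(
            f"root element {root.tag!r} is not a dmdkit metadata document"
        )
    tables: dict[str, list[dict[str, str]]] = {}
    for set_el in root:
        rows = [
            {leaf.tag: (leaf.text or "") for leaf in row_el}
            for row_el in set_el
            if row_el.tag == "row"
        ]
        tables[set_el.tag] = rows
    return MetadataSet(scheme_name=root.tag, scheme_version=version, tables=tables)


# ---------------------------------------------------------------------------
# per-data-file export


def _scoped_rows(meta: MetadataSet, scheme: Scheme, fname: str) -> dict[str, list[int]]:
    """Row indices (0-based) of each multi-row set scoped to data file
    ``fname`` by following refersTo chains from the data-file set outward.

    Sets never reached by a chain are left out of the mapping, meaning
    *all* their rows are kept (conservative completeness).  Exactly-one-row
    sets are always kept whole.
    """
    d = scheme.data_files
    assert d is not None
    scoped: dict[str, set[int]] = {
        d.file_set: {
            i
            for i, row in enumerate(meta.tables.get(d.file_set, []))
            if row.get(d.file_property, "") == fname
        }
    }
    edges = [
        (ps.name, p.name, p.refers_to[0], p.refers_to[1])
        for ps in scheme.property_sets
        for p in ps.properties
        if p.refers_to is not None
    ]
    changed = True
    while changed:
        changed = False
        for src_set, src_prop, tgt_set, tgt_prop in edges:
            src_rows = meta.tables.get(src_set, [])
            tgt_rows = meta.tables.get(tgt_set, [])
            if tgt_set in scoped and src_set not in scoped:
                # downstream: keep source rows that point into the scoped target
                keys = {
                    tgt_rows[i].get(tgt_prop, "")
                    for i in scoped[tgt_set]
                    if i < len(tgt_rows)
                }
                scoped[src_set] = {
                    i
                    for i, row in enumerate(src_rows)
                    if row.get(src_prop, "") in keys
                }
                changed = True
            elif src_set in scoped and tgt_set not in scoped:
                # upstream: keep target rows referenced by the scoped source
                refs = {
                    src_rows[i].get(src_prop, "")
                    for i in scoped[src_set]
                    if i < len(src_rows)
                }
                scoped[tgt_set] = {
                    i
                    for i, row in enumerate(tgt_rows)
                    if row.get(tgt_prop, "") in refs
                }
                changed = True
    one_row_sets = {
        ps.name for ps in scheme.property_sets if ps.cardinality == "exactly-one-row"
    }
    return {
        name: sorted(rows)
        for name, rows in scoped.items()
        if name not in one_row_sets
    }


def export_xml_per_datafile(
    meta: MetadataSet, scheme: Scheme, out_dir, data_dir=None
) -> dict[str, Path]:
    """Write one XML document per declared data file into ``out_dir``.

    Returns a mapping from data-file name to the written document path.
    Experiment-level sets are replicated verbatim into every document.
    """
    _check_gate(meta, scheme, data_dir)
    d = scheme.data_files
    if d is None:
        return {}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    for row in meta.tables.get(d.file_set, []):
        name = row.get(d.file_property, "")
        if name and name not in files:
            files.append(name)
    written: dict[str, Path] = {}
    for fname in files:
        target = out_dir / f"{fname}.xml"
        if target in written.values():
            raise IOError(f"output name collision: {target}")
        root = _build_element(meta, scheme, row_filter=_scoped_rows(meta, scheme, fname))
        target.write_bytes(_serialize(root))
        written[fname] = target
    return written


# ---------------------------------------------------------------------------
# EML mapping hook


def eml_mapping_stub(scheme: Scheme, mapping: dict[str, str]) -> dict[str, list[str]]:
    """Coverage report for a property → EML-path mapping table.

    Property paths are written ``Set/Property``.  No EML is emitted; this
    only reports which scheme properties are mapped, which are not, and
    which mapping keys dangle (name no existing property).
    """
    paths = [
        f"{ps.name}/{p.name}" for ps in scheme.property_sets for p in ps.properties
    ]
    mapped = [p for p in paths if p in mapping]
    unmapped = [p for p in paths if p not in mapping]
    dangling = sorted(k for k in mapping if k not in paths)
    return {"mapped": mapped, "unmapped": unmapped, "dangling": dangling}
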