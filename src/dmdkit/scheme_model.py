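"""In-memory model of domain-specific metadata schemes and filled metadata.

A *scheme* is a named, versioned collection of *property sets*; each
property set groups related metadata *properties* (one worksheet per set
when rendered as a workbook).  Filled metadata is held as a
:class:`MetadataSet`: raw string values, exactly as entered, keyed by
property-set and property name.  Typing, vocabularies and ranges are only
interpreted by the validation stage — never at construction time — so a
half-filled workbook can always be read back without loss.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional

from .errors import SchemeDefinitionError

#: the closed type system for property values
TYPES = ("character", "integer", "real", "logical", "date")

#: how many rows a property-set table may carry
CARDINALITIES = ("exactly-one-row", "zero-or-more-rows")

_SEMVER_RE = re.compile(r"^(\d+)\.(\d+)\.(\d+)(?:-([0-9A-Za-z.\-]+))?$")
_LOGICAL_TOKENS = {"TRUE", "FALSE", "True", "False", "true", "false"}


def parse_semver(version: str) -> tuple[int, int, int, Optional[str]]:
    """Parse ``major.minor.patch[-prerelease]``; raise on anything else."""
    m = _SEMVER_RE.match(version or "")
    if not m:
        raise SchemeDefinitionError(f"not a semantic version: {version!r}")
    return int(m.group(1)), int(m.group(2)), int(m.group(3)), m.group(4)


def semver_key(version: str) -> tuple[int, int, int]:
    """Numeric ordering key (pre-release tag ignored)."""
    major, minor, patch, _ = parse_semver(version)
    return major, minor, patch


def is_prerelease(version: str) -> bool:
    return parse_semver(version)[3] is not None


def parse_typed(raw: str, type_: str):
    """Convert a raw cell string to its typed value; ValueError on failure.

    ``character`` accepts anything; ``integer`` a decimal integer; ``real``
    a float; ``logical`` TRUE/FALSE (any common capitalisation); ``date``
    an ISO-8601 calendar date (YYYY-MM-DD).
    """
    if type_ == "character":
        return raw
    if type_ == "integer":
        try:
            return int(raw)
        except ValueError:
            raise ValueError(f"not an integer: {raw!r}")
    if type_ == "real":
        return float(raw)
    if type_ == "logical":
        if raw in _LOGICAL_TOKENS:
            return raw.lower() == "true"
        raise ValueError(f"not a logical (TRUE/FALSE): {raw!r}")
    if type_ == "date":
        return date.fromisoformat(raw)
    raise ValueError(f"unknown type {type_!r}")


def _valid_identifier(name: str) -> bool:
    return bool(name) and not any(ch.isspace() for ch in name)


@dataclass
class Property:
    """One metadata field of a property set."""

    name: str
    description: str = ""
    type: str = "character"
    required: bool = False
    allowed_values: tuple[str, ...] = ()
    suggested_values: tuple[str, ...] = ()
    min_value: Optional[float] = None
    max_value: Optional[float] = None
    refers_to: Optional[tuple[str, str]] = None  # (propertySetName, propertyName)
    example: Optional[str] = None

    def __post_init__(self) -> None:
        self.allowed_values = tuple(self.allowed_values)
        self.suggested_values = tuple(self.suggested_values)
        if self.refers_to is not None:
            self.refers_to = (self.refers_to[0], self.refers_to[1])


@dataclass
class PropertySet:
    """A named group of properties, rendered as one worksheet."""

    name: str
    description: str = ""
    cardinality: str = "zero-or-more-rows"
    properties: list[Property] = field(default_factory=list)

    def property(self, name: str) -> Property:
        for p in self.properties:
            if p.name == name:
                return p
        raise KeyError(name)

    def property_names(self) -> list[str]:
        return [p.name for p in self.properties]


@dataclass
class DataFileDesignation:
    """Marks which property sets describe the data files themselves.

    ``file_set``/``file_property`` name the table and column listing the
    data-file names (one row per file, carrying its measurement and
    extraction method); ``column_set`` lists the columns of each file as
    (file, column name, column type) rows.
    """

    file_set: str
    file_property: str
    column_set: str
    column_file_property: str
    column_name_property: str
    column_type_property: str


@dataclass
class Scheme:
    """A named, versioned, ordered collection of property sets."""

    name: str
    version: str
    description: str = ""
    property_sets: list[PropertySet] = field(default_factory=list)
    data_files: Optional[DataFileDesignation] = None

    @property
    def identifier(self) -> str:
        return f"{self.name}_{self.version}"

    def property_set(self, name: str) -> PropertySet:
        for ps in self.property_sets:
            if ps.name == name:
                return ps
        raise KeyError(name)

    def set_names(self) -> list[str]:
        return [ps.name for ps in self.property_sets]


@dataclass(eq=False)
class MetadataSet:
    """Filled metadata: raw string tables tied to a scheme name + version.

    The empty string is the missing value; no other sentinel exists.  Two
    metadata sets compare equal when their scheme identity matches and
    their tables agree after dropping empty-string entries and empty
    tables (missing and empty are the same thing).
    """

    scheme_name: str
    scheme_version: str
    tables: dict[str, list[dict[str, str]]] = field(default_factory=dict)

    def normalized_tables(self) -> dict[str, list[dict[str, str]]]:
        out: dict[str, list[dict[str, str]]] = {}
        for name, rows in self.tables.items():
            norm = [{k: v for k, v in row.items() if v != ""} for row in rows]
            if norm:
                out[name] = norm
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetadataSet):
            return NotImplemented
        return (
            self.scheme_name == other.scheme_name
            and self.scheme_version == other.scheme_version
            and self.normalized_tables() == other.normalized_tables()
        )


# ---------------------------------------------------------------------------
# operations


def new_template_scheme(name: str, version: str) -> Scheme:
    """Return the minimal generic scheme from which domain schemes are grown.

    The template carries a single exactly-one-row set ``Metadata`` with the
    three fields any dataset needs: Title, Author, Date.
    """
    if not _valid_identifier(name):
        raise SchemeDefinitionError(f"invalid scheme name: {name!r}")
    parse_semver(version)
    return Scheme(
        name=name,
        version=version,
        description="Template metadata scheme; extend with domain property sets.",
        property_sets=[
            PropertySet(
                name="Metadata",
                description="Core metadata about the dataset as a whole.",
                cardinality="exactly-one-row",
                properties=[
                    Property("Title", "Title of the dataset.", "character", True),
                    Property("Author", "Person responsible for the dataset.", "character", True),
                    Property("Date", "Date of creation (YYYY-MM-DD).", "date", True),
                ],
            )
        ],
    )


def check_scheme_definition(scheme: Scheme) -> list[str]:
    """Return the list of well-formedness problems (empty iff well-formed).

    Each problem string names the offending property set / property and the
    rule that was broken; nothing is raised.
    """
    problems: list[str] = []

    if not _valid_identifier(scheme.name):
        problems.append(f"scheme: invalid name {scheme.name!r}")
    try:
        parse_semver(scheme.version)
    except SchemeDefinitionError:
        problems.append(f"scheme: invalid version {scheme.version!r}")

    seen_sets: set[str] = set()
    for ps in scheme.property_sets:
        loc = f"property set {ps.name!r}"
        if not _valid_identifier(ps.name):
            problems.append(f"{loc}: invalid name (empty or contains whitespace)")
        if ps.name in seen_sets:
            problems.append(f"{loc}: duplicate property-set name")
        seen_sets.add(ps.name)
        if ps.cardinality not in CARDINALITIES:
            problems.append(f"{loc}: unknown cardinality {ps.cardinality!r}")
        if not ps.properties:
            problems.append(f"{loc}: has no properties")

        seen_props: set[str] = set()
        for p in ps.properties:
            ploc = f"{ps.name}.{p.name}"
            if not _valid_identifier(p.name):
                problems.append(f"{ploc}: invalid property name")
            if p.name in seen_props:
                problems.append(f"{ploc}: duplicate property name")
            seen_props.add(p.name)
            if p.type not in TYPES:
                problems.append(f"{ploc}: unknown type {p.type!r}")
            if p.allowed_values and p.suggested_values:
                problems.append(
                    f"{ploc}: allowedValues and suggestedValues are both non-empty"
                )
            numeric = p.type in ("integer", "real")
            if (p.min_value is not None or p.max_value is not None) and not numeric:
                problems.append(f"{ploc}: range given for non-numeric type {p.type!r}")
            if p.min_value is not None and p.max_value is not None:
                if p.min_value > p.max_value:
                    problems.append(f"{ploc}: minValue exceeds maxValue")
            if p.type in TYPES:
                for v in (*p.allowed_values, *p.suggested_values):
                    try:
                        parse_typed(v, p.type)
                    except ValueError:
                        problems.append(
                            f"{ploc}: vocabulary value {v!r} does not parse as {p.type}"
                        )

    # cross-references resolve inside the scheme
    for ps in scheme.property_sets:
        for p in ps.properties:
            if p.refers_to is None:
                continue
            tgt_set, tgt_prop = p.refers_to
            ploc = f"{ps.name}.{p.name}"
            try:
                target = scheme.property_set(tgt_set)
            except KeyError:
                problems.append(f"{ploc}: refersTo names missing property set {tgt_set!r}")
                continue
            if tgt_prop not in target.property_names():
                problems.append(
                    f"{ploc}: refersTo names missing property {tgt_set}.{tgt_prop}"
                )

    d = scheme.data_files
    if d is not None:
        for set_name, prop_name, what in (
            (d.file_set, d.file_property, "data-file"),
            (d.column_set, d.column_file_property, "column/file"),
            (d.column_set, d.column_name_property, "column/name"),
            (d.column_set, d.column_type_property, "column/type"),
        ):
            try:
                ps = scheme.property_set(set_name)
            except KeyError:
                problems.append(
                    f"data-file designation: missing property set {set_name!r}"
                )
                continue
            if prop_name not in ps.property_names():
                problems.append(
                    f"data-file designation ({what}): missing property "
                    f"{set_name}.{prop_name}"
                )
    return problems


def add_property_set(scheme: Scheme, ps: PropertySet) -> Scheme:
    """Return a new scheme extended with ``ps``; the input is unmodified."""
    if ps.name in scheme.set_names():
        raise SchemeDefinitionError(f"property set {ps.name!r} already exists")
    out = copy.deepcopy(scheme)
    out.property_sets.append(copy.deepcopy(ps))
    return out


def add_property(scheme: Scheme, set_name: str, p: Property) -> Scheme:
    """Return a new scheme with ``p`` appended to the named property set."""
    try:
        target = scheme.property_set(set_name)
    except KeyError:
        raise SchemeDefinitionError(f"no property set named {set_name!r}")
    if p.name in target.property_names():
        raise SchemeDefinitionError(f"property {set_name}.{p.name} already exists")
    out = copy.deepcopy(scheme)
    out.property_set(set_name).properties.append(copy.deepcopy(p))
    return out


def remove_property_set(scheme: Scheme, set_name: str) -> Scheme:
    """Inverse of :func:`add_property_set` (fixture/test helper)."""
    if set_name not in scheme.set_names():
        raise SchemeDefinitionError(f"no property set named {set_name!r}")
    out = copy.deepcopy(scheme)
    out.property_sets = [ps for ps in out.property_sets if ps.name != set_name]
    return out


# ---------------------------------------------------------------------------
# JSON manifest (the machine-readable scheme serialization inside packages)


def scheme_to_dict(scheme: Scheme) -> dict:
    def prop(p: Property) -> dict:
        d: dict = {
            "name": p.name,
            "description": p.description,
            "type": p.type,
            "required": p.required,
            "allowedValues": list(p.allowed_values),
            "suggestedValues": list(p.suggested_values),
        }
        if p.min_value is not None:
            d["minValue"] = p.min_value
        if p.max_value is not None:
            d["maxValue"] = p.max_value
        if p.refers_to is not None:
            d["refersTo"] = {"propertySet": p.refers_to[0], "property": p.refers_to[1]}
        if p.example is not None:
            d["example"] = p.example
        return d

    out: dict = {
        "name": scheme.name,
        "version": scheme.version,
        "description": scheme.description,
        "propertySets": [
            {
                "name": ps.name,
                "description": ps.description,
                "cardinality": ps.cardinality,
                "properties": [prop(p) for p in ps.properties],
            }
            for ps in scheme.property_sets
        ],
    }
    if scheme.data_files is not None:
        d = scheme.data_files
        out["dataFileDesignation"] = {
            "fileSet": d.file_set,
            "fileProperty": d.file_property,
            "columnSet": d.column_set,
            "columnFileProperty": d.column_file_property,
            "columnNameProperty": d.column_name_property,
            "columnTypeProperty": d.column_type_property,
        }
    return out


def scheme_from_dict(data: dict) -> Scheme:
    try:
        sets = [
            PropertySet(
                name=ps["name"],
                description=ps.get("description", ""),
                cardinality=ps.get("cardinality", "zero-or-more-rows"),
                properties=[
                    Property(
                        name=p["name"],
                        description=p.get("description", ""),
                        type=p.get("type", "character"),
                        required=p.get("required", False),
                        allowed_values=tuple(p.get("allowedValues", ())),
                        suggested_values=tuple(p.get("suggestedValues", ())),
                        min_value=p.get("minValue"),
                        max_value=p.get("maxValue"),
                        refers_to=(
                            (p["refersTo"]["propertySet"], p["refersTo"]["property"])
                            if "refersTo" in p
                            else None
                        ),
                        example=p.get("example"),
                    )
                    for p in ps.get("properties", ())
                ],
            )
            for ps in data.get("propertySets", ())
        ]
        designation = None
        if "dataFileDesignation" in data:
            d = data["dataFileDesignation"]
            designation = DataFileDesignation(
                file_set=d["fileSet"],
                file_property=d["fileProperty"],
                column_set=d["columnSet"],
                column_file_property=d["columnFileProperty"],
                column_name_property=d["columnNameProperty"],
                column_type_property=d["columnTypeProperty"],
            )
        return Scheme(
            name=data["name"],
            version=data["version"],
            description=data.get("description", ""),
            property_sets=sets,
            data_files=designation,
        )
    except (KeyError, TypeError) as exc:
        raise SchemeDefinitionError(f"malformed scheme manifest: {exc}") from exc


def scheme_to_json(scheme: Scheme) -> str:
    return json.dumps(scheme_to_dict(scheme), indent=2, sort_keys=True) + "\n"


def scheme_from_json(text: str) -> Scheme:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemeDefinitionError(f"scheme manifest is not valid JSON: {exc}") from exc
    return scheme_from_dict(data)


def load_scheme(path) -> Scheme:
    """Read a scheme manifest (JSON) from disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return scheme_from_json(fh.read())


def save_scheme(scheme: Scheme, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(scheme_to_json(scheme))
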