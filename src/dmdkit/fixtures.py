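"""Synthetic example scheme, filled metadata, toy data files, fault injection.

This module is the package's test oracle and demonstration material in
one.  It builds a realistic Experimental-Microbial-Ecology-style scheme
(``emeScheme`` 0.9.9: protist species, treatments, measurement and
extraction methods, data files and their columns), clean metadata that
validates with zero issues, matching toy CSV data files — and, on
request, seeds a precise number of violations of any validation rule,
returning the exact (code, severity, location) triples the validator must
report.

Fault seeding is allocated so that independently seeded faults occupy
disjoint cells/rows/tables and never mask each other.  Structure-level
faults that suppress downstream checks (deleting a sheet, removing a
column) are drawn only from tables that no other seeded rule needs; when
a specification cannot be realised this way, :class:`FixtureError` is
raised rather than producing an unreliable oracle.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FixtureError
from .scheme_model import (
    DataFileDesignation,
    MetadataSet,
    Property,
    PropertySet,
    Scheme,
)
from .validation import RULES, Severity

#: (code, severity, (propertySet, property, row)) — what the validator must emit
ExpectedIssue = tuple[str, Severity, tuple[str, str, int]]

_SPECIES_POOL = (
    "Tetrahymena thermophila",
    "Colpidium striatum",
    "Paramecium aurelia",
    "Euplotes daidaleos",
    "Didinium nasutum",
    "Loxocephalus sp.",
    "Spirostomum teres",
    "Blepharisma japonicum",
)
_MEDIA = ("PEA medium", "PPG medium", "WC medium")
_METHODS = ("flowcytometer", "microscope")
_SOFTWARE = ("ImageJ", "BEMOVI", "R-script")
_UNITS = ("cells/ml", "mg/l")

#: the three columns every toy data file declares: (name, type)
_FILE_COLUMNS = (("time", "integer"), ("speciesName", "character"), ("abundance", "real"))
_TYPED_COLUMNS = ("time", "abundance")
_TOY_ROWS = 5


@dataclass
class FaultSpec:
    """How many violations of each rule code to seed, plus the RNG seed."""

    counts: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for code, k in self.counts.items():
            if code not in RULES:
                raise FixtureError(f"unknown rule code in fault spec: {code!r}")
            if k < 0:
                raise FixtureError(f"negative fault count for {code}: {k}")

    def get(self, code: str) -> int:
        return self.counts.get(code, 0)


def make_example_scheme() -> Scheme:
    """The EME-style example scheme: 7 property sets, vocabularies, ranges,
    and cross-references (Treatment→Species, DataFiles→Measurement/
    DataExtraction, DataFileColumns→DataFiles)."""
    return Scheme(
        name="emeScheme",
        version="0.9.9",
        description=(
            "Metadata scheme for Experimental Microbial Ecology: the "
            "experiment, its species, treatments, measurement and data "
            "extraction methods, and the resulting data files."
        ),
        property_sets=[
            PropertySet(
                name="Experiment",
                description="The experiment as a whole (one row).",
                cardinality="exactly-one-row",
                properties=[
                    Property("Title", "Title of the experiment.", "character", True),
                    Property("Author", "Person who ran the experiment.", "character", True),
                    Property("StartDate", "First day of the experiment (YYYY-MM-DD).", "date"),
                    Property("Temperature", "Incubation temperature in degrees C.", "real",
                             min_value=0.0, max_value=40.0),
                    Property("NumCommunities", "Number of experimental communities.",
                             "integer", min_value=1, max_value=10000),
                    Property("Comment", "Free-text remarks.", "character"),
                ],
            ),
            PropertySet(
                name="Species",
                description="Organisms used in the experiment, one per row.",
                properties=[
                    Property("speciesName", "Binomial name of the organism.", "character", True),
                    Property("medium", "Culture medium the stock was kept in.", "character",
                             allowed_values=_MEDIA),
                    Property("strainId", "Laboratory strain identifier.", "character"),
                ],
            ),
            PropertySet(
                name="Treatment",
                description="Experimental treatments applied to communities.",
                properties=[
                    Property("treatmentName", "Short treatment label.", "character", True),
                    Property("species", "Species the treatment concerns.", "character",
                             refers_to=("Species", "speciesName")),
                    Property("concentration", "Nutrient concentration in g/l.", "real",
                             min_value=0.0, max_value=10.0),
                    Property("duration", "Duration of the treatment in days.", "integer"),
                ],
            ),
            PropertySet(
                name="Measurement",
                description="Measurement methods producing raw data.",
                properties=[
                    Property("measurementName", "Short measurement label.", "character", True),
                    Property("method", "Instrument or approach used.", "character",
                             suggested_values=_METHODS),
                    Property("unit", "Unit of the measured quantity.", "character"),
                ],
            ),
            PropertySet(
                name="DataExtraction",
                description="How analysis-ready data was extracted from raw data.",
                properties=[
                    Property("extractionName", "Short extraction label.", "character", True),
                    Property("software", "Software used for extraction.", "character",
                             suggested_values=_SOFTWARE),
                ],
            ),
            PropertySet(
                name="DataFiles",
                description=(
                    "One row per data file; exactly one measurement and one "
                    "extraction method per file."
                ),
                properties=[
                    Property("fileName", "Name of the delimited data file.", "character", True),
                    Property("measurement", "Measurement that produced this file.", "character",
                             refers_to=("Measurement", "measurementName")),
                    Property("extraction", "Extraction that produced this file.", "character",
                             refers_to=("DataExtraction", "extractionName")),
                    Property("description", "What the file contains.", "character"),
                ],
            ),
            PropertySet(
                name="DataFileColumns",
                description="One row per column of each data file.",
                properties=[
                    Property("fileName", "Data file the column belongs to.", "character", True,
                             refers_to=("DataFiles", "fileName")),
                    Property("columnName", "Header name of the column.", "character", True),
                    Property("columnType", "Type of the column's values.", "character", True,
                             allowed_values=("character", "integer", "real", "logical", "date")),
                    Property("description", "What the column contains.", "character"),
                ],
            ),
        ],
        data_files=DataFileDesignation(
            file_set="DataFiles",
            file_property="fileName",
            column_set="DataFileColumns",
            column_file_property="fileName",
            column_name_property="columnName",
            column_type_property="columnType",
        ),
    )


def _file_names(n: int) -> list[str]:
    return [f"exp{i + 1}_counts.csv" for i in range(n)]


def _clean_tables(n_species: int, n_data_files: int) -> dict[str, list[dict[str, str]]]:
    species = [
        _SPECIES_POOL[i] if i < len(_SPECIES_POOL) else f"Protistum synthicum {i + 1}"
        for i in range(n_species)
    ]
    files = _file_names(n_data_files)
    n_meas = max(2, n_data_files)
    tables: dict[str, list[dict[str, str]]] = {
        "Experiment": [{
            "Title": "Protist community warming experiment",
            "Author": "A. Researcher",
            "StartDate": "2021-03-15",
            "Temperature": "20.0",
            "NumCommunities": "24",
            "Comment": "",
        }],
        "Species": [
            {
                "speciesName": species[i],
                "medium": _MEDIA[i % len(_MEDIA)],
                "strainId": f"ST-{i + 1:03d}",
            }
            for i in range(n_species)
        ],
        "Treatment": [
            {
                "treatmentName": f"treatment_{i + 1:02d}",
                "species": species[i],
                "concentration": f"{(i % 5) * 1.5:.1f}",
                "duration": str(7 + i),
            }
            for i in range(n_species)
        ],
        "Measurement": [
            {
                "measurementName": f"measurement_{i + 1:02d}",
                "method": _METHODS[i % len(_METHODS)],
                "unit": _UNITS[i % len(_UNITS)],
            }
            for i in range(n_meas)
        ],
        "DataExtraction": [
            {"extractionName": "manual_count", "software": "ImageJ"},
            {"extractionName": "video_tracking", "software": "BEMOVI"},
        ],
        "DataFiles": [
            {
                "fileName": files[i],
                "measurement": f"measurement_{i + 1:02d}",
                "extraction": ("manual_count", "video_tracking")[i % 2],
                "description": f"Abundance counts from run {i + 1}",
            }
            for i in range(n_data_files)
        ],
        "DataFileColumns": [
            {
                "fileName": files[i],
                "columnName": cname,
                "columnType": ctype,
                "description": f"{cname} for run {i + 1}",
            }
            for i in range(n_data_files)
            for cname, ctype in _FILE_COLUMNS
        ],
    }
    return tables


# tables that structure-level faults may delete / strip a column from,
# and which other rules need intact
_DELETABLE = ("Experiment", "Species", "Treatment", "Measurement", "DataExtraction")
_REMOVABLE_COLUMN = {
    "Experiment": "Comment",
    "Species": "strainId",
    "Treatment": "duration",
    "Measurement": "unit",
    "DataExtraction": "software",
}
_NEEDED_TABLES = {
    "STRUCT_ROW_COUNT": {"Experiment"},
    "VAL_NOT_ALLOWED": {"Species"},
    "VAL_NOT_SUGGESTED": {"Measurement"},
    "VAL_TYPE": {"Treatment"},
    "VAL_RANGE": {"Treatment"},
    "VAL_REQUIRED_MISSING": {"Treatment"},
    "CONS_DANGLING_REF": {"Treatment", "Species"},
    "CONS_DUPLICATE_KEY": {"Species"},
}


def _plan_data_faults(spec: FaultSpec, files: list[str]) -> dict:
    """Deterministic allocation of data-file faults to disjoint sites."""
    plan = {
        "missing_files": [],
        "extra_files": [],
        "drop_columns": [],
        "extra_columns": [],
        "corrupt_type": [],
    }
    used: set[tuple[str, str]] = set()

    k = spec.get("DATA_FILE_MISSING")
    if k > len(files):
        raise FixtureError(
            f"cannot seed {k} DATA_FILE_MISSING faults with {len(files)} files"
        )
    plan["missing_files"] = list(files[len(files) - k:])
    surviving = [f for f in files if f not in plan["missing_files"]]

    plan["extra_files"] = [
        f"undeclared_{i + 1:02d}.csv" for i in range(spec.get("DATA_FILE_UNDECLARED"))
    ]

    def allocate(count: int, eligible_columns, bucket: str) -> None:
        taken = 0
        for fname in surviving:
            for cname in eligible_columns:
                if taken == count:
                    return
                if (fname, cname) in used:
                    continue
                used.add((fname, cname))
                plan[bucket].append((fname, cname))
                taken += 1
        if taken < count:
            raise FixtureError(
                f"cannot seed {count} faults of kind {bucket}: only {taken} sites"
            )

    allocate(spec.get("DATA_COLUMN_MISSING"), [c for c, _ in _FILE_COLUMNS], "drop_columns")
    allocate(spec.get("DATA_COLUMN_TYPE"), list(_TYPED_COLUMNS), "corrupt_type")
    n_undecl = spec.get("DATA_COLUMN_UNDECLARED")
    if n_undecl and not surviving:
        raise FixtureError("cannot seed DATA_COLUMN_UNDECLARED without any file")
    plan["extra_columns"] = [
        (surviving[i % len(surviving)], f"extra_{i + 1:02d}") for i in range(n_undecl)
    ]
    return plan


def _column_decl_row(files: list[str], fname: str, cname: str) -> int:
    fi = files.index(fname)
    ci = [c for c, _ in _FILE_COLUMNS].index(cname)
    return fi * len(_FILE_COLUMNS) + ci + 1


def make_filled_metadata(
    scheme: Scheme,
    n_species: int = 3,
    n_data_files: int = 2,
    faults: FaultSpec | None = None,
) -> tuple[MetadataSet, list[ExpectedIssue]]:
    """Generate filled metadata over the example scheme.

    Without faults the result validates with zero issues (given the
    matching toy data files).  With faults, the returned expectation list
    holds exactly the (code, severity, location) triples the validator
    must report for the seeded codes.  Data-file fault codes are included
    in the expectations here; the files themselves are realised by
    :func:`make_toy_datafiles` called with the same spec.
    """
    if n_species < 1 or n_data_files < 0:
        raise FixtureError("need at least one species and a non-negative file count")
    spec = faults or FaultSpec()
    tables = _clean_tables(n_species, n_data_files)
    clean = copy.deepcopy(tables)
    files = _file_names(n_data_files)
    expected: list[ExpectedIssue] = []
    meta = MetadataSet(scheme_name=scheme.name, scheme_version=scheme.version,
                       tables=tables)

    def expect(code: str, location: tuple[str, str, int]) -> None:
        expected.append((code, RULES[code][0], location))

    # --- scheme identity ---------------------------------------------------
    k = spec.get("STRUCT_SCHEME_MISMATCH")
    if k > 2:
        raise FixtureError("at most 2 STRUCT_SCHEME_MISMATCH faults are seedable")
    if k >= 1:
        meta.scheme_version = "0.0.0"
        expect("STRUCT_SCHEME_MISMATCH", ("", "", 0))
    if k == 2:
        meta.scheme_name = scheme.name + "X"
        expect("STRUCT_SCHEME_MISMATCH", ("", "", 0))

    # --- structure faults that suppress downstream checks ------------------
    needed: set[str] = set()
    for code, count in spec.counts.items():
        if count > 0 and code not in ("STRUCT_MISSING_SET", "STRUCT_MISSING_PROPERTY"):
            needed |= _NEEDED_TABLES.get(code, set())
    pool = [t for t in _DELETABLE if t not in needed]

    n_del = spec.get("STRUCT_MISSING_SET")
    n_strip = spec.get("STRUCT_MISSING_PROPERTY")
    if n_del + n_strip > len(pool):
        raise FixtureError(
            f"cannot seed {n_del} missing-set + {n_strip} missing-property "
            f"faults: only {len(pool)} tables are expendable for this spec"
        )
    for t in pool[:n_del]:
        del tables[t]
        expect("STRUCT_MISSING_SET", (t, "", 0))
    for t in pool[n_del:n_del + n_strip]:
        col = _REMOVABLE_COLUMN[t]
        for row in tables[t]:
            row.pop(col, None)
        expect("STRUCT_MISSING_PROPERTY", (t, col, 0))

    for i in range(spec.get("STRUCT_UNKNOWN_SET")):
        name = f"Unknown_{i + 1:02d}"
        tables[name] = [{"value": "x"}]
        expect("STRUCT_UNKNOWN_SET", (name, "", 0))

    survivors = [t for t in scheme.set_names() if t in tables]
    n_extra_col = spec.get("STRUCT_UNKNOWN_PROPERTY")
    if n_extra_col > len(survivors):
        raise FixtureError(
            f"cannot seed {n_extra_col} unknown-column faults: "
            f"only {len(survivors)} sheets remain"
        )
    for i in range(n_extra_col):
        t, col = survivors[i], f"extra_{i + 1:02d}"
        for row in tables[t]:
            row[col] = "x"
        expect("STRUCT_UNKNOWN_PROPERTY", (t, col, 0))

    for i in range(spec.get("STRUCT_ROW_COUNT")):
        if "Experiment" not in tables:
            raise FixtureError("cannot seed STRUCT_ROW_COUNT: Experiment sheet gone")
        tables["Experiment"].append(copy.deepcopy(clean["Experiment"][0]))
        expect("STRUCT_ROW_COUNT", ("Experiment", "", len(tables["Experiment"])))

    # --- cell-level value & reference faults (disjoint cells, own cursors) --
    cursors: dict[tuple[str, str], int] = {}

    def corrupt(code: str, table: str, column: str, make_value) -> None:
        for i in range(spec.get(code)):
            key = (table, column)
            row_idx = cursors.get(key, 1)
            if table not in tables or row_idx > len(tables[table]):
                raise FixtureError(
                    f"cannot seed {spec.get(code)} {code} faults: "
                    f"not enough rows in {table}"
                )
            tables[table][row_idx - 1][column] = make_value(i)
            cursors[key] = row_idx + 1
            expect(code, (table, column, row_idx))

    corrupt("VAL_REQUIRED_MISSING", "Treatment", "treatmentName", lambda i: "")
    corrupt("VAL_TYPE", "Treatment", "duration", lambda i: "3.7")
    corrupt("VAL_NOT_ALLOWED", "Species", "medium",
            lambda i: f"unknown medium {i + 1}")
    corrupt("VAL_NOT_SUGGESTED", "Measurement", "method",
            lambda i: f"flowcytometer{i + 2}")
    corrupt("VAL_RANGE", "Treatment", "concentration", lambda i: "12.5")
    corrupt("CONS_DANGLING_REF", "Treatment", "species",
            lambda i: f"Phantomella ghosti {i + 1}")

    for _ in range(spec.get("CONS_DUPLICATE_KEY")):
        if "Species" not in tables:
            raise FixtureError("cannot seed CONS_DUPLICATE_KEY: Species sheet gone")
        tables["Species"].append(copy.deepcopy(clean["Species"][0]))
        expect("CONS_DUPLICATE_KEY", ("Species", "speciesName", len(tables["Species"])))

    n_meas = len(clean["Measurement"])
    for i in range(spec.get("CONS_MULTIPLE_METHODS")):
        if n_data_files < 1:
            raise FixtureError("cannot seed CONS_MULTIPLE_METHODS without data files")
        row = copy.deepcopy(clean["DataFiles"][0])
        row["measurement"] = f"measurement_{((i + 1) % n_meas) + 1:02d}"
        row["description"] = f"duplicate method row {i + 1}"
        tables["DataFiles"].append(row)
        expect("CONS_MULTIPLE_METHODS",
               ("DataFiles", "fileName", len(tables["DataFiles"])))

    # --- data-file faults: expectations here, files in make_toy_datafiles --
    plan = _plan_data_faults(spec, files)
    file_rows = {f: i + 1 for i, f in enumerate(files)}
    for fname in plan["missing_files"]:
        expect("DATA_FILE_MISSING", ("DataFiles", "fileName", file_rows[fname]))
    for _ in plan["extra_files"]:
        expect("DATA_FILE_UNDECLARED", ("DataFiles", "fileName", 0))
    for fname, cname in plan["drop_columns"]:
        expect("DATA_COLUMN_MISSING",
               ("DataFileColumns", "columnName", _column_decl_row(files, fname, cname)))
    for _ in plan["extra_columns"]:
        expect("DATA_COLUMN_UNDECLARED", ("DataFileColumns", "columnName", 0))
    for fname, cname in plan["corrupt_type"]:
        expect("DATA_COLUMN_TYPE",
               ("DataFileColumns", "columnType", _column_decl_row(files, fname, cname)))

    return meta, expected


def make_toy_datafiles(
    meta: MetadataSet,
    data_dir,
    faults: FaultSpec | None = None,
) -> tuple[list[Path], list[ExpectedIssue]]:
    """Write one delimited file per data file declared in ``meta``.

    Each file gets exactly the declared header and five typed data rows.
    ``DATA_*`` fault codes from the spec are realised as instructed (a
    declared file not written, an extra undeclared file, a dropped or
    extra header column, a type-violating value); the same spec passed to
    :func:`make_filled_metadata` yields the full expectation list — the
    subset returned here covers the data-file codes only.
    """
    spec = faults or FaultSpec()
    d = Path(data_dir)
    d.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    declared: list[str] = []
    for row in meta.tables.get("DataFiles", ()):
        name = row.get("fileName", "")
        if name and name not in declared:
            declared.append(name)
    plan = _plan_data_faults(spec, declared)
    file_rows = {f: i + 1 for i, f in enumerate(declared)}
    dropped = set(plan["drop_columns"])
    corrupt = set(plan["corrupt_type"])
    extras = {}
    for fname, cname in plan["extra_columns"]:
        extras.setdefault(fname, []).append(cname)

    written: list[Path] = []
    expected: list[ExpectedIssue] = []
    for fname in declared:
        if fname in plan["missing_files"]:
            expected.append((
                "DATA_FILE_MISSING", RULES["DATA_FILE_MISSING"][0],
                ("DataFiles", "fileName", file_rows[fname]),
            ))
            continue
        cols = [
            (cname, ctype) for cname, ctype in _FILE_COLUMNS
            if (fname, cname) not in dropped
        ]
        header = [c for c, _ in cols] + extras.get(fname, [])
        rows = []
        for i in range(_TOY_ROWS):
            row = []
            for cname, ctype in cols:
                if cname == "time":
                    v = str(i + 1)
                elif cname == "speciesName":
                    v = _SPECIES_POOL[i % len(_SPECIES_POOL)]
                else:  # abundance
                    v = f"{rng.uniform(0.0, 100.0):.2f}"
                if i == 0 and (fname, cname) in corrupt:
                    v = "not-a-number"
                row.append(v)
            row += [f"x{i + 1}"] * len(extras.get(fname, []))
            rows.append(row)
        path = d / fname
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(",".join(header) + "\n")
            for row in rows:
                fh.write(",".join(row) + "\n")
        written.append(path)

    for fname, cname in plan["drop_columns"]:
        expected.append((
            "DATA_COLUMN_MISSING", RULES["DATA_COLUMN_MISSING"][0],
            ("DataFileColumns", "columnName", _column_decl_row(declared, fname, cname)),
        ))
    for fname, cname in plan["corrupt_type"]:
        expected.append((
            "DATA_COLUMN_TYPE", RULES["DATA_COLUMN_TYPE"][0],
            ("DataFileColumns", "columnType", _column_decl_row(declared, fname, cname)),
        ))
    for i, fname in enumerate(plan["extra_files"]):
        path = d / fname
        path.write_text("a,b\n1,2\n", encoding="utf-8")
        written.append(path)
        expected.append((
            "DATA_FILE_UNDECLARED", RULES["DATA_FILE_UNDECLARED"][0],
            ("DataFiles", "fileName", 0),
        ))
    for fname, cname in plan["extra_columns"]:
        expected.append((
            "DATA_COLUMN_UNDECLARED", RULES["DATA_COLUMN_UNDECLARED"][0],
            ("DataFileColumns", "columnName", 0),
        ))
    return written, expected


def issue_triples(issues) -> list[ExpectedIssue]:
    """Project validator issues onto (code, severity, location) triples."""
    return [(i.code, i.severity, i.location) for i in issues]


def restrict_to_codes(triples, codes) -> list[ExpectedIssue]:
    return [t for t in triples if t[0] in codes]


def make_fixture_repository(repo_dir) -> list:
    """Build a throwaway repository holding two versions of the example
    scheme (0.9.9 and 1.1.7), each packed with one clean example."""
    from .repository import build_index, pack_scheme

    repo = Path(repo_dir)
    repo.mkdir(parents=True, exist_ok=True)
    for version in ("0.9.9", "1.1.7"):
        scheme = make_example_scheme()
        scheme.version = version
        meta, _ = make_filled_metadata(scheme, n_species=3, n_data_files=2)
        pack_scheme(scheme, [meta], repo)
    return build_index(repo)
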