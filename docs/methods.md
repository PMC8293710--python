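# Methods

## The model

A metadata *scheme* is a named, versioned, ordered list of *property
sets*; a property set is an ordered list of *properties* and renders as
one worksheet. Property sets have a cardinality: `exactly-one-row` for
experiment-level sheets (the experiment happens once) and
`zero-or-more-rows` for per-entity sheets (species, treatments, data
files). Properties carry:

| field | meaning | default |
|---|---|---|
| `type` | one of `character`, `integer`, `real`, `logical`, `date` (ISO-8601) | `character` |
| `required` | empty cell is an error | `False` |
| `allowed_values` | closed vocabulary — anything else is an **error** | empty |
| `suggested_values` | open vocabulary — anything else is a **note** | empty |
| `min_value`, `max_value` | inclusive numeric range (numeric types only) | none |
| `refers_to` | `(set, property)` the values must occur in | none |

The five-type system is deliberately minimal: it covers everything a
spreadsheet cell in this kind of metadata can sensibly hold, and every
type has an unambiguous string form, which matters because **filled
metadata is stored verbatim as strings** (`MetadataSet`). The empty
string is the one and only missing-value representation; typing happens
exclusively in validation and export. This is what lets a half-filled or
faulty workbook always be read back and reported on rather than rejected
at parse time.

A scheme may additionally designate a *data-file set* (the sheet listing
data-file names, one row per file with its measurement and extraction
method) and a *column set* (one row per (file, column name, column
type)). These power the data-file validation stage and the per-file
export. The designation is declarative — there is no executable
per-scheme code in packages; everything a scheme can express is data.

Scheme edits (`add_property_set`, `add_property`) have value semantics:
they return a new scheme and never mutate their input, so iterative
scheme development is reproducible step by step.

## Workbook dialect

One worksheet per property set plus a leading `_scheme` identity sheet
(scheme name, version, per-sheet cardinality). Data sheets have four
header rows — property names, descriptions, `type[:required]`, and the
vocabulary as `allowed:a|b` / `suggested:a|b` — with data from row 5.
The file is self-describing: no hidden cells, no styling-dependent
semantics, one value per cell (multiplicity = extra rows). Reading strips
surrounding whitespace, drops trailing all-empty rows, and retains
unknown sheets and columns so validation can report them.

Workbooks are byte-deterministic: document timestamps are pinned and the
xlsx zip container is rewritten with constant member timestamps, so
identical content yields identical bytes. This makes fixture
determinism, package checksums and the pack→install→pack fixed point
testable at the byte level rather than "equal after parsing".

## Validation

Four sub-stages run in order; all findings are issues, nothing raises
(except an unreadable data directory, which is a genuine I/O error):

1. **structure** — scheme identity, missing/unknown sheets, missing/
   unknown columns, row-count of exactly-one-row sheets (one issue per
   extra row, so violations are countable).
2. **values** — per cell: required, type parse, closed vocabulary
   (error), open vocabulary (note), numeric range. Empty optional cells
   are not checked.
3. **consistency** — every non-empty `refers_to` value must occur in its
   target column; duplicate first-property keys warn; a data-file name
   appearing in more than one row of the data-file set is an error (one
   file, one measurement and extraction method — the constraint that
   keeps per-file export and downstream standard mapping well-defined).
4. **data_files** — declared files must exist (missing = error, extra =
   warning), headers must match the declared columns (same polarity),
   and every value in a typed column must parse under the declared
   column type (one error per offending column). Delimiter comes from
   the extension (`.tsv` → tab) or an override; `max_rows` caps the
   scan for large files, default is all rows since these files are
   desk-scale.

Severities are totally ordered (`error` > `warning` > `note`); the
report's `worst_severity` is the maximum, or `success` with no issues.
Every rule has a stable code in a documented registry, which makes
reports machine-checkable and fault injection exact.

Design choices where the behaviour was genuinely open:

* **Cascade suppression.** An error-level *structure* problem in a table
  suppresses the value/consistency/data-file checks that depend on that
  table (and cross-reference checks whose target it is). One broken
  sheet therefore produces one structural error, not a flood of
  misleading value errors.
* **Key checks per set kind.** The generic duplicate-key warning uses a
  set's first property. For the designated data-file set this is
  superseded by the stronger one-method-per-file error; for the column
  set the key is the (file, column) pair, since the file name
  legitimately repeats across a file's columns.
* **Vocabulary matching is exact and case-sensitive** — deterministic
  vocabularies surface mismatches early instead of hiding them behind
  fuzzy matching.
* Warning-level assignments (unknown sheet/column, undeclared
  file/column, duplicate key) are this package's calibration; only the
  error and note exemplars (closed vs open vocabulary) are fixed by the
  approach itself.

Reports render to markdown or HTML (summary counts, then issues grouped
stage → property set). The report object carries a timestamp, but it is
excluded from both equality and rendering, so identical inputs produce
byte-identical rendered reports.

## Export

Export requires a report with no error-level issues; notes and warnings
pass. The combined document has the scheme name as root (with
`schemeVersion` and a `schemeNamespace` attribute
`urn:dmdscheme:<name>:<version>`), one child element per property set,
`<row>` elements per data row, and leaf elements per non-empty value —
missing values are absent elements, the XML mirror of "empty string =
missing". Output is UTF-8, two-space indented, attributes sorted:
byte-stable. `read_xml` inverts the combined export exactly under the
package's metadata-equality (which normalizes empty values away).

Per-data-file export computes, for each declared file, which rows of
each multi-row set are *scoped* to it by propagating along `refers_to`
edges from the data-file set to a fixed point — downstream (the column
set's rows naming this file) and upstream (the measurement/extraction
rows this file's row references). Exactly-one-row sets are always
replicated whole; sets never reached by any chain (e.g. Species,
Treatment in the example scheme) are conservatively included everywhere,
so each document is self-contained. Rows referencing exactly one file
therefore appear in exactly one document.

The EML hook is a mapping *coverage* report only (`Set/Property` →
EML-path table; mapped / unmapped / dangling): emitting actual EML is
out of scope.

## Scheme packages and repositories

A package is `<name>_<version>.zip` containing the JSON scheme manifest,
the generated template workbook, example filled workbooks, and a package
manifest whose SHA-256 covers the other members' names and bytes.
Packing refuses ill-formed schemes and examples that do not validate
error-free (examples travel without their data, so the data-file stage
is not part of the packing gate). A repository is a directory or static
URL with `index.json` (name, version, archive, SHA-256 of the archive
file). Install verifies both checksums, unpacks into a per-session
temporary directory by default, and never writes to the repository.
`latest` resolves by numeric semver, pre-releases excluded.

## The fixture generator

`make_example_scheme` builds the shipped example: an Experimental
Microbial Ecology scheme (`emeScheme` 0.9.9) with seven property sets —
Experiment (one row), Species, Treatment, Measurement, DataExtraction,
DataFiles, DataFileColumns — including a closed vocabulary (culture
media), an open vocabulary (measurement methods: flow cytometer,
microscope), numeric ranges (temperature 0–40 °C, concentration
0–10 g/l), and the reference chain Treatment→Species,
DataFiles→Measurement/DataExtraction, DataFileColumns→DataFiles. The
vocabularies and species names are invented but domain-plausible; the
generator emulates the *shape* of real entry workbooks, not any
particular lab's catalogue.

`make_filled_metadata(scheme, n_species, n_data_files, faults)` produces
metadata that validates with zero issues when unfaulted (defaults: 3
species, 2 data files — a small but complete experiment), and
`make_toy_datafiles` writes the matching CSVs (declared header + 5 typed
rows; big enough to exercise type checks, small enough to be instant).
All randomness flows from the fault spec's seed; identical inputs give
byte-identical outputs.

Fault injection is the package's oracle: each rule code has a seeding
strategy occupying sites disjoint from every other code's — distinct
cells (own per-column cursors), appended pristine rows (duplicates,
extra experiment rows), added sheets/columns, or planned file-level
edits. The generator returns the exact (code, severity, location)
triples the validator must emit, so tests compare multisets, not counts.
Structure faults that suppress downstream checking (deleting a sheet,
removing a column) are drawn only from tables no other seeded rule
needs; an unrealisable spec raises `FixtureError` instead of producing
an unreliable expectation. Two capacity limits are inherent: the scheme
identity offers two mismatch sites (name, version), and five sheets are
expendable for deletion (the data-file sheets must survive for the data
stage to remain meaningful).

## What passing tests do and do not show

The fixtures exercise every rule, both vocabular polarities, all
round-trips and the export partition on a realistic but synthetic
workbook. They do not cover: hand-edited workbooks with formulas, merged
cells or locale-formatted numbers (out of scope by design — one value
per cell, plain strings); very large data files (the `max_rows` cap
exists but defaults to scanning everything); concurrent repository
writes; or schemes whose consistency rules need arbitrary code — the
declarative `refers_to`/designation mechanism is the supported
extension point.

## Problem sizes

Tests and the acceptance script run at desk scale by choice — 3–6
species, 2–5 data files, 5-row data files, ~60–100 randomized fault
specifications, 10 round-trip trials — which exercises every code path
(vocabularies, ranges, all reference chains, both cardinalities) while
keeping the whole suite in seconds.
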