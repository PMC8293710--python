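# dmdkit

Domain-specific metadata schemes for research data: define a small,
purpose-built scheme for one research domain, let researchers fill it in
through an ordinary spreadsheet, validate the result at three levels, and
export error-free metadata to XML — one document per data file.

Broad metadata standards (EML, Darwin Core, Dublin Core) are powerful but
complex, and many datasets end up with little or no metadata because
filling those standards in is daunting. A *domain-specific* scheme is the
opposite trade-off: as complex as necessary for one domain (for example
Experimental Microbial Ecology, the worked example shipped here), as
simple as possible for the researcher. `dmdkit` is the tooling around such
schemes:

* **scheme_model** — schemes as data: named, versioned collections of
  *property sets* (one worksheet each), whose *properties* carry a type
  (`character`, `integer`, `real`, `logical`, `date`), a required flag,
  closed (`allowed`) or open (`suggested`) vocabularies, numeric ranges,
  and cross-references between sheets.
* **spreadsheet_io** — generates the entry workbook (four header rows:
  names, descriptions, types, vocabularies; data from row 5) and reads
  filled workbooks back verbatim. A CSV-directory twin format round-trips
  identically.
* **validation** — three stages with three severities (`error` >
  `warning` > `note`): structure against the scheme, cell values against
  types/vocabularies/ranges, and consistency — cross-references must
  resolve, keys must be unique, each data file may carry exactly one
  measurement and extraction method, and the declared files/columns/types
  are checked against the actual delimited files on disk. Every finding
  carries a stable rule code (`VAL_NOT_ALLOWED`, `CONS_DANGLING_REF`, …).
* **export** — XML export, gated on validation: any error refuses the
  export; notes and warnings do not. Besides the combined document, the
  per-data-file export writes one XML document per declared data file,
  replicating the experiment-level metadata into each and narrowing
  multi-row sheets to the rows that concern that file.
* **repository** — schemes travel as checksummed zip packages
  (`<name>_<version>.zip`: manifest, template workbook, examples) indexed
  by an `index.json` in a directory or behind a static URL; `latest`
  resolves by semantic version.
* **fixtures** — a complete synthetic example (the `emeScheme`, protist
  species / treatments / measurements / data files) with *fault
  injection*: seed any number of violations of any rule and get back the
  exact issues the validator must report.

## Worked example

```sh
dmdkit fixtures --seed 7 --faults "VAL_NOT_ALLOWED=1,VAL_NOT_SUGGESTED=1" --out demo
dmdkit validate demo/metadata.xlsx --scheme demo/scheme.json --data-dir demo/data
```

prints the rendered report followed by the summary line

```
1 errors / 0 warnings / 1 notes
```

and exits with status 1: the species medium `"unknown medium 1"` is not
in the closed vocabulary of `Species.medium` (an **error**), while the
measurement method `"flowcytometer2"` merely falls outside the open
vocabulary `flowcytometer|microscope` (a **note**). Export now refuses:

```sh
$ dmdkit export demo/metadata.xlsx --scheme demo/scheme.json -o demo/meta.xml
error: validation found 1 error(s); export refused until the metadata
validates without errors
```

Re-run the fixture without faults and the same commands validate with
`0 errors / 0 warnings / 0 notes`, the export succeeds, and

```sh
dmdkit export demo/metadata.xlsx --scheme demo/scheme.json --per-datafile --out-dir demo/xml
```

writes `exp1_counts.csv.xml` and `exp2_counts.csv.xml` — one document per
declared data file, each carrying the full experiment-level metadata plus
only its own file's column declarations.

The same workflow is available as library calls
(`make_filled_metadata`, `validate_all`, `export_xml_per_datafile`, …);
the CLI is a thin shell over them.

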