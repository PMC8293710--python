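"""The three validation stages, severity semantics, and report rendering."""

import pytest

from dmdkit import fixtures as fx
from dmdkit.errors import UsageError
from dmdkit.scheme_model import MetadataSet, Property, PropertySet, Scheme
from dmdkit.validation import (
    RULES,
    Severity,
    ValidationReport,
    issue,
    render_report,
    validate_all,
    validate_consistency,
    validate_structure,
    validate_values,
)


def mini_scheme(**prop_kwargs) -> Scheme:
    """One-set scheme with a single configurable property ``p``."""
    return Scheme(
        name="mini", version="1.0.0",
        property_sets=[PropertySet("Set", properties=[Property("p", **prop_kwargs)])],
    )


def mini_meta(value: str) -> MetadataSet:
    return MetadataSet("mini", "1.0.0", {"Set": [{"p": value}]})


class TestValueSemantics:
    """Closed vocabularies error; open vocabularies only note."""

    def test_value_outside_allowed_values_is_one_error(self):
        s = mini_scheme(allowed_values=("Tetrahymena thermophila", "Colpidium striatum"))
        found = validate_values(mini_meta("Paramecium caudatum"), s)
        assert [(i.code, i.severity) for i in found] == [
            ("VAL_NOT_ALLOWED", Severity.ERROR)
        ]

    def test_value_outside_suggested_values_is_one_note(self):
        s = mini_scheme(suggested_values=("flowcytometer", "microscope"))
        found = validate_values(mini_meta("flowcytometer2"), s)
        assert [(i.code, i.severity) for i in found] == [
            ("VAL_NOT_SUGGESTED", Severity.NOTE)
        ]

    def test_missing_required_value_is_one_error(self):
        found = validate_values(mini_meta(""), mini_scheme(required=True))
        assert [(i.code, i.severity) for i in found] == [
            ("VAL_REQUIRED_MISSING", Severity.ERROR)
        ]

    def test_integer_type_violation(self):
        found = validate_values(mini_meta("3.7"), mini_scheme(type="integer"))
        assert [i.code for i in found] == ["VAL_TYPE"]

    def test_numeric_value_outside_range_is_one_error(self):
        s = mini_scheme(type="real", min_value=0.0, max_value=10.0)
        found = validate_values(mini_meta("12.0"), s)
        assert [(i.code, i.severity) for i in found] == [
            ("VAL_RANGE", Severity.ERROR)
        ]

    def test_valid_cell_yields_nothing(self):
        s = mini_scheme(type="real", min_value=0.0, max_value=10.0, required=True)
        assert validate_values(mini_meta("7.5"), s) == []

    def test_empty_optional_cell_is_not_checked(self):
        s = mini_scheme(allowed_values=("a",))
        assert validate_values(mini_meta(""), s) == []


class TestStructure:
    def test_clean_fixture_has_no_structure_issues(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme)
        assert validate_structure(meta, scheme) == []

    def test_missing_sheet(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme)
        del meta.tables["Species"]
        found = validate_structure(meta, scheme)
        assert [(i.code, i.location[0]) for i in found] == [
            ("STRUCT_MISSING_SET", "Species")
        ]

    def test_extra_column_is_a_warning(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme)
        meta.tables["Species"][0]["Color"] = "green"
        found = validate_structure(meta, scheme)
        assert [(i.code, i.severity) for i in found] == [
            ("STRUCT_UNKNOWN_PROPERTY", Severity.WARNING)
        ]

    def test_exactly_one_row_violations(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme)
        meta.tables["Experiment"] = []
        assert [i.code for i in validate_structure(meta, scheme)] == ["STRUCT_ROW_COUNT"]
        meta2, _ = fx.make_filled_metadata(scheme)
        meta2.tables["Experiment"].append(dict(meta2.tables["Experiment"][0]))
        assert [i.code for i in validate_structure(meta2, scheme)] == ["STRUCT_ROW_COUNT"]

    def test_scheme_identity_mismatch(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme)
        meta.scheme_version = "9.9.9"
        codes = [i.code for i in validate_structure(meta, scheme)]
        assert codes == ["STRUCT_SCHEME_MISMATCH"]

    def test_structure_error_suppresses_value_checks_for_that_table_only(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme)
        for row in meta.tables["Species"]:
            row.pop("medium")  # missing column: error-level structure issue
        meta.tables["Species"][0]["speciesName"] = ""  # would be VAL_REQUIRED_MISSING
        meta.tables["Treatment"][0]["concentration"] = "99.0"  # other table still checked
        report = validate_all(meta, scheme)
        codes = [i.code for i in report.issues]
        assert "VAL_REQUIRED_MISSING" not in codes
        assert "VAL_RANGE" in codes


class TestConsistency:
    def test_dangling_reference(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme)
        meta.tables["Treatment"][0]["species"] = "T. thermophila"  # not the full name
        found = validate_consistency(meta, scheme)
        assert [(i.code, i.severity) for i in found] == [
            ("CONS_DANGLING_REF", Severity.ERROR)
        ]

    def test_data_file_with_two_method_rows(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme, n_data_files=2)
        extra = dict(meta.tables["DataFiles"][0])
        extra["measurement"] = "measurement_02"
        meta.tables["DataFiles"].append(extra)
        found = validate_consistency(meta, scheme)
        assert [(i.code, i.location[0]) for i in found] == [
            ("CONS_MULTIPLE_METHODS", "DataFiles")
        ]

    def test_duplicate_key_is_a_warning(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme)
        meta.tables["Species"].append(dict(meta.tables["Species"][0]))
        found = validate_consistency(meta, scheme)
        assert [(i.code, i.severity) for i in found] == [
            ("CONS_DUPLICATE_KEY", Severity.WARNING)
        ]

    def test_fully_consistent_fixture(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme)
        assert validate_consistency(meta, scheme) == []


class TestDataFiles:
    def test_matching_toy_files_are_clean(self, scheme, clean_bundle):
        meta, data_dir = clean_bundle
        report = validate_all(meta, scheme, data_dir=data_dir)
        assert report.worst_severity == "success"

    def test_renamed_header_column(self, scheme, clean_bundle):
        meta, data_dir = clean_bundle
        f = data_dir / "exp1_counts.csv"
        f.write_text(f.read_text().replace("abundance", "abund", 1))
        report = validate_all(meta, scheme, data_dir=data_dir)
        codes = sorted(i.code for i in report.issues)
        assert codes == ["DATA_COLUMN_MISSING", "DATA_COLUMN_UNDECLARED"]

    def test_deleted_declared_file(self, scheme, clean_bundle):
        meta, data_dir = clean_bundle
        (data_dir / "exp2_counts.csv").unlink()
        report = validate_all(meta, scheme, data_dir=data_dir)
        assert [i.code for i in report.issues] == ["DATA_FILE_MISSING"]

    def test_unreadable_data_dir_raises(self, scheme, clean_bundle, tmp_path):
        meta, _ = clean_bundle
        with pytest.raises(IOError):
            validate_all(meta, scheme, data_dir=tmp_path / "nonexistent")


class TestReport:
    def test_worst_severity_is_the_maximum(self):
        report = ValidationReport(("x", "1.0.0"), {"values": [
            issue("VAL_NOT_SUGGESTED", ("S", "p", 1), "m"),
            issue("VAL_NOT_ALLOWED", ("S", "p", 2), "m"),
            issue("STRUCT_UNKNOWN_SET", ("T", "", 0), "m"),
        ]})
        assert report.worst_severity == "error"

    def test_empty_report_is_success(self):
        report = ValidationReport(("x", "1.0.0"), {s: [] for s in ("structure",)})
        assert report.worst_severity == "success"
        assert "0 errors / 0 warnings / 0 notes" in render_report(report)

    def test_adding_issues_never_lowers_worst_severity(self):
        stages = {"values": [issue("VAL_NOT_ALLOWED", ("S", "p", 1), "m")]}
        before = ValidationReport(("x", "1.0.0"), stages)
        grown = ValidationReport(("x", "1.0.0"), {
            "values": stages["values"] + [issue("VAL_NOT_SUGGESTED", ("S", "p", 2), "m")]
        })
        order = {"note": 1, "warning": 2, "error": 3}
        assert order[grown.worst_severity] >= order[before.worst_severity]

    @pytest.mark.parametrize("fmt", ["markdown", "html"])
    def test_rendered_summary_counts_match(self, fmt):
        report = ValidationReport(("x", "1.0.0"), {"values": [
            issue("VAL_NOT_ALLOWED", ("S", "p", 1), "bad"),
            issue("VAL_NOT_ALLOWED", ("S", "p", 2), "bad"),
            issue("VAL_NOT_SUGGESTED", ("S", "p", 3), "odd"),
        ]})
        text = render_report(report, format=fmt)
        assert "2 errors / 0 warnings / 1 notes" in text
        assert "VAL_NOT_ALLOWED" in text

    def test_unknown_format_is_usage_error(self):
        with pytest.raises(UsageError):
            render_report(ValidationReport(("x", "1.0.0")), format="pdf")

    def test_validation_is_idempotent(self, scheme, clean_bundle):
        meta, data_dir = clean_bundle
        r1 = validate_all(meta, scheme, data_dir=data_dir)
        r2 = validate_all(meta, scheme, data_dir=data_dir)
        assert r1 == r2  # timestamp excluded from equality

    def test_every_rule_code_has_a_fixed_severity(self):
        assert set(RULES) == {i for i in RULES}
        for code, (severity, doc) in RULES.items():
            assert isinstance(severity, Severity) and doc
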