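"""XML export: round-trips, the error gate, and per-data-file partitioning."""

import xml.etree.ElementTree as ET

import pytest

from dmdkit import fixtures as fx
from dmdkit.errors import ExportRefusedError, XmlFormatError
from dmdkit.export import (
    eml_mapping_stub,
    export_xml,
    export_xml_per_datafile,
    read_xml,
)
from dmdkit.scheme_model import MetadataSet, new_template_scheme


class TestCombinedExport:
    def test_round_trip_equals_input(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme, n_species=4, n_data_files=3)
        assert read_xml(export_xml(meta, scheme)) == meta

    def test_empty_sets_serialize_as_empty_elements(self):
        from dmdkit.scheme_model import Property, PropertySet, add_property_set

        s = add_property_set(
            new_template_scheme("dmdScheme", "0.9.9"),
            PropertySet("Notes", properties=[Property("text")]),
        )
        meta = MetadataSet("dmdScheme", "0.9.9", {
            "Metadata": [{"Title": "t", "Author": "a", "Date": "2021-06-25"}],
            "Notes": [],
        })
        root = ET.fromstring(export_xml(meta, s))
        assert root.tag == "dmdScheme"
        assert [el.tag for el in root] == ["Metadata", "Notes"]
        assert len(root.find("Notes")) == 0

    def test_missing_values_are_absent_elements(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme)
        root = ET.fromstring(export_xml(meta, scheme))
        exp_row = root.find("Experiment").find("row")
        assert exp_row.find("Comment") is None  # empty in the fixture
        assert exp_row.find("Title") is not None

    def test_output_is_deterministic(self, scheme):
        meta, _ = fx.make_filled_metadata(scheme)
        assert export_xml(meta, scheme) == export_xml(meta, scheme)


class TestExportGate:
    def test_error_level_issue_refuses_export(self, scheme):
        meta, _ = fx.make_filled_metadata(
            scheme, faults=fx.FaultSpec({"VAL_NOT_ALLOWED": 1})
        )
        with pytest.raises(ExportRefusedError, match="1 error"):
            export_xml(meta, scheme)
        with pytest.raises(ExportRefusedError):
            export_xml_per_datafile(meta, scheme, "unused")

    def test_notes_and_warnings_do_not_block_export(self, scheme, tmp_path):
        meta, _ = fx.make_filled_metadata(
            scheme,
            faults=fx.FaultSpec({"VAL_NOT_SUGGESTED": 1, "STRUCT_UNKNOWN_SET": 1}),
        )
        assert export_xml(meta, scheme).startswith(b"<?xml")
        assert export_xml_per_datafile(meta, scheme, tmp_path / "xml")

    @pytest.mark.parametrize("code", [
        "VAL_REQUIRED_MISSING", "VAL_TYPE", "VAL_RANGE",
        "CONS_DANGLING_REF", "CONS_MULTIPLE_METHODS", "STRUCT_MISSING_SET",
    ])
    def test_gate_refuses_every_error_rule(self, scheme, code):
        meta, _ = fx.make_filled_metadata(scheme, faults=fx.FaultSpec({code: 1}))
        with pytest.raises(ExportRefusedError):
            export_xml(meta, scheme)


class TestPerDataFileExport:
    def test_one_document_per_data_file(self, scheme, tmp_path):
        meta, _ = fx.make_filled_metadata(scheme, n_data_files=3)
        docs = export_xml_per_datafile(meta, scheme, tmp_path / "xml")
        assert sorted(docs) == ["exp1_counts.csv", "exp2_counts.csv", "exp3_counts.csv"]
        assert all(p.name == f"{f}.xml" and p.is_file() for f, p in docs.items())

    def test_experiment_section_byte_identical_across_documents(self, scheme, tmp_path):
        meta, _ = fx.make_filled_metadata(scheme, n_data_files=3)
        docs = export_xml_per_datafile(meta, scheme, tmp_path / "xml")
        sections = {
            ET.tostring(ET.parse(p).getroot().find("Experiment"))
            for p in docs.values()
        }
        assert len(sections) == 1

    def test_file_scoped_records_partition_exactly(self, scheme, tmp_path):
        meta, _ = fx.make_filled_metadata(scheme, n_data_files=3)
        docs = export_xml_per_datafile(meta, scheme, tmp_path / "xml")
        seen = []
        for fname, path in docs.items():
            root = ET.parse(path).getroot()
            for row in root.find("DataFileColumns"):
                pair = (row.findtext("fileName"), row.findtext("columnName"))
                assert pair[0] == fname  # only this file's columns appear
                seen.append(pair)
            file_rows = [r.findtext("fileName") for r in root.find("DataFiles")]
            assert file_rows == [fname]
        assert len(seen) == len(set(seen)) == 3 * 3

    def test_unreferenced_sets_are_replicated_everywhere(self, scheme, tmp_path):
        meta, _ = fx.make_filled_metadata(scheme, n_species=3, n_data_files=2)
        docs = export_xml_per_datafile(meta, scheme, tmp_path / "xml")
        for path in docs.values():
            root = ET.parse(path).getroot()
            assert len(root.find("Species")) == 3
            assert len(root.find("Treatment")) == 3

    def test_zero_data_files_yields_empty_mapping(self, scheme, tmp_path):
        meta, _ = fx.make_filled_metadata(scheme, n_data_files=0)
        assert export_xml_per_datafile(meta, scheme, tmp_path / "xml") == {}


class TestReadXml:
    def test_malformed_xml(self):
        with pytest.raises(XmlFormatError):
            read_xml(b"<broken")

    def test_foreign_root(self):
        with pytest.raises(XmlFormatError):
            read_xml(b"<foreign><x/></foreign>")


class TestEmlMappingStub:
    def test_empty_mapping_leaves_all_unmapped(self, scheme):
        report = eml_mapping_stub(scheme, {})
        assert report["mapped"] == [] and report["dangling"] == []
        assert len(report["unmapped"]) == sum(
            len(ps.properties) for ps in scheme.property_sets
        )

    def test_full_mapping_has_zero_unmapped(self, scheme):
        mapping = {
            f"{ps.name}/{p.name}": f"eml/dataset/{p.name}"
            for ps in scheme.property_sets
            for p in ps.properties
        }
        report = eml_mapping_stub(scheme, mapping)
        assert report["unmapped"] == [] and report["dangling"] == []

    def test_nonexistent_property_is_dangling(self, scheme):
        report = eml_mapping_stub(scheme, {"Nowhere/nothing": "eml/x"})
        assert report["dangling"] == ["Nowhere/nothing"]
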