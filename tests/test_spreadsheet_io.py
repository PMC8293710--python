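"""Workbook layout, verbatim reading, and round-trip fidelity."""

import openpyxl
import pytest

from dmdkit import fixtures as fx
from dmdkit.errors import SchemeDefinitionError, WorkbookFormatError
from dmdkit.scheme_model import MetadataSet, new_template_scheme
from dmdkit.spreadsheet_io import (
    DATA_START_ROW,
    ID_SHEET,
    detect_scheme_id,
    read_metadata_dir,
    read_metadata_workbook,
    write_filled_workbook,
    write_metadata_dir,
    write_template_workbook,
)


class TestTemplateWorkbook:
    def test_template_scheme_sheets(self, tmp_path):
        path = tmp_path / "t.xlsx"
        write_template_workbook(new_template_scheme("dmdScheme", "0.9.9"), path)
        wb = openpyxl.load_workbook(path)
        assert wb.sheetnames == [ID_SHEET, "Metadata"]

    def test_example_scheme_has_seven_data_sheets(self, scheme, tmp_path):
        path = tmp_path / "t.xlsx"
        write_template_workbook(scheme, path)
        wb = openpyxl.load_workbook(path)
        assert len(wb.sheetnames) == 8 and wb.sheetnames[0] == ID_SHEET

    def test_header_rows(self, scheme, tmp_path):
        path = tmp_path / "t.xlsx"
        write_template_workbook(scheme, path)
        ws = openpyxl.load_workbook(path)["Species"]
        assert [c.value for c in ws[1][:3]] == ["speciesName", "medium", "strainId"]
        assert ws.cell(row=3, column=1).value == "character:required"
        assert str(ws.cell(row=4, column=2).value).startswith("allowed:")
        assert DATA_START_ROW == 5

    def test_ill_formed_scheme_refused(self, scheme, tmp_path):
        scheme.property_sets[0].properties = []
        with pytest.raises(SchemeDefinitionError):
            write_template_workbook(scheme, tmp_path / "t.xlsx")

    def test_write_is_byte_deterministic(self, scheme, tmp_path):
        a, b = tmp_path / "a.xlsx", tmp_path / "b.xlsx"
        write_template_workbook(scheme, a)
        write_template_workbook(scheme, b)
        assert a.read_bytes() == b.read_bytes()


class TestReading:
    def test_empty_template_reads_as_empty_tables(self, scheme, tmp_path):
        path = tmp_path / "t.xlsx"
        write_template_workbook(scheme, path)
        meta = read_metadata_workbook(path)
        assert meta.scheme_name == "emeScheme"
        assert set(meta.tables) == set(scheme.set_names())
        assert all(rows == [] for rows in meta.tables.values())

    def test_filled_round_trip(self, scheme, tmp_path):
        meta, _ = fx.make_filled_metadata(scheme, n_species=4, n_data_files=2)
        path = tmp_path / "m.xlsx"
        write_filled_workbook(scheme, meta, path)
        assert read_metadata_workbook(path) == meta

    def test_round_trip_preserves_unknown_sheets_and_columns(self, scheme, tmp_path):
        spec = fx.FaultSpec({"STRUCT_UNKNOWN_SET": 1, "STRUCT_UNKNOWN_PROPERTY": 1})
        meta, _ = fx.make_filled_metadata(scheme, faults=spec)
        path = tmp_path / "m.xlsx"
        write_filled_workbook(scheme, meta, path)
        back = read_metadata_workbook(path)
        assert "Unknown_01" in back.tables
        assert back == meta

    def test_detect_scheme_id(self, scheme, tmp_path):
        path = tmp_path / "t.xlsx"
        write_template_workbook(scheme, path)
        assert detect_scheme_id(path) == ("emeScheme", "0.9.9")
        t = tmp_path / "d.xlsx"
        write_template_workbook(new_template_scheme("dmdScheme", "0.9.9"), t)
        assert detect_scheme_id(t) == ("dmdScheme", "0.9.9")

    def test_missing_id_sheet_is_format_error(self, tmp_path):
        path = tmp_path / "plain.xlsx"
        wb = openpyxl.Workbook()
        wb.active.title = "Data"
        wb.save(path)
        with pytest.raises(WorkbookFormatError, match="_scheme"):
            read_metadata_workbook(path)
        with pytest.raises(WorkbookFormatError):
            detect_scheme_id(path)

    def test_corrupted_id_sheet(self, tmp_path):
        path = tmp_path / "bad.xlsx"
        wb = openpyxl.Workbook()
        wb.active.title = ID_SHEET
        wb.active.append(["unrelated", "junk"])
        wb.save(path)
        with pytest.raises(WorkbookFormatError, match="corrupted"):
            detect_scheme_id(path)

    def test_whitespace_stripped_and_trailing_empty_rows_dropped(
        self, scheme, tmp_path
    ):
        meta, _ = fx.make_filled_metadata(scheme)
        meta.tables["Species"][0]["speciesName"] = "  Tetrahymena thermophila  "
        meta.tables["Species"].append({"speciesName": "", "medium": "", "strainId": ""})
        path = tmp_path / "m.xlsx"
        write_filled_workbook(scheme, meta, path)
        back = read_metadata_workbook(path)
        assert back.tables["Species"][0]["speciesName"] == "Tetrahymena thermophila"
        assert len(back.tables["Species"]) == 3


class TestPlainTextTwin:
    def test_csv_dir_round_trip_matches_workbook(self, scheme, tmp_path):
        meta, _ = fx.make_filled_metadata(scheme, n_species=5, n_data_files=3)
        write_metadata_dir(meta, tmp_path / "d", scheme=scheme)
        from_dir = read_metadata_dir(tmp_path / "d")
        path = tmp_path / "m.xlsx"
        write_filled_workbook(scheme, meta, path)
        from_wb = read_metadata_workbook(path)
        assert from_dir == meta
        assert from_dir == from_wb

    def test_missing_identity_file(self, tmp_path):
        (tmp_path / "e").mkdir()
        with pytest.raises(WorkbookFormatError):
            read_metadata_dir(tmp_path / "e")
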