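"""Readers/writers: round trips, validation diagnostics, ordering."""

import random

import pytest

from mitooxtox import (
    ChemicalRecord,
    DetectedConcentration,
    MieClass,
    TableDialect,
    TreatmentKind,
    WellRecord,
    read_chemical_table,
    read_detection_table,
    read_well_table,
    write_chemical_table,
    write_detection_table,
    write_well_table,
)
from mitooxtox.assay_io import SchemaError, TableValidationError, parse_well_id
from mitooxtox.synthetic_data import chemical_records


def make_well(**kw):
    defaults = dict(
        plate_id="P1", well_id="A1", treatment_id="chemA",
        treatment_kind=TreatmentKind.CHEMICAL, dose=1e-6, dose_unit="M",
        red_signal=2000.0, green_signal=1000.0, cell_count=9500,
        luminescence=480.0, run_id="run1",
    )
    defaults.update(kw)
    return WellRecord(**defaults)


HEADER = ("plate_id,well_id,treatment_id,treatment_kind,dose,dose_unit,"
          "red_signal,green_signal,cell_count,luminescence,run_id")


class TestWellTable:
    def test_small_file_reads_all_rows(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text(
            HEADER + "\n"
            "P1,A1,chemA,chemical,1e-06,M,2000,1000,9500,480,run1\n"
            "P1,A2,chemA,chemical,5e-07,M,2100,1010,9800,490,run1\n"
            "P1,P24,solvent,solvent_control,0,none,2000,1000,10000,500,run1\n"
        )
        recs = read_well_table(p)
        assert len(recs) == 3
        assert recs[0].treatment_kind is TreatmentKind.CHEMICAL
        assert recs[-1].well_id == "P24"  # sorted to plate end

    @pytest.mark.parametrize(
        "bad_row,fragment",
        [
            ("P1,A1,chemA,chemical,1e-6,M,-5,1000,9500,480,run1", "red_signal"),
            ("P1,A1,chemA,chemical,1e-6,M,oops,1000,9500,480,run1", "non-numeric"),
            ("P1,Z1,chemA,chemical,1e-6,M,5,1000,9500,480,run1", "well id"),
            ("P1,A1,solvent,solvent_control,2e-6,none,5,1000,9500,480,run1", "nonzero dose"),
            ("P1,A1,chemA,chemical,0,M,5,1000,9500,480,run1", "dose 0"),
        ],
    )
    def test_invalid_rows_rejected_with_row_index(self, tmp_path, bad_row, fragment):
        p = tmp_path / "w.csv"
        p.write_text(
            HEADER + "\nP1,A1,chemA,chemical,1e-06,M,2000,1000,9500,480,run1\n" + bad_row + "\n"
        )
        with pytest.raises(TableValidationError, match="row 1") as exc:
            read_well_table(p)
        assert fragment in str(exc.value)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text("plate_id,well_id\nP1,A1\n")
        with pytest.raises(SchemaError, match="treatment_kind"):
            read_well_table(p)

    def test_round_trip_full_plate_lossless(self, tmp_path, clean_plate):
        p = tmp_path / "plate.csv"
        write_well_table(clean_plate, p)
        assert read_well_table(p) == sorted(
            clean_plate, key=lambda r: (r.plate_id, *r.well_position, r.run_id)
        )

    def test_reader_output_independent_of_row_order(self, tmp_path, clean_plate):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        shuffled = list(clean_plate)
        random.Random(5).shuffle(shuffled)
        write_well_table(clean_plate, p1)
        write_well_table(shuffled, p2)
        assert read_well_table(p1) == read_well_table(p2)

    def test_semicolon_decimal_comma_dialect(self, tmp_path):
        d = TableDialect(delimiter=";", decimal=",")
        p = tmp_path / "w.csv"
        recs = [make_well(dose=1.5e-6)]
        write_well_table(recs, p, d)
        assert ";" in p.read_text().splitlines()[1]
        assert read_well_table(p, d) == recs


class TestWellIdParsing:
    @pytest.mark.parametrize("wid,expected", [("A1", ("A", 1)), ("P24", ("P", 24)), ("B17", ("B", 17))])
    def test_valid(self, wid, expected):
        assert parse_well_id(wid) == expected

    @pytest.mark.parametrize("wid", ["Q1", "A0", "A25", "11", "AA1", ""])
    def test_invalid(self, wid):
        with pytest.raises(ValueError):
            parse_well_id(wid)


class TestChemicalTable:
    def test_single_row(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("chem_id,name,log_dlipw,mie_class\nrotenone,Rotenone,4.5,complexI\n")
        (rec,) = read_chemical_table(p)
        assert rec.mie_class is MieClass.COMPLEX_I
        assert rec.log_dlipw == 4.5

    def test_unknown_mie_class_warns_and_maps(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("chem_id,name,log_dlipw,mie_class\nx,,2.0,mystery\n")
        with pytest.warns(UserWarning, match="mystery"):
            (rec,) = read_chemical_table(p)
        assert rec.mie_class is MieClass.UNKNOWN

    def test_duplicate_chem_id_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("chem_id,name,log_dlipw,mie_class\nx,,2.0,uncoupler\nx,,2.1,uncoupler\n")
        with pytest.raises(TableValidationError, match="duplicate"):
            read_chemical_table(p)

    def test_synthetic_screen_round_trip(self, tmp_path):
        from mitooxtox import EndpointTruth, GenerativeChemical

        classes = ["complexI", "complexII", "complexIII", "complexV", "uncoupler", "baseline"]
        chems = [
            GenerativeChemical(
                f"c{i:02d}", mmp=EndpointTruth(90, 10.0 ** (-8 + i % 5), 1.5),
                cytotoxicity=None, log_dlipw=1.0 + 0.1 * i, mie_class=classes[i % 6],
            )
            for i in range(36)
        ]
        records = chemical_records(chems)
        p = tmp_path / "c.csv"
        write_chemical_table(records, p)
        back = read_chemical_table(p)
        assert back == sorted(records, key=lambda r: r.chem_id)
        assert [r.mie_class.value for r in back] == [
            r.mie_class.value for r in sorted(records, key=lambda r: r.chem_id)
        ]


class TestDetectionTable:
    def test_round_trip_and_duplicate_rejection(self, tmp_path):
        recs = [
            DetectedConcentration("S1", "24DNP", 4e-7),
            DetectedConcentration("S1", "azoxy", 5e-9),
            DetectedConcentration("S2", "24DNP", 1e-8),
        ]
        p = tmp_path / "d.csv"
        write_detection_table(recs, p)
        assert read_detection_table(p) == recs
        p.write_text(
            "sample_id,chem_id,concentration\nS1,x,1e-9\nS1,x,2e-9\n"
        )
        with pytest.raises(TableValidationError, match="duplicate"):
            read_detection_table(p)

    def test_negative_concentration_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("sample_id,chem_id,concentration\nS1,x,-1e-9\n")
        with pytest.raises(TableValidationError, match="row 0"):
            read_detection_table(p)
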