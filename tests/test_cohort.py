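"""Cohort I/O, validation, and the Bazett heart-rate correction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brsrisk import (
    Cohort,
    DomainError,
    PatientRecord,
    SchemaError,
    ValidationError,
    bazett_qtc,
    read_cohort,
    read_cohort_with_report,
    write_cohort,
)


def _record(pid="P1", **over):
    base = dict(
        patient_id=pid,
        age_years=50.0,
        sex="male",
        syncope=False,
        initial_type1=True,
        af=False,
        pvs_performed=False,
        icd=False,
        qrs_ms=100.0,
        qtc_ms=410.0,
        vtvf=False,
    )
    base.update(over)
    return PatientRecord(**base)


class TestBazett:
    @pytest.mark.parametrize(
        "qt, rr, expected",
        [(400.0, 1.0, 400.0), (400.0, 0.64, 500.0), (380.0, 0.81, 380.0 / 0.9)],
    )
    def test_known_values(self, qt, rr, expected):
        assert bazett_qtc(qt, rr) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("qt, rr", [(0.0, 1.0), (-5.0, 1.0), (400.0, 0.0), (400.0, -1.0)])
    def test_nonpositive_inputs_rejected(self, qt, rr):
        with pytest.raises(DomainError):
            bazett_qtc(qt, rr)

    @given(
        qt=st.floats(1.0, 600.0),
        rr=st.floats(0.3, 2.0),
        k=st.floats(0.1, 10.0),
    )
    def test_homogeneous_in_qt(self, qt, rr, k):
        assert bazett_qtc(k * qt, rr) == pytest.approx(
            k * bazett_qtc(qt, rr), rel=1e-12
        )


class TestRecordValidation:
    def test_qrs_out_of_range(self):
        with pytest.raises(ValidationError, match="qrs_ms"):
            _record(qrs_ms=-5.0)

    def test_pvs_positive_without_pvs(self):
        with pytest.raises(ValidationError, match="pvs_positive"):
            _record(pvs_performed=False, pvs_positive=True)

    def test_pvs_positive_required_when_performed(self):
        with pytest.raises(ValidationError, match="pvs_positive"):
            _record(pvs_performed=True, pvs_positive=None)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            Cohort(records=(_record("A"), _record("A")))


class TestCsvRoundTrip:
    def test_identity_on_fixture(self, table1_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(table1_cohort, path)
        back = read_cohort(path)
        assert len(back) == len(table1_cohort)
        for a, b in zip(table1_cohort, back):
            assert a == b

    def test_empty_cohort_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_cohort(Cohort(records=()), path)
        text = path.read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("patient_id,")
        assert len(read_cohort(path)) == 0

    def test_absent_optionals_preserved(self, tmp_path):
        rec = _record(qt_ms=None, rr_s=None, pvs_performed=False)
        path = tmp_path / "opt.csv"
        write_cohort(Cohort(records=(rec,)), path)
        back = read_cohort(path)
        assert back.records[0].qt_ms is None
        assert back.records[0].rr_s is None
        assert back.records[0].pvs_positive is None

    def test_three_row_file(self, tmp_path):
        cohort = Cohort(records=tuple(_record(f"P{i}") for i in range(3)))
        path = tmp_path / "three.csv"
        write_cohort(cohort, path)
        assert len(read_cohort(path)) == 3


class TestReadValidation:
    HEADER = (
        "patient_id,age_years,sex,syncope,initial_type1,af,pvs_performed,"
        "pvs_positive,icd,qrs_ms,qt_ms,rr_s,qtc_ms,vtvf"
    )

    def _write(self, tmp_path, rows, header=None):
        path = tmp_path / "c.csv"
        path.write_text("\n".join([header or self.HEADER, *rows]) + "\n")
        return path

    def test_negative_qrs_row_rejected_with_reason(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                "A,50,male,0,1,0,0,,0,100,,,410,0",
                "B,50,male,0,1,0,0,,0,-5,,,410,0",
            ],
        )
        cohort, reports = read_cohort_with_report(path)
        assert len(cohort) == 1
        assert len(reports) == 1
        assert reports[0].row_index == 1
        assert "qrs_ms" in reports[0].reason

    def test_inconsistent_pvs_row_rejected(self, tmp_path):
        path = self._write(tmp_path, ["A,50,male,0,1,0,0,1,0,100,,,410,0"])
        cohort, reports = read_cohort_with_report(path)
        assert len(cohort) == 0
        assert "pvs_positive" in reports[0].reason

    def test_missing_required_column_named(self, tmp_path):
        header = self.HEADER.replace("qrs_ms,", "")
        path = self._write(
            tmp_path, ["A,50,male,0,1,0,0,,0,,,410,0"], header=header
        )
        with pytest.raises(SchemaError, match="qrs_ms"):
            read_cohort(path)

    def test_unparseable_cell_reported_with_row_index(self, tmp_path):
        path = self._write(tmp_path, ["A,fifty,male,0,1,0,0,,0,100,,,410,0"])
        cohort, reports = read_cohort_with_report(path)
        assert len(cohort) == 0
        assert reports[0].row_index == 0
        assert "age_years" in reports[0].reason

    def test_duplicate_patient_id(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                "A,50,male,0,1,0,0,,0,100,,,410,0",
                "A,51,male,0,1,0,0,,0,100,,,410,0",
            ],
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_cohort(path)

    def test_qtc_derived_via_bazett_when_absent(self, tmp_path):
        path = self._write(tmp_path, ["A,50,male,0,1,0,0,,0,100,400,0.64,,0"])
        cohort = read_cohort(path)
        assert cohort.records[0].qtc_ms == pytest.approx(500.0)

    def test_schema_mapping(self, tmp_path):
        header = self.HEADER.replace("patient_id", "subject")
        path = self._write(
            tmp_path, ["A,50,male,0,1,0,0,,0,100,,,410,0"], header=header
        )
        cohort = read_cohort(path, schema={"patient_id": "subject"})
        assert cohort.records[0].patient_id == "A"
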