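"""ECG CSV dialects, calibration, and manifest loading."""
from datetime import date

import numpy as np
import pandas as pd
import pytest

from ecgtraj.signal_io import (LEAD_NAMES, EcgFormatError, EcgRecord,
                               load_manifest, read_ecg_csv, write_ecg_csv)


def make_record(rng, n=1000, scale=1.0):
    sig = rng.normal(0.0, 0.3, size=(12, n)) * scale
    return EcgRecord(signal=sig, patient_id="X", date=date(2021, 3, 1))


class TestRecordInvariants:
    def test_wrong_shape_rejected(self, rng):
        with pytest.raises(EcgFormatError):
            EcgRecord(signal=rng.normal(size=(11, 100)))

    def test_lead_order_enforced(self, rng):
        with pytest.raises(EcgFormatError):
            EcgRecord(signal=rng.normal(size=(12, 100)),
                      lead_names=tuple(reversed(LEAD_NAMES)))

    def test_nonfinite_rejected(self):
        sig = np.zeros((12, 50))
        sig[3, 10] = np.nan
        with pytest.raises(EcgFormatError):
            EcgRecord(signal=sig)


class TestRoundTrip:
    def test_mv_round_trip_bit_exact(self, rng, tmp_path):
        rec = make_record(rng)
        path = write_ecg_csv(rec, tmp_path / "a.csv")
        back = read_ecg_csv(path, expected_duration_s=None)
        # 6-decimal fixed formatting: exact equality after rounding to 1e-6 mV
        np.testing.assert_array_equal(back.signal, np.round(rec.signal, 6))
        assert np.max(np.abs(back.signal - rec.signal)) <= 5e-7

    def test_line_count_and_header(self, rng, tmp_path):
        rec = make_record(rng, n=7500)
        path = write_ecg_csv(rec, tmp_path / "b.csv")
        lines = path.read_text().splitlines()
        assert len(lines) == 7501
        assert lines[0] == "I,II,III,aVR,aVL,aVF,V1,V2,V3,V4,V5,V6"

    def test_second_write_is_byte_identical(self, rng, tmp_path):
        rec = make_record(rng)
        p1 = write_ecg_csv(rec, tmp_path / "c1.csv")
        p2 = write_ecg_csv(rec, tmp_path / "c2.csv")
        assert p1.read_bytes() == p2.read_bytes()


class TestCountsDialect:
    def test_single_count_calibration(self, tmp_path):
        # 800 counts at 1.25 uV/count = 1000 uV = 1.0 mV
        counts = np.zeros((12, 10), dtype=int)
        counts[1, 4] = 800
        df = pd.DataFrame(counts.T, columns=list(LEAD_NAMES))
        path = tmp_path / "counts.csv"
        df.to_csv(path, index=False)
        rec = read_ecg_csv(path, dialect="counts", expected_duration_s=None)
        assert rec.signal[1, 4] == pytest.approx(1.0)
        assert rec.signal.sum() == pytest.approx(1.0)

    def test_calibration_linearity(self, tmp_path, rng):
        counts = rng.integers(-500, 500, size=(12, 20))
        for k in (1, 3):
            df = pd.DataFrame((k * counts).T, columns=list(LEAD_NAMES))
            path = tmp_path / f"lin{k}.csv"
            df.to_csv(path, index=False)
            rec = read_ecg_csv(path, dialect="counts", expected_duration_s=None)
            if k == 1:
                base = rec.signal.copy()
            else:
                np.testing.assert_allclose(rec.signal, k * base, rtol=0, atol=1e-12)

    def test_all_zero_counts(self, tmp_path):
        df = pd.DataFrame(np.zeros((5, 12), dtype=int), columns=list(LEAD_NAMES))
        path = tmp_path / "zero.csv"
        df.to_csv(path, index=False)
        rec = read_ecg_csv(path, dialect="counts", expected_duration_s=None)
        assert not rec.signal.any()


class TestReadErrors:
    def test_wrong_columns(self, tmp_path):
        (tmp_path / "bad.csv").write_text("a,b,c\n1,2,3\n")
        with pytest.raises(EcgFormatError, match="expected header"):
            read_ecg_csv(tmp_path / "bad.csv")

    def test_non_numeric_cell(self, tmp_path):
        header = ",".join(LEAD_NAMES)
        rows = [",".join(["0.0"] * 12)] * 3
        rows[1] = rows[1].replace("0.0", "oops", 1)
        (tmp_path / "nan.csv").write_text(header + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(EcgFormatError, match="non-numeric"):
            read_ecg_csv(tmp_path / "nan.csv", expected_duration_s=None)

    def test_length_mismatch_warns_but_keeps(self, rng, tmp_path, caplog):
        rec = make_record(rng, n=100)
        path = write_ecg_csv(rec, tmp_path / "short.csv")
        with caplog.at_level("WARNING"):
            back = read_ecg_csv(path, expected_duration_s=15.0)
        assert back.n_samples == 100
        assert "expected 7500" in caplog.text

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_ecg_csv(tmp_path / "absent.csv")


class TestManifest:
    def test_cohort_round_trip(self, cohort_dir):
        out, data = cohort_dir
        manifest, patients = load_manifest(out / "manifest.csv")
        assert len(manifest) == len(data.manifest)
        assert [p.patient_id for p in patients] == \
            sorted({p.patient_id for p in data.patients})
        # visits are date-sorted and carry calibrated signals
        for p in patients:
            dates = [v.date for v in p.visits]
            assert dates == sorted(dates)
            assert p.visits[0].ecg.signal.shape[0] == 12

    def test_single_visit_patient_dropped(self, tmp_path, rng, caplog):
        rec = make_record(rng)
        write_ecg_csv(rec, tmp_path / "e1.csv")
        write_ecg_csv(rec, tmp_path / "e2.csv")
        write_ecg_csv(rec, tmp_path / "e3.csv")
        pd.DataFrame({
            "patient_id": ["A", "A", "B"],
            "visit_date": ["2021-01-01", "2021-06-01", "2021-01-01"],
            "ecg_path": ["e1.csv", "e2.csv", "e3.csv"],
            "bnp_pg_ml": [80.0, 120.0, 60.0],
        }).to_csv(tmp_path / "m.csv", index=False)
        with caplog.at_level("WARNING"):
            _, patients = load_manifest(tmp_path / "m.csv")
        assert [p.patient_id for p in patients] == ["A"]
        assert "dropped" in caplog.text

    def test_nonpositive_bnp_row_rejected(self, tmp_path, rng, caplog):
        rec = make_record(rng)
        for i in range(3):
            write_ecg_csv(rec, tmp_path / f"f{i}.csv")
        pd.DataFrame({
            "patient_id": ["A", "A", "A"],
            "visit_date": ["2021-01-01", "2021-06-01", "2021-09-01"],
            "ecg_path": ["f0.csv", "f1.csv", "f2.csv"],
            "bnp_pg_ml": [80.0, 0.0, 95.0],
        }).to_csv(tmp_path / "m.csv", index=False)
        with caplog.at_level("WARNING"):
            _, patients = load_manifest(tmp_path / "m.csv")
        assert patients[0].m == 2
        assert "rejected" in caplog.text

    def test_unsorted_dates_sorted(self, tmp_path, rng):
        rec = make_record(rng)
        for i in range(2):
            write_ecg_csv(rec, tmp_path / f"g{i}.csv")
        pd.DataFrame({
            "patient_id": ["A", "A"],
            "visit_date": ["2021-06-01", "2021-01-01"],
            "ecg_path": ["g0.csv", "g1.csv"],
            "bnp_pg_ml": [80.0, 90.0],
        }).to_csv(tmp_path / "m.csv", index=False)
        _, patients = load_manifest(tmp_path / "m.csv")
        assert [v.date.isoformat() for v in patients[0].visits] == \
            ["2021-01-01", "2021-06-01"]

    def test_missing_column_schema_error(self, tmp_path):
        pd.DataFrame({"patient_id": ["A"], "visit_date": ["2021-01-01"],
                      "bnp_pg_ml": [10.0]}).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(EcgFormatError, match="missing column"):
            load_manifest(tmp_path / "m.csv")
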