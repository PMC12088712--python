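"""ECG CSV reading/writing, calibration, and cohort-manifest loading.

On-disk dialects
----------------
``mv``      — floats in millivolts, 6-decimal fixed formatting (canonical).
``counts``  — integer ADC counts; calibrated on read at 1.25 µV per count
              (0.00125 mV), matching a 500 Hz / 1.25 µV acquisition chain.

Files carry the header ``I,II,III,aVR,aVL,aVF,V1,V2,V3,V4,V5,V6`` and one row
per sample; a 15 s record at 500 Hz is 7500 rows.  The 150 Hz anti-aliasing
low-pass of the recorder is an acquisition property and is not re-applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date, datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import BnpMeasurement, Patient, VisitPair

logger = logging.getLogger(__name__)

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")
N_LEADS = 12
DEFAULT_FS = 500.0           # Hz
DEFAULT_RESOLUTION_UV = 1.25  # microvolt per ADC count
DEFAULT_DURATION_S = 15.0
MV_PER_COUNT = DEFAULT_RESOLUTION_UV * 1e-3

MANIFEST_COLUMNS = ("patient_id", "visit_date", "ecg_path", "bnp_pg_ml")


class EcgFormatError(ValueError):
    pass


@dataclass
class EcgRecord:
    """A calibrated 12-lead ECG: ``signal`` is (12, T) in mV."""
    signal: np.ndarray
    fs: float = DEFAULT_FS
    resolution_uv: float = DEFAULT_RESOLUTION_UV
    patient_id: str = ""
    date: Date | None = None
    lead_names: tuple[str, ...] = LEAD_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        if self.signal.dtype not in (np.float32, np.float64):
            self.signal = self.signal.astype(np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] != N_LEADS:
            raise EcgFormatError(
                f"expected a ({N_LEADS}, T) lead x sample matrix, got {self.signal.shape}")
        if tuple(self.lead_names) != LEAD_NAMES:
            raise EcgFormatError(
                f"lead order must be {LEAD_NAMES}, got {tuple(self.lead_names)}")
        if not np.all(np.isfinite(self.signal)):
            raise EcgFormatError("ECG signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def write_ecg_csv(record: EcgRecord, path: str | Path, dialect: str = "mv") -> Path:
    """Write one record; ``mv`` uses fixed 6-decimal floats (exact round-trip
    at 1e-6 mV), ``counts`` rounds to integer ADC counts."""
    path = Path(path)
    header = ",".join(LEAD_NAMES)
    data = record.signal.T  # one row per sample
    if dialect == "mv":
        fmt, out = "%.6f", data
    elif dialect == "counts":
        fmt, out = "%d", np.rint(data / MV_PER_COUNT)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    np.savetxt(path, out, fmt=fmt, delimiter=",", header=header, comments="")
    return path


def read_ecg_csv(path: str | Path, dialect: str = "mv", fs: float = DEFAULT_FS,
                 expected_duration_s: float | None = DEFAULT_DURATION_S,
                 patient_id: str = "", date: Date | None = None) -> EcgRecord:
    """Read and calibrate one ECG CSV into mV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise EcgFormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    if list(df.columns) != list(LEAD_NAMES):
        raise EcgFormatError(
            f"{path}: expected header {','.join(LEAD_NAMES)}, got {','.join(map(str, df.columns))}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = int(np.argmax(~df.map(np.isreal).to_numpy().all(axis=1)))
        raise EcgFormatError(f"{path}: non-numeric cell at data row {bad}")
    signal = values.T.astype(np.float64)
    if dialect == "counts":
        signal = signal * MV_PER_COUNT
    elif dialect != "mv":
        raise ValueError(f"unknown dialect {dialect!r}")
    if expected_duration_s is not None:
        expected = int(round(fs * expected_duration_s))
        if signal.shape[1] != expected:
            logger.warning("%s: %d samples, expected %d (record kept)",
                           path, signal.shape[1], expected)
    return EcgRecord(signal=signal, fs=fs, patient_id=patient_id, date=date)


# -------------------------------------------------------------------------
# manifest
# -------------------------------------------------------------------------

@dataclass
class CohortManifest:
    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise EcgFormatError(f"manifest missing column(s): {missing}")
        dup = self.frame.duplicated(subset=["patient_id", "visit_date", "ecg_path"])
        if dup.any():
            raise EcgFormatError(
                f"manifest has {int(dup.sum())} duplicate (patient, date, path) row(s)")

    def __len__(self) -> int:
        return len(self.frame)


def _parse_date(value) -> Date:
    if isinstance(value, Date) and not isinstance(value, datetime):
        return value
    return datetime.strptime(str(value)[:10], "%Y-%m-%d").date()


def load_manifest(path: str | Path, ecg_dir: str | Path | None = None,
                  dialect: str = "mv", load_signals: bool = True
                  ) -> tuple[CohortManifest, list[Patient]]:
    """Load a cohort manifest CSV and group rows into Patients.

    Rows with BNP <= 0 are rejected (logged); patients left with fewer than
    two same-day pairs are dropped (logged).  Visits are date-sorted.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    manifest = CohortManifest(frame=frame)
    base = Path(ecg_dir) if ecg_dir is not None else path.parent

    patients: dict[str, list[VisitPair]] = {}
    for idx, row in frame.iterrows():
        bnp_val = float(row["bnp_pg_ml"])
        if not bnp_val > 0:
            logger.warning("manifest row %d (patient %s): BNP %.3g pg/mL <= 0, rejected",
                           idx, row["patient_id"], bnp_val)
            continue
        visit_date = _parse_date(row["visit_date"])
        ecg_path = Path(row["ecg_path"])
        if not ecg_path.is_absolute():
            ecg_path = base / ecg_path
        ecg = None
        if load_signals:
            ecg = read_ecg_csv(ecg_path, dialect=dialect,
                               patient_id=str(row["patient_id"]), date=visit_date)
        elif not ecg_path.exists():
            raise FileNotFoundError(f"manifest row {idx}: {ecg_path}")
        pid = str(row["patient_id"])
        patients.setdefault(pid, []).append(VisitPair(
            patient_id=pid, date=visit_date, ecg=ecg,
            bnp=BnpMeasurement(value=bnp_val, date=visit_date)))

    out: list[Patient] = []
    for pid in sorted(patients):
        visits = patients[pid]
        if len(visits) < 2:
            logger.warning("patient %s has %d visit(s) after filtering; dropped",
                           pid, len(visits))
            continue
        out.append(Patient(patient_id=pid, visits=visits))
    return manifest, out
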