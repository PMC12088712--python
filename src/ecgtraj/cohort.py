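"""Synthetic ECG+BNP cohort generator.

A latent heart-failure severity ``s`` in [0, 1] per visit drives both signals
the models consume:

* **BNP** (pg/mL): ``exp(alpha + beta * s + eps)``, ``eps ~ N(0, sigma)`` —
  log-linear in severity, so thresholded BNP labels are consistent with the
  latent state up to the noise ``sigma``.
* **ECG morphology**: each beat is a sum of five Gaussian waves (P, Q, R, S,
  T) per lead, tiled at the visit heart rate with lognormal RR jitter.
  Severity multiplies the R amplitude by ``(1 - e_R * s)``, the Q/R/S widths
  by ``(1 + e_W * s)`` and the T amplitude by ``(1 - e_T * s)`` — a stylised
  low-voltage / wide-QRS / flat-T picture of worsening failure.

Visits per patient are >= 2; inter-visit gaps are lognormal with a median of
172 days (metadata only).  Everything is reproducible from ``rng_seed``,
including bytes on disk.  The generator makes no claim of pathophysiological
realism (no arrhythmia, no vectorcardiographic consistency across leads); it
exists so that labeling, training and attention mapping are testable without
restricted hospital data.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import BnpMeasurement, Patient, VisitPair
from .signal_io import EcgRecord, write_ecg_csv

WAVE_NAMES = ("P", "Q", "R", "S", "T")

# Base beat template, lead II reference: (amplitude mV, offset s from R, width s)
_BASE_AMP = np.array([0.12, -0.10, 1.10, -0.22, 0.30])
_BASE_OFFSET = np.array([-0.20, -0.028, 0.0, 0.028, 0.30])
_BASE_WIDTH = np.array([0.025, 0.010, 0.012, 0.012, 0.055])
# Per-lead overall scale (sign = dominant R polarity of the lead)
_LEAD_SCALE = np.array([0.7, 1.0, 0.4, -0.8, 0.35, 0.7,
                        -0.5, 0.8, 1.0, 1.2, 1.1, 0.9])


@dataclass
class BeatTemplateParams:
    """Gaussian-sum beat model: per-lead, per-wave amplitude/offset/width."""
    amplitudes: np.ndarray = field(default_factory=lambda: np.outer(_LEAD_SCALE, _BASE_AMP))
    offsets: np.ndarray = field(default_factory=lambda: _BASE_OFFSET.copy())
    widths: np.ndarray = field(default_factory=lambda: _BASE_WIDTH.copy())

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != (12, len(WAVE_NAMES)):
            raise ValueError(f"amplitudes must be (12, 5), got {self.amplitudes.shape}")
        if np.any(self.widths <= 0):
            raise ValueError("wave widths must be positive")
        r = self.amplitudes[:, WAVE_NAMES.index("R")]
        if np.any(np.sign(r) != np.sign(_LEAD_SCALE)):
            raise ValueError("R-wave amplitude sign must match lead polarity")


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters; defaults are the package's moderate-effect
    study conditions (see the methods note)."""
    n_patients: int = 100
    visits_min: int = 2
    visits_max: int = 4                 # inclusive
    gap_days_median: float = 172.0
    gap_days_log_sd: float = 0.6
    bnp_intercept: float = float(np.log(15.0))   # alpha, log pg/mL
    bnp_slope: float = 3.0                       # beta, log pg/mL per unit severity
    bnp_noise: float = 0.3                       # sigma, log-scale SD
    effect_r_amp: float = 0.3                    # e_R
    effect_qrs_width: float = 0.15               # e_W
    effect_t_amp: float = 0.3                    # e_T
    hr_bpm_range: tuple[float, float] = (60.0, 90.0)
    rr_jitter_log_sd: float = 0.04
    baseline_wander_mv: float = 0.05
    noise_floor_mv: float = 0.01
    record_seconds: float = 15.0
    fs: float = 500.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.visits_min < 2 or self.visits_max < self.visits_min:
            raise ValueError("need visits_min >= 2 and visits_max >= visits_min")
        if self.bnp_slope < 0:
            raise ValueError("bnp_slope must be >= 0 (severity raises BNP)")
        n = self.fs * self.record_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * record_seconds must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.record_seconds))


EFFECT_PRESETS = {
    # severity confined to the QRS complex (R amplitude + QRS width): the
    # strong-effect condition used for recovery and attention-localization runs
    "strong": dict(bnp_noise=0.1, effect_r_amp=0.5, effect_qrs_width=0.25,
                   effect_t_amp=0.0),
    "moderate": dict(),
}


def spec_with_preset(spec: CohortSpec, preset: str) -> CohortSpec:
    try:
        return replace(spec, **EFFECT_PRESETS[preset])
    except KeyError:
        raise ValueError(f"unknown effect preset {preset!r}; "
                         f"choose from {sorted(EFFECT_PRESETS)}") from None


@dataclass
class SeverityTrajectory:
    patient_id: str
    severities: list[float]
    dates: list[Date]

    def __post_init__(self):
        if any(not 0 <= s <= 1 for s in self.severities):
            raise ValueError("severities must lie in [0, 1]")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("visit dates must be strictly increasing")


# -------------------------------------------------------------------------
# waveform synthesis
# -------------------------------------------------------------------------

def _severity_template(template: BeatTemplateParams, severity: float,
                       spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    amps = template.amplitudes.copy()
    widths = template.widths.copy()
    p, q, r, s, t = range(5)
    amps[:, r] *= 1.0 - spec.effect_r_amp * severity
    amps[:, t] *= 1.0 - spec.effect_t_amp * severity
    widths[[q, r, s]] *= 1.0 + spec.effect_qrs_width * severity
    return amps, widths


def synthesize_ecg(severity: float, hr_bpm: float, spec: CohortSpec,
                   rng: np.random.Generator,
                   template: BeatTemplateParams | None = None) -> EcgRecord:
    """One 12-lead record at the given severity and heart rate.

    Ground-truth R-peak sample indices, the severity and the heart rate are
    stored in ``record.meta`` for test assertions.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    if not hr_bpm > 0:
        raise ValueError(f"heart rate must be positive, got {hr_bpm}")
    template = template or BeatTemplateParams()
    fs, n = spec.fs, spec.n_samples
    t_axis = np.arange(n) / fs
    amps, widths = _severity_template(template, severity, spec)
    offsets = template.offsets

    rr_mean = 60.0 / hr_bpm
    # R-peak times with multiplicative lognormal jitter; pad past both edges
    # so partial beats at the borders are rendered.
    r_times = []
    t_r = float(rng.uniform(0.1, 0.1 + rr_mean))
    while t_r < spec.record_seconds + rr_mean:
        r_times.append(t_r)
        t_r += rr_mean * float(np.exp(rng.normal(0.0, spec.rr_jitter_log_sd)))
    signal = np.zeros((12, n), dtype=np.float32)
    for t_r in [r_times[0] - rr_mean] + r_times:
        for w in range(5):
            center = t_r + offsets[w]
            half = 4.0 * widths[w]
            lo = max(0, int(np.floor((center - half) * fs)))
            hi = min(n, int(np.ceil((center + half) * fs)) + 1)
            if hi <= lo:
                continue
            gauss = np.exp(-0.5 * ((t_axis[lo:hi] - center) / widths[w]) ** 2)
            signal[:, lo:hi] += amps[:, w, None] * gauss
    if spec.baseline_wander_mv > 0:
        f_w = rng.uniform(0.15, 0.4)
        phases = rng.uniform(0, 2 * np.pi, size=12)
        signal += (spec.baseline_wander_mv
                   * np.sin(2 * np.pi * f_w * t_axis[None, :] + phases[:, None])
                   ).astype(np.float32)
    if spec.noise_floor_mv > 0:
        signal += rng.normal(0.0, spec.noise_floor_mv, size=signal.shape).astype(np.float32)

    r_peaks = np.array([int(round(tr * fs)) for tr in r_times
                        if 0 <= int(round(tr * fs)) < n])
    return EcgRecord(signal=signal, fs=fs,
                     meta={"severity": severity, "hr_bpm": hr_bpm,
                           "r_peaks": r_peaks})


def severity_to_bnp(severity: float, spec: CohortSpec,
                    rng: np.random.Generator | None = None) -> float:
    """BNP pg/mL = exp(alpha + beta * severity + N(0, sigma))."""
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    eps = 0.0
    if spec.bnp_noise > 0:
        if rng is None:
            raise ValueError("rng required when bnp_noise > 0")
        eps = float(rng.normal(0.0, spec.bnp_noise))
    return float(np.exp(spec.bnp_intercept + spec.bnp_slope * severity + eps))


# -------------------------------------------------------------------------
# cohort assembly
# -------------------------------------------------------------------------

@dataclass
class CohortData:
    patients: list[Patient]
    manifest: pd.DataFrame
    trajectories: list[SeverityTrajectory]
    spec: CohortSpec


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> CohortData:
    """Generate the full cohort; optionally write ECG CSVs, the manifest and a
    ground-truth JSON sidecar (severities and R-peak indices) under ``out_dir``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    template = BeatTemplateParams()
    start = Date(2020, 1, 1)
    patients: list[Patient] = []
    trajectories: list[SeverityTrajectory] = []
    rows = []
    truth: dict[str, dict] = {}

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "ecg").mkdir(parents=True, exist_ok=True)

    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        m = int(rng.integers(spec.visits_min, spec.visits_max + 1))
        severities = rng.uniform(0.0, 1.0, size=m)
        gaps = np.maximum(1, np.round(np.exp(
            rng.normal(np.log(spec.gap_days_median), spec.gap_days_log_sd, size=m - 1)
        ))).astype(int)
        dates = [start + timedelta(days=int(d))
                 for d in np.concatenate([[0], np.cumsum(gaps)])]
        visits = []
        truth[pid] = {"severities": [float(s) for s in severities], "r_peaks": []}
        for s, d in zip(severities, dates):
            hr = float(rng.uniform(*spec.hr_bpm_range))
            ecg = synthesize_ecg(float(s), hr, spec, rng, template)
            ecg.patient_id, ecg.date = pid, d
            bnp = severity_to_bnp(float(s), spec, rng if spec.bnp_noise > 0 else None)
            rel_path = f"ecg/{pid}_{d.isoformat()}.csv"
            if out_path is not None:
                write_ecg_csv(ecg, out_path / rel_path)
            truth[pid]["r_peaks"].append([int(p) for p in ecg.meta["r_peaks"]])
            visits.append(VisitPair(patient_id=pid, date=d, ecg=ecg,
                                    bnp=BnpMeasurement(value=bnp, date=d)))
            rows.append({"patient_id": pid, "visit_date": d.isoformat(),
                         "ecg_path": rel_path, "bnp_pg_ml": bnp})
        patients.append(Patient(patient_id=pid, visits=visits))
        trajectories.append(SeverityTrajectory(
            patient_id=pid, severities=[float(s) for s in severities], dates=dates))

    manifest = pd.DataFrame(rows, columns=["patient_id", "visit_date", "ecg_path", "bnp_pg_ml"])
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False, float_format="%.6f")
        with open(out_path / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=0, sort_keys=True)
    return CohortData(patients=patients, manifest=manifest,
                      trajectories=trajectories, spec=spec)
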