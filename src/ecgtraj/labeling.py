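"""BNP-based heart-failure status labels, trajectory pairing and patient splits.

Heart-failure (HF) status change between two same-day ECG+BNP visits is
defined from the brain natriuretic peptide (BNP, pg/mL) measurements alone:

* ``improved``      — relative BNP change <= -40% AND baseline BNP >= 100 pg/mL
* ``deteriorated``  — relative BNP change >= +40% AND follow-up BNP >= 100 pg/mL
* ``no_change``     — everything else

with relative change = (follow_up - baseline) / baseline * 100%.  Both
inequalities are inclusive; a visit pair sitting exactly on the -40% / 100
pg/mL boundary is classified ``improved`` (symmetrically for deteriorated).

A patient with ``m`` visits contributes every chronological (earlier, later)
visit pair, i.e. ``m*(m-1)/2`` trajectory samples.  Dataset splitting is done
at the patient level so no patient's samples leak across train/validation/test.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date as Date
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .signal_io import EcgRecord

logger = logging.getLogger(__name__)

IMPROVED = "improved"
DETERIORATED = "deteriorated"
NO_CHANGE = "no_change"
CLASS_NAMES = (DETERIORATED, IMPROVED, NO_CHANGE)
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


class HfStatusLabel(str, Enum):
    improved = IMPROVED
    deteriorated = DETERIORATED
    no_change = NO_CHANGE


@dataclass(frozen=True)
class LabelThresholds:
    """Relative-change (percent) and absolute BNP (pg/mL) thresholds."""
    rel_change_pct: float = 40.0
    abs_bnp: float = 100.0

    def __post_init__(self):
        if self.rel_change_pct <= 0 or self.abs_bnp <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class BnpMeasurement:
    value: float          # pg/mL
    date: Date

    def __post_init__(self):
        if not (self.value > 0) or not math.isfinite(self.value):
            raise ValueError(f"BNP must be a positive finite pg/mL value, got {self.value}")


@dataclass
class VisitPair:
    """One same-day (ECG, BNP) measurement pair."""
    patient_id: str
    date: Date
    ecg: "EcgRecord | None"
    bnp: BnpMeasurement

    def __post_init__(self):
        if self.bnp.date != self.date:
            raise ValueError(
                f"visit {self.patient_id}/{self.date}: BNP dated {self.bnp.date} "
                "(ECG and BNP must be same-day)")

    @property
    def log_bnp(self) -> float:
        return log_bnp(self.bnp.value)


@dataclass
class Patient:
    patient_id: str
    visits: list[VisitPair] = field(default_factory=list)

    def __post_init__(self):
        self.visits = sorted(self.visits, key=lambda v: v.date)
        dates = [v.date for v in self.visits]
        if len(set(dates)) != len(dates):
            raise ValueError(f"patient {self.patient_id}: duplicate visit dates")

    @property
    def m(self) -> int:
        return len(self.visits)


@dataclass
class TrajectorySample:
    baseline: VisitPair
    follow_up: VisitPair
    label: HfStatusLabel
    rel_change: float     # percent

    def __post_init__(self):
        if self.baseline.patient_id != self.follow_up.patient_id:
            raise ValueError("trajectory sample spans two patients")
        if not self.baseline.date < self.follow_up.date:
            raise ValueError("baseline must strictly precede follow-up")

    @property
    def patient_id(self) -> str:
        return self.baseline.patient_id

    @property
    def class_index(self) -> int:
        return CLASS_INDEX[self.label.value]


# -------------------------------------------------------------------------
# labeling rules
# -------------------------------------------------------------------------

def relative_bnp_change(baseline_bnp: float, follow_up_bnp: float) -> float:
    """Signed percent change (follow_up - baseline) / baseline * 100."""
    if not baseline_bnp > 0:
        raise ValueError(f"baseline BNP must be > 0 pg/mL, got {baseline_bnp}")
    if not follow_up_bnp > 0:
        raise ValueError(f"follow-up BNP must be > 0 pg/mL, got {follow_up_bnp}")
    return (follow_up_bnp - baseline_bnp) / baseline_bnp * 100.0


def classify_status(baseline_bnp: float, follow_up_bnp: float,
                    thresholds: LabelThresholds = LabelThresholds()) -> HfStatusLabel:
    """Three-class HF status change from two BNP values (inclusive thresholds)."""
    rel = relative_bnp_change(baseline_bnp, follow_up_bnp)
    if rel <= -thresholds.rel_change_pct and baseline_bnp >= thresholds.abs_bnp:
        return HfStatusLabel.improved
    if rel >= thresholds.rel_change_pct and follow_up_bnp >= thresholds.abs_bnp:
        return HfStatusLabel.deteriorated
    return HfStatusLabel.no_change


def log_bnp(value: float, base: str = "e") -> float:
    """Logarithm of a BNP value (natural log by default, ``base='10'`` optional)."""
    if not value > 0:
        raise ValueError(f"BNP must be > 0 to take a logarithm, got {value}")
    return math.log10(value) if base == "10" else math.log(value)


def build_trajectory_samples(patient: Patient,
                             thresholds: LabelThresholds = LabelThresholds()
                             ) -> list[TrajectorySample]:
    """All m*(m-1)/2 chronological visit pairs of one patient, labeled."""
    if patient.m < 2:
        logger.warning("patient %s has %d visit(s); skipped (need >= 2)",
                       patient.patient_id, patient.m)
        return []
    samples = []
    for i in range(patient.m):
        for j in range(i + 1, patient.m):
            b, f = patient.visits[i], patient.visits[j]
            samples.append(TrajectorySample(
                baseline=b, follow_up=f,
                label=classify_status(b.bnp.value, f.bnp.value, thresholds),
                rel_change=relative_bnp_change(b.bnp.value, f.bnp.value)))
    return samples


# -------------------------------------------------------------------------
# splitting
# -------------------------------------------------------------------------

SPLIT_NAMES = ("train", "validation", "test")


@dataclass
class DatasetSplit:
    assignment: dict[str, str]          # patient_id -> split name
    fractions: tuple[float, float, float]
    seed: int

    def patients_in(self, split: str) -> list[str]:
        return [pid for pid, s in self.assignment.items() if s == split]

    def of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def subset(self, samples: Iterable[TrajectorySample], split: str) -> list[TrajectorySample]:
        return [s for s in samples if self.assignment[s.patient_id] == split]


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    sizes = [int(math.floor(r)) for r in raw]
    rem = n - sum(sizes)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def split_patients(patients: Sequence[Patient],
                   fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                   seed: int = 0) -> DatasetSplit:
    """Patient-level random 70/15/15 partition (largest-remainder rounding)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    ids = [p.patient_id for p in patients]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate patient ids")
    if len(ids) < len(SPLIT_NAMES):
        raise ValueError(f"need at least {len(SPLIT_NAMES)} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = list(np.array(sorted(ids))[rng.permutation(len(ids))])
    sizes = _largest_remainder_sizes(len(ids), fractions)
    assignment: dict[str, str] = {}
    start = 0
    for name, size in zip(SPLIT_NAMES, sizes):
        for pid in order[start:start + size]:
            assignment[pid] = name
        start += size
    return DatasetSplit(assignment=assignment, fractions=tuple(fractions), seed=seed)
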