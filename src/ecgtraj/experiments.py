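"""Desk-scale study runners: synthetic-recovery, chance-floor, QRS-recovery
and attention-localization experiments, each fully seeded.

These functions define the package's reference study conditions (cohort
size, effect preset, tiny model configuration, optimization budget) in one
place so tests, scripts and documentation all exercise the same experiment.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .cohort import CohortData, CohortSpec, generate_cohort, spec_with_preset, synthesize_ecg
from .interpret import class_averaged_map, detect_qrs, qrs_window_ratio
from .labeling import (DatasetSplit, TrajectorySample, build_trajectory_samples,
                       split_patients)
from .metrics import BootstrapSpec
from .model import tiny_config
from .train import DehtModel, DehtResults, EbtModel, TrainConfig

#: study conditions for the scaled-down recovery experiments
N_PATIENTS = 200
EFFECT_PRESET = "strong"

RECOVERY_TRAIN = TrainConfig(batch_size=16, lr=1e-3, max_steps=800,
                             eval_every=50, patience=8, max_val_samples=128)
CHANCE_TRAIN = TrainConfig(batch_size=16, lr=1e-3, max_steps=300,
                           eval_every=50, patience=8, max_val_samples=128)


@dataclass
class StudyData:
    cohort: CohortData
    split: DatasetSplit
    samples: dict[str, list[TrajectorySample]]
    visits: dict[str, list]


def make_study_cohort(seed: int, n_patients: int = N_PATIENTS,
                      preset: str = EFFECT_PRESET) -> StudyData:
    """Generate the cohort and patient-level 70/15/15 split."""
    spec = spec_with_preset(CohortSpec(n_patients=n_patients, rng_seed=seed), preset)
    cohort = generate_cohort(spec)
    split = split_patients(cohort.patients, seed=seed + 1)
    all_samples = [s for p in cohort.patients for s in build_trajectory_samples(p)]
    samples = {name: split.subset(all_samples, name)
               for name in ("train", "validation", "test")}
    visits = {name: [v for p in cohort.patients
                     if split.of(p.patient_id) == name for v in p.visits]
              for name in ("train", "validation", "test")}
    return StudyData(cohort=cohort, split=split, samples=samples, visits=visits)


def run_deht_recovery(seed: int, study: StudyData | None = None,
                      n_boot: int = 200) -> dict:
    """Train the tiny dual-ECG classifier on the strong-effect cohort and
    evaluate on held-out test patients (one sample per patient)."""
    study = study or make_study_cohort(seed)
    model = DehtModel(study.samples["train"], study.samples["validation"],
                      tiny_config(n_lead_tokens=24, head="classification_3", seed=seed),
                      dataclasses.replace(RECOVERY_TRAIN, seed=seed))
    results = model.fit()
    report = results.evaluate(study.samples["test"],
                              BootstrapSpec(n_boot=n_boot, seed=seed),
                              seed=seed, one_per_patient=True)
    return {"study": study, "results": results, "report": report,
            "weighted_auroc": report.weighted["auroc"],
            "accuracy": report.accuracy}


def run_ebt_recovery(seed: int, study: StudyData | None = None,
                     n_boot: int = 200) -> dict:
    """Train the tiny single-ECG log-BNP regressor; evaluate on test visits."""
    study = study or make_study_cohort(seed)
    model = EbtModel(study.visits["train"], study.visits["validation"],
                     tiny_config(n_lead_tokens=12, head="regression", seed=seed),
                     dataclasses.replace(RECOVERY_TRAIN, seed=seed))
    results = model.fit()
    report = results.evaluate(study.visits["test"],
                              BootstrapSpec(n_boot=n_boot, seed=seed), seed=seed)
    return {"study": study, "results": results, "report": report,
            "pearson_r": report.pearson_r, "mae_log": report.mae}


def shuffle_labels(samples: list[TrajectorySample], seed: int) -> list[TrajectorySample]:
    """Return copies with labels permuted across samples (class priors kept)."""
    rng = np.random.default_rng(seed)
    labels = [s.label for s in samples]
    perm = rng.permutation(len(labels))
    return [dataclasses.replace(s, label=labels[int(j)]) for s, j in zip(samples, perm)]


def run_chance_floor(seed: int, study: StudyData | None = None) -> dict:
    """Label-shuffled training: test weighted AUROC should sit at chance.

    Evaluated on all held-out trajectory samples with 3 independent window
    draws each, to keep the sampling error of the AUROC estimate small.
    """
    study = study or make_study_cohort(seed)
    model = DehtModel(shuffle_labels(study.samples["train"], seed + 10),
                      shuffle_labels(study.samples["validation"], seed + 11),
                      tiny_config(n_lead_tokens=24, head="classification_3",
                                  seed=seed + 1),
                      dataclasses.replace(CHANCE_TRAIN, seed=seed))
    results = model.fit()
    report = results.evaluate(study.samples["test"],
                              BootstrapSpec(n_boot=200, seed=seed),
                              seed=seed, one_per_patient=False, n_draws=3)
    return {"study": study, "results": results, "report": report,
            "weighted_auroc": report.weighted["auroc"]}


def run_attention_localization(deht: DehtResults, study: StudyData,
                               seed: int = 0, max_samples: int = 20) -> dict:
    """Class-averaged fused heatmaps on the beat grid for the held-out set;
    the QRS-window / background ratio quantifies localization."""
    out = {"per_class": {}}
    ratios = []
    test = study.samples["test"]
    present = sorted({s.label.value for s in test})
    maps = {}
    for cls in present:
        amap = class_averaged_map(deht.network, test, cls, seed=seed,
                                  max_samples=max_samples)
        r = qrs_window_ratio(amap)
        maps[cls] = amap
        out["per_class"][cls] = r
        ratios.append((amap.n_beats, r))
    total = sum(n for n, _ in ratios)
    out["ratio"] = float(sum(n * r for n, r in ratios) / total)
    out["maps"] = maps
    return out


def run_qrs_recovery(seed: int, n_records: int = 20,
                     tolerance_ms: float = 20.0) -> dict:
    """Detector recall against generator ground truth on noiseless records."""
    spec = CohortSpec(noise_floor_mv=0.0, baseline_wander_mv=0.0, rng_seed=seed)
    rng = np.random.default_rng(seed)
    tol = int(round(tolerance_ms * 1e-3 * spec.fs))
    n_true = n_hit = 0
    errors = []
    for _ in range(n_records):
        sev = float(rng.uniform(0, 1))
        hr = float(rng.uniform(*spec.hr_bpm_range))
        rec = synthesize_ecg(sev, hr, spec, rng)
        truth = np.asarray(rec.meta["r_peaks"])
        found = detect_qrs(rec.signal[1], spec.fs).indices
        n_true += truth.size
        for t in truth:
            if found.size:
                err = np.min(np.abs(found - t))
                if err <= tol:
                    n_hit += 1
                    errors.append(err / spec.fs * 1e3)
    return {"recall": n_hit / n_true, "n_true_peaks": n_true,
            "mean_error_ms": float(np.mean(errors)) if errors else np.nan}
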