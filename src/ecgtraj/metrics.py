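"""Evaluation metrics: regression report, one-vs-rest class metrics with
support-weighted aggregates, percentile-bootstrap confidence intervals, and
the one-test-per-patient evaluation protocol.

Thresholded metrics (precision, recall, specificity, F1, accuracy) are
computed from argmax predictions; AUROC and AUPRC use the class's predicted
probability as the score.  "Weighted" aggregates average per-class values
with weights equal to the number of true instances of each class.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .labeling import CLASS_NAMES, TrajectorySample

THRESHOLD_METRICS = ("accuracy", "precision", "recall", "specificity", "f1")
SCORE_METRICS = ("auroc", "auprc")
ALL_METRICS = THRESHOLD_METRICS + SCORE_METRICS


@dataclass(frozen=True)
class BootstrapSpec:
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")


def bootstrap_ci(metric_function, n: int, boot: BootstrapSpec) -> tuple[float, float]:
    """Percentile CI of ``metric_function(indices)`` over ``boot.n_boot``
    resamples (with replacement) of ``range(n)``.  Resamples on which the
    metric is undefined (raises ``ValueError``) are redrawn.
    """
    if n < 10:
        raise ValueError(f"need at least 10 evaluation samples, got {n}")
    rng = np.random.default_rng(boot.seed)
    values = []
    redraws = 0
    while len(values) < boot.n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            values.append(float(metric_function(idx)))
        except ValueError:
            redraws += 1
            if redraws > 50 * boot.n_boot:
                raise RuntimeError("metric undefined on almost every resample")
    alpha = (1.0 - boot.ci_level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# -------------------------------------------------------------------------
# regression
# -------------------------------------------------------------------------

@dataclass
class RegressionReport:
    pearson_r: float
    pearson_r_ci: tuple[float, float]
    mae: float
    mae_ci: tuple[float, float]
    n: int

    def summary(self) -> str:
        return (f"log-BNP regression (n={self.n})\n"
                f"  Pearson r : {self.pearson_r:.3f} "
                f"(95% CI {self.pearson_r_ci[0]:.3f}-{self.pearson_r_ci[1]:.3f})\n"
                f"  MAE (log) : {self.mae:.3f} "
                f"(95% CI {self.mae_ci[0]:.3f}-{self.mae_ci[1]:.3f})")


def evaluate_regression(pred_log_bnp: np.ndarray, true_log_bnp: np.ndarray,
                        boot: BootstrapSpec = BootstrapSpec()) -> RegressionReport:
    pred = np.asarray(pred_log_bnp, dtype=float)
    true = np.asarray(true_log_bnp, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1 or pred.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.std(pred) == 0 or np.std(true) == 0:
        raise ValueError("Pearson r undefined for zero-variance input")
    r = float(stats.pearsonr(pred, true).statistic)
    mae = float(np.mean(np.abs(pred - true)))

    def _r(idx):
        if np.std(pred[idx]) == 0 or np.std(true[idx]) == 0:
            raise ValueError("degenerate resample")
        return stats.pearsonr(pred[idx], true[idx]).statistic

    r_ci = bootstrap_ci(_r, pred.size, boot)
    mae_ci = bootstrap_ci(lambda idx: np.mean(np.abs(pred[idx] - true[idx])),
                          pred.size, boot)
    return RegressionReport(pearson_r=r, pearson_r_ci=r_ci, mae=mae,
                            mae_ci=mae_ci, n=pred.size)


# -------------------------------------------------------------------------
# classification
# -------------------------------------------------------------------------

def ovr_class_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                      positive_class: int) -> dict[str, float]:
    """One-vs-rest metrics for one class of a 3-class problem.

    ``y_true`` holds integer class indices, ``y_prob`` is (n, 3) with rows
    summing to 1.  Thresholded metrics binarize argmax predictions.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_prob.ndim != 2 or y_prob.shape[0] != y_true.size:
        raise ValueError("y_prob must be (n, n_classes) matching y_true")
    pos = y_true == positive_class
    if not pos.any():
        raise ValueError(f"class {positive_class} absent from y_true; AUROC undefined")
    pred_pos = y_prob.argmax(axis=1) == positive_class
    tp = float(np.sum(pos & pred_pos))
    fp = float(np.sum(~pos & pred_pos))
    fn = float(np.sum(pos & ~pred_pos))
    tn = float(np.sum(~pos & ~pred_pos))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn)
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    out = {
        "accuracy": (tp + tn) / y_true.size,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
        "support": int(pos.sum()),
    }
    if pos.all():
        raise ValueError("negative class empty; AUROC/AUPRC undefined")
    out["auroc"] = float(roc_auc_score(pos, y_prob[:, positive_class]))
    out["auprc"] = float(average_precision_score(pos, y_prob[:, positive_class]))
    return out


def weighted_metrics(per_class: dict[str, dict[str, float]]) -> dict[str, float]:
    """Support-weighted aggregate of per-class one-vs-rest metrics."""
    supports = np.array([per_class[c]["support"] for c in per_class], dtype=float)
    if np.any(supports <= 0):
        raise ValueError("all included classes need positive support")
    out = {}
    for m in ALL_METRICS:
        vals = np.array([per_class[c][m] for c in per_class])
        out[m] = float(np.sum(supports * vals) / supports.sum())
    return out


def overall_accuracy(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_prob).argmax(axis=1)))


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics with bootstrap CIs, weighted aggregates
    and overall accuracy — the shape of a standard multi-class report table."""
    per_class: dict[str, dict[str, float]]
    per_class_ci: dict[str, dict[str, tuple[float, float]]]
    weighted: dict[str, float]
    weighted_ci: dict[str, tuple[float, float]]
    accuracy: float
    accuracy_ci: tuple[float, float]
    supports: dict[str, int]
    n: int = 0
    class_names: tuple[str, ...] = field(default=CLASS_NAMES)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cname in self.class_names:
            row = {"class": cname}
            for m in ALL_METRICS:
                lo, hi = self.per_class_ci[cname][m]
                row[m] = self.per_class[cname][m]
                row[f"{m}_ci"] = f"({lo:.3f}-{hi:.3f})"
            rows.append(row)
        row = {"class": "overall"}
        for m in ALL_METRICS:
            lo, hi = self.weighted_ci[m]
            row[m] = self.weighted[m]
            row[f"{m}_ci"] = f"({lo:.3f}-{hi:.3f})"
        row["accuracy"] = self.accuracy
        lo, hi = self.accuracy_ci
        row["accuracy_ci"] = f"({lo:.3f}-{hi:.3f})"
        rows.append(row)
        return pd.DataFrame(rows).set_index("class")

    def summary(self) -> str:
        with pd.option_context("display.width", 160, "display.max_columns", 30):
            return (f"HF status classification (n={self.n})\n"
                    + self.to_frame().round(3).to_string())


def classification_report(y_true: np.ndarray, y_prob: np.ndarray,
                          boot: BootstrapSpec = BootstrapSpec(),
                          class_names: tuple[str, ...] = CLASS_NAMES) -> MetricsReport:
    """Full one-vs-rest report with percentile-bootstrap CIs."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    present = [c for c in range(len(class_names)) if (y_true == c).any()]
    per_class, per_ci = {}, {}
    for c in present:
        name = class_names[c]
        per_class[name] = ovr_class_metrics(y_true, y_prob, c)
        per_ci[name] = {}
        for m in ALL_METRICS:
            per_ci[name][m] = bootstrap_ci(
                lambda idx, c=c, m=m: ovr_class_metrics(y_true[idx], y_prob[idx], c)[m],
                y_true.size, boot)
    weighted = weighted_metrics(per_class)
    weighted_ci = {}
    for m in ALL_METRICS:
        def _w(idx, m=m):
            pc = {class_names[c]: ovr_class_metrics(y_true[idx], y_prob[idx], c)
                  for c in present if (y_true[idx] == c).any()}
            return weighted_metrics(pc)[m]
        weighted_ci[m] = bootstrap_ci(_w, y_true.size, boot)
    acc = overall_accuracy(y_true, y_prob)
    acc_ci = bootstrap_ci(lambda idx: overall_accuracy(y_true[idx], y_prob[idx]),
                          y_true.size, boot)
    return MetricsReport(
        per_class=per_class, per_class_ci=per_ci, weighted=weighted,
        weighted_ci=weighted_ci, accuracy=acc, accuracy_ci=acc_ci,
        supports={class_names[c]: int((y_true == c).sum()) for c in present},
        n=int(y_true.size),
        class_names=tuple(class_names[c] for c in present))


def sample_one_per_patient(samples: list[TrajectorySample], seed: int = 0
                           ) -> list[TrajectorySample]:
    """Uniformly pick exactly one trajectory sample per distinct patient."""
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[TrajectorySample]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, []).append(s)
    return [group[int(rng.integers(len(group)))]
            for _, group in sorted(by_patient.items())]
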