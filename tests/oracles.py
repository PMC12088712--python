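"""Independent brute-force oracles used to cross-check the package.

Deliberately naive implementations (loops, pair counting, literal truth
tables) kept free of any code path they are used to verify.
"""
from __future__ import annotations

import numpy as np


def truth_table_label(baseline: float, follow_up: float,
                      rel_pct: float = 40.0, abs_bnp: float = 100.0) -> str:
    """Literal rule-by-rule re-statement of the three-class criteria."""
    rel = (follow_up - baseline) / baseline * 100.0
    improved = (rel <= -rel_pct) and (baseline >= abs_bnp)
    deteriorated = (rel >= rel_pct) and (follow_up >= abs_bnp)
    if improved and deteriorated:
        raise AssertionError("labels must be mutually exclusive")
    if improved:
        return "improved"
    if deteriorated:
        return "deteriorated"
    return "no_change"


def naive_auroc(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney pair counting with half-credit for ties."""
    pos = scores[y_bin == 1]
    neg = scores[y_bin == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def naive_auprc(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """Average precision: sum of (recall step) x precision at each threshold."""
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(y_bin)[order]
    s = np.asarray(scores)[order]
    n_pos = y.sum()
    tp = fp = 0
    last_recall = 0.0
    ap = 0.0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:   # process tied scores as one cut
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - last_recall) * precision
        last_recall = recall
        i = j
    return float(ap)


def naive_ovr_metrics(y_true: np.ndarray, y_prob: np.ndarray, cls: int) -> dict:
    pred = np.argmax(y_prob, axis=1)
    tp = fp = fn = tn = 0
    for yt, yp in zip(y_true, pred):
        if yt == cls and yp == cls:
            tp += 1
        elif yt != cls and yp == cls:
            fp += 1
        elif yt == cls and yp != cls:
            fn += 1
        else:
            tn += 1
    y_bin = (np.asarray(y_true) == cls).astype(int)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn)
    return {
        "accuracy": (tp + tn) / len(y_true),
        "precision": precision,
        "recall": recall,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "f1": (2 * precision * recall / (precision + recall)
               if precision + recall else 0.0),
        "auroc": naive_auroc(y_bin, y_prob[:, cls]),
        "auprc": naive_auprc(y_bin, y_prob[:, cls]),
        "support": int(y_bin.sum()),
    }


def naive_weighted(y_true: np.ndarray, y_prob: np.ndarray) -> dict:
    classes = sorted(set(int(c) for c in y_true))
    per = {c: naive_ovr_metrics(y_true, y_prob, c) for c in classes}
    total = sum(per[c]["support"] for c in classes)
    out = {}
    for m in ("accuracy", "precision", "recall", "specificity", "f1", "auroc", "auprc"):
        out[m] = sum(per[c]["support"] * per[c][m] for c in classes) / total
    return out
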