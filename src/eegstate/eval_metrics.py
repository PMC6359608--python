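"""Three-class evaluation: confusion matrix, per-class sensitivity and
specificity, accuracy, one-vs-rest ROC/AUC and precision-recall curves.

The confusion matrix uses the fixed clinical class order
[healthy {OZ} = -1, interictal {FN} = 0, ictal {S} = 1], rows = true
class, columns = predicted.  Per-class rates follow the three-class
definitions used in the epilepsy-detection literature:

    SEN_i = A_ii / A_i
    SPE_i = sum_{j != i, k != i} A_jk / sum_{j != i} A_j
    ACC   = trace / total

Note the specificity excludes both row i and column i — it is the
accuracy of the classifier restricted to the other two classes, not the
usual one-vs-rest true-negative rate; ``spec_mode="standard"`` provides
the conventional formula (TN / (TN + FP) over the rest-vs-i split).
Undefined rates (zero denominator) are reported as NaN, never as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: Fixed evaluation class order: healthy, interictal, ictal.
CLASS_ORDER = (-1, 0, 1)
CLASS_NAMES = {-1: "OZ", 0: "FN", 1: "S"}


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted, order [OZ, FN, S]."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError(f"expected a 3x3 matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count matrix A_ij = #{true = class i, predicted = class j}."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    index = {c: i for i, c in enumerate(CLASS_ORDER)}
    bad = set(np.unique(y_true)) | set(np.unique(y_pred))
    bad -= set(CLASS_ORDER)
    if bad:
        raise ValueError(f"labels {sorted(bad)} outside {list(CLASS_ORDER)}")
    counts = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[int(t)], index[int(p)]] += 1
    return ConfusionMatrix(counts=counts)


def three_class_metrics(cm: ConfusionMatrix, spec_mode: str = "literature"
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """(sensitivity per class, specificity per class, accuracy).

    Rates with a zero denominator come back as NaN.  ``spec_mode``:
    ``"literature"`` (default) uses the 2x2-block definition above;
    ``"standard"`` the conventional one-vs-rest TN / (TN + FP).
    """
    A = cm.counts.astype(float)
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    row = A.sum(axis=1)
    col = A.sum(axis=0)
    sen = np.full(3, np.nan)
    spe = np.full(3, np.nan)
    for i in range(3):
        if row[i] > 0:
            sen[i] = A[i, i] / row[i]
        rest_rows = row.sum() - row[i]
        if rest_rows > 0:
            if spec_mode == "literature":
                mask = np.ones(3, dtype=bool)
                mask[i] = False
                spe[i] = A[np.ix_(mask, mask)].sum() / rest_rows
            elif spec_mode == "standard":
                fp = col[i] - A[i, i]
                tn = rest_rows - fp
                spe[i] = tn / rest_rows
            else:
                raise ValueError(f"unknown spec_mode {spec_mode!r}")
    acc = float(np.trace(A) / cm.total)
    return sen, spe, acc


def _binary_curve(y_bin: np.ndarray, scores: np.ndarray):
    """Cumulative TP/FP counts along decreasing score thresholds.

    Returns (tps, fps, thresholds) evaluated after each distinct score
    value, the standard threshold sweep.
    """
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    y_bin = y_bin[order]
    distinct = np.flatnonzero(np.diff(scores)) if len(scores) > 1 else np.array([], int)
    idx = np.r_[distinct, len(scores) - 1]
    tps = np.cumsum(y_bin)[idx]
    fps = np.cumsum(1 - y_bin)[idx]
    return tps, fps, scores[idx]


def roc_auc_ovr(y_true, proba: np.ndarray, class_code: int
                ) -> tuple[np.ndarray, float]:
    """One-vs-rest ROC points and trapezoidal AUC for one class.

    ``proba`` columns follow :data:`CLASS_ORDER`.  Returns an (m, 2)
    array of (FPR, TPR) points from (0,0) to (1,1) and the AUC, which by
    construction equals the probability that a random positive outscores
    a random negative (ties counting half).
    """
    y_true = np.asarray(y_true)
    proba = np.atleast_2d(np.asarray(proba, dtype=float))
    j = CLASS_ORDER.index(class_code)
    scores = proba[:, j]
    y_bin = (y_true == class_code).astype(int)
    P = y_bin.sum()
    N = len(y_bin) - P
    if P == 0 or N == 0:
        raise ValueError(
            f"class {class_code}: need both positives and negatives for ROC")
    tps, fps, _ = _binary_curve(y_bin, scores)
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def macro_auc(y_true, proba: np.ndarray) -> float:
    """Unweighted mean one-vs-rest AUC over the three classes."""
    return float(np.mean([roc_auc_ovr(y_true, proba, c)[1] for c in CLASS_ORDER]))


def precision_recall_ovr(y_true, proba: np.ndarray, class_code: int
                         ) -> np.ndarray:
    """One-vs-rest precision-recall points for one class.

    Returns an (m, 2) array of (recall, precision) at each distinct
    threshold, swept from high to low score so recall is nondecreasing.
    """
    y_true = np.asarray(y_true)
    proba = np.atleast_2d(np.asarray(proba, dtype=float))
    j = CLASS_ORDER.index(class_code)
    scores = proba[:, j]
    y_bin = (y_true == class_code).astype(int)
    P = y_bin.sum()
    if P == 0:
        raise ValueError(f"class {class_code}: no positives for PRC")
    tps, fps, _ = _binary_curve(y_bin, scores)
    recall = tps / P
    precision = tps / (tps + fps)
    return np.column_stack([recall, precision])


@dataclass
class EvaluationReport:
    """Bundle of all evaluation outputs for one classifier run."""

    cm: ConfusionMatrix
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: float
    auc: dict = field(default_factory=dict)
    macro_auc: float = float("nan")
    roc: dict = field(default_factory=dict)
    prc: dict = field(default_factory=dict)
    spec_mode: str = "literature"

    def to_json(self) -> str:
        def clean(x):
            return None if (isinstance(x, float) and np.isnan(x)) else x
        return json.dumps({
            "class_order": [CLASS_NAMES[c] for c in CLASS_ORDER],
            "confusion_matrix": self.cm.counts.tolist(),
            "sensitivity": [clean(float(v)) for v in self.sensitivity],
            "specificity": [clean(float(v)) for v in self.specificity],
            "spec_mode": self.spec_mode,
            "accuracy": self.accuracy,
            "auc": {CLASS_NAMES[c]: clean(v) for c, v in self.auc.items()},
            "macro_auc": clean(self.macro_auc),
            "roc": {CLASS_NAMES[c]: np.asarray(v).tolist()
                    for c, v in self.roc.items()},
            "prc": {CLASS_NAMES[c]: np.asarray(v).tolist()
                    for c, v in self.prc.items()},
        }, indent=2)


def evaluate(y_true, y_pred, proba: np.ndarray | None = None,
             spec_mode: str = "literature") -> EvaluationReport:
    """Full report: confusion matrix, per-class rates, and (with
    probabilities) ROC/AUC and PRC per class plus the macro AUC."""
    cm = confusion(y_true, y_pred)
    sen, spe, acc = three_class_metrics(cm, spec_mode=spec_mode)
    report = EvaluationReport(cm=cm, sensitivity=sen, specificity=spe,
                              accuracy=acc, spec_mode=spec_mode)
    if proba is not None:
        aucs = []
        for c in CLASS_ORDER:
            try:
                pts, auc = roc_auc_ovr(y_true, proba, c)
            except ValueError:
                report.auc[c] = float("nan")
                continue
            report.roc[c] = pts
            report.auc[c] = auc
            report.prc[c] = precision_recall_ovr(y_true, proba, c)
            aucs.append(auc)
        if aucs:
            report.macro_auc = float(np.mean(aucs))
    return report
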