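"""Quality measures: classification suite, regression measures, ROC curve
and tree-ensemble feature importance.

ACTIVE is the positive class throughout. The classification report covers
accuracy, precision, recall/sensitivity, specificity, F1, ROC AUC, average
precision and the Matthews correlation coefficient, all derived from the
confusion counts (degenerate MCC denominators yield 0). Regression reports
the mean squared error in log units and the fraction of compounds
predicted within 1.0 log unit (boundary inclusive).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import average_precision_score, roc_curve

from .errors import CapabilityError, ValidationError
from .modeling import TREE_FAMILIES, TrainedModel
from .targets import ACTIVE, INACTIVE


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall_sensitivity: float
    specificity: float
    f1: float
    roc_auc: float
    average_precision: float
    matthews: float

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "Accuracy": self.accuracy,
            "Precision": self.precision,
            "Recall/Sensitivity": self.recall_sensitivity,
            "Specificity": self.specificity,
            "F1-score": self.f1,
            "ROCAUC": self.roc_auc,
            "Average precision": self.average_precision,
            "Matthew coefficient": self.matthews,
        }


@dataclass
class RegressionReport:
    mse: float
    fraction_within_1log: float
    pairs: List[Tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "MSE": self.mse,
            "Fraction within 1 log unit": self.fraction_within_1log,
        }


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class FeatureImportanceReport:
    importances: List[Tuple[str, float]]  # one per feature, sorted descending
    default_top_k: int = 40

    def top(self, k: Optional[int] = None) -> List[Tuple[str, float]]:
        return self.importances[: (self.default_top_k if k is None else k)]


def _as_binary(labels: Sequence) -> np.ndarray:
    out = []
    for lab in labels:
        if lab in (ACTIVE, 1, True):
            out.append(1)
        elif lab in (INACTIVE, 0, False):
            out.append(0)
        else:
            raise ValidationError(f"unknown class label {lab!r}")
    return np.array(out, dtype=int)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def auc_mann_whitney(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC as the probability a random positive outscores a random
    negative, ties credited 1/2 — equals the trapezoidal curve area."""
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("AUC requires both classes present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def roc_and_ap(true_labels: Sequence, scores: Sequence[float]) -> Tuple[ROCCurve, float]:
    """ROC curve with its AUC, plus the average precision.

    The curve starts at (0,0) and ends at (1,1); the AUC equals the
    pairwise Mann–Whitney statistic. Average precision is the step-wise
    integral of the precision–recall curve.
    """
    y = _as_binary(true_labels)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValidationError("labels and scores must have equal length")
    auc = auc_mann_whitney(y, s)
    fpr, tpr, _ = roc_curve(y, s)
    ap = float(average_precision_score(y, s))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc), ap


def classification_metrics(
    true_labels: Sequence,
    predicted_labels: Sequence,
    scores: Optional[Sequence[float]] = None,
) -> ClassificationReport:
    """The full eight-measure classification suite, ACTIVE positive.

    ``scores`` (ACTIVE-class probabilities or monotone scores) feed ROC
    AUC and average precision; without them those two fields are NaN.
    """
    y = _as_binary(true_labels)
    p = _as_binary(predicted_labels)
    if len(y) != len(p):
        raise ValidationError("label vectors must have equal length")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    n = tp + fp + tn + fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    if scores is not None:
        curve, ap = roc_and_ap(true_labels, scores)
        auc = curve.auc
    else:
        auc, ap = float("nan"), float("nan")
    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_safe_div(tp + tn, n),
        precision=precision,
        recall_sensitivity=recall,
        specificity=specificity,
        f1=f1,
        roc_auc=auc,
        average_precision=ap,
        matthews=mcc,
    )


def regression_metrics(true_plog: Sequence[float],
                       predicted_plog: Sequence[float]) -> RegressionReport:
    """MSE in log units and the within-1.0-log-unit fraction (inclusive)."""
    t = np.asarray(true_plog, dtype=float)
    p = np.asarray(predicted_plog, dtype=float)
    if len(t) != len(p):
        raise ValidationError("truth and prediction must have equal length")
    if len(t) == 0:
        raise ValidationError("regression metrics need at least one pair")
    err = p - t
    return RegressionReport(
        mse=float(np.mean(err**2)),
        fraction_within_1log=float(np.mean(np.abs(err) <= 1.0)),
        pairs=list(zip(t.tolist(), p.tolist())),
    )


def feature_importance(model: TrainedModel, feature_names: Sequence[str],
                       top_k: int = 40) -> FeatureImportanceReport:
    """Native (gain-based) importances of a tree-ensemble model,
    normalized to sum to 1, sorted descending; top_k defaults to 40."""
    if model.family not in TREE_FAMILIES:
        raise CapabilityError(
            f"feature importance is available for tree-based families "
            f"{TREE_FAMILIES}, not {model.family!r}"
        )
    est = model.estimator
    if hasattr(est, "feature_importances_"):
        weights = np.asarray(est.feature_importances_, dtype=float)
    else:  # bagging ensembles: average member importances
        weights = np.mean(
            [m.feature_importances_ for m in est.estimators_], axis=0
        )
    if len(weights) != len(feature_names):
        raise ValidationError("importance/feature-name length mismatch")
    total = weights.sum()
    if total > 0:
        weights = weights / total
    order = np.argsort(-weights, kind="stable")
    pairs = [(feature_names[i], float(weights[i])) for i in order]
    return FeatureImportanceReport(importances=pairs, default_top_k=top_k)


# ---------------------------------------------------------------------------
# Plot helpers (file outputs for the CLI; Agg backend, no display needed).


def plot_regression_scatter(report: RegressionReport, path) -> None:
    """Experimental vs predicted pIC50 with the ±1 log unit band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.array([a for a, _ in report.pairs])
    p = np.array([b for _, b in report.pairs])
    lo, hi = min(t.min(), p.min()) - 0.5, max(t.max(), p.max()) + 0.5
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([lo, hi], [lo, hi], "k-", lw=1)
    ax.fill_between([lo, hi], [lo - 1, hi - 1], [lo + 1, hi + 1],
                    alpha=0.15, color="gray", label="±1 log unit")
    ax.scatter(t, p, s=12, alpha=0.7)
    ax.set_xlabel("experimental pIC50/pEC50")
    ax.set_ylabel("predicted pIC50/pEC50")
    ax.set_title(f"MSE={report.mse:.2f}, within 1 log: "
                 f"{100 * report.fraction_within_1log:.0f}%")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(curve: ROCCurve, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(curve.fpr, curve.tpr, lw=1.5, label=f"AUC = {curve.auc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_importance(report: FeatureImportanceReport, path, top_k: int = 40) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = report.top(top_k)
    names = [n for n, _ in pairs][::-1]
    vals = [v for _, v in pairs][::-1]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.18 * len(pairs))))
    ax.barh(names, vals)
    ax.set_xlabel("normalized importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
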