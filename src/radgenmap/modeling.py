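"""Radiogenomics classification model and its evaluation metrics.

A random forest (default 201 trees) distinguishes the two tumour
classes from the selected radiomic + genomic features. Evaluation uses
cross-validation with out-of-fold predictions pooled into a single
confusion matrix and ROC; the metric suite is accuracy, sensitivity,
specificity, AUC, Matthews correlation coefficient and F1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import math

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "ModelReport",
    "confusion_metrics",
    "roc_auc",
    "evaluate_rf",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, F1 and MCC from counts.

    Rates are fractions in [0, 1]; MCC uses the 0 convention when any
    marginal is zero. Undefined rates (empty class) are reported as 0.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    total = cm.total
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
        "mcc": mcc,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney formulation.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg)
    over all positive/negative pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


@dataclass(frozen=True)
class ModelReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    mcc: float
    f1: float
    n_estimators: int
    cv_scheme: str
    seed: int
    confusion: ConfusionMatrix

    def as_percent(self) -> dict[str, float]:
        """Headline rates as percentages rounded to 2 decimals."""
        return {
            "accuracy": round(100 * self.accuracy, 2),
            "sensitivity": round(100 * self.sensitivity, 2),
            "specificity": round(100 * self.specificity, 2),
            "auc": round(100 * self.auc, 2),
        }


def evaluate_rf(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_estimators: int = 201,
    cv: str = "loo",
    n_splits: int = 5,
    seed: int = 0,
) -> ModelReport:
    """Cross-validated random-forest evaluation.

    Out-of-fold class-1 probabilities are pooled into one ROC and one
    confusion matrix (threshold 0.5). ``cv`` is ``"loo"`` (leave one
    out, the default for small cohorts) or ``"stratified-kfold"``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels must contain both classes")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 patients per class")
    if cv == "loo":
        splitter = LeaveOneOut()
    elif cv == "stratified-kfold":
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    else:
        raise ValueError(f"unknown cv scheme: {cv!r}")

    proba = np.empty(len(y))
    for train, test in splitter.split(X, y):
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        clf.fit(X[train], y[train])
        proba[test] = clf.predict_proba(X[test])[:, list(clf.classes_).index(1)]

    pred = (proba >= 0.5).astype(int)
    cm = ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )
    metrics = confusion_metrics(cm)
    return ModelReport(
        accuracy=metrics["accuracy"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        auc=roc_auc(proba, y),
        mcc=metrics["mcc"],
        f1=metrics["f1"],
        n_estimators=n_estimators,
        cv_scheme=cv,
        seed=seed,
        confusion=cm,
    )
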