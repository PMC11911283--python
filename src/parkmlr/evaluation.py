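"""Validation harness: ROC analysis, operating-point metrics, confusion matrices.

Each disease class is evaluated one-vs-rest on its predicted probability.
The operating point on each ROC curve follows the classical cost-slope
construction: a line of slope

    S = (Cost(P|N) - Cost(N|N)) / (Cost(N|P) - Cost(P|P)) * N / P

(equal unit misclassification costs by default, so S = N/P) is swept down
from the top-left corner and the first ROC vertex it touches — the vertex
maximizing TPR - S*FPR — is chosen, ties broken toward lower FPR.

Subjects are classified either by the plain argmax over the four
probabilities, or with a reject option: the best disease class only if
its probability exceeds a threshold (90% or 99%), otherwise undetermined
(UD). Validation cohorts contain no true UD subjects, so confusion
matrices are 3 x 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .image_io import BrainVolume
from .mlr import CLASS_ORDER

__all__ = [
    "ROCResult",
    "ConfusionMatrix",
    "EvaluationReport",
    "roc_curve",
    "optimal_operating_point",
    "metrics_at_point",
    "classify",
    "confusion",
    "evaluate",
]

DISEASES = CLASS_ORDER[:3]
DEFAULT_RULES: tuple[float | None, ...] = (None, 0.90, 0.99)


@dataclass
class ROCResult:
    """One-vs-rest ROC curve for a single class, with its operating point."""

    class_label: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int
    operating_point: tuple[float, float, float]  # (fpr*, tpr*, threshold*)


@dataclass
class ConfusionMatrix:
    """3 x 4 true-class by predicted-class table under one decision rule."""

    threshold_rule: float | None
    counts: pd.DataFrame            # index PD/MSA/PSP, columns PD/MSA/PSP/UD
    row_percentages: pd.DataFrame   # each row sums to 100


@dataclass
class EvaluationReport:
    """Everything the validation run produces."""

    probabilities: pd.DataFrame          # subjects x (PD, MSA, PSP, UD)
    true_labels: list[str]
    roc: dict[str, ROCResult]
    metrics: pd.DataFrame                # per class: sensitivity/specificity/ppv/npv (%)
    confusions: dict[str, ConfusionMatrix]

    def summary(self) -> dict:
        return {
            "auc": {c: self.roc[c].auc for c in self.roc},
            "operating_points": {
                c: {
                    "fpr": self.roc[c].operating_point[0],
                    "tpr": self.roc[c].operating_point[1],
                }
                for c in self.roc
            },
            "metrics": self.metrics.to_dict(orient="index"),
        }


def roc_curve(
    scores: np.ndarray, labels: list[str], positive: str, costs: tuple[float, float, float, float] = (1.0, 0.0, 1.0, 0.0)
) -> ROCResult:
    """One-vs-rest ROC of ``scores`` for class ``positive``.

    Negatives are all subjects of any other class. AUC is the trapezoidal
    area (equivalently the pair-concordance probability). Raises when only
    one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.array([lab == positive for lab in labels], dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"ROC for {positive!r} needs at least one positive and one negative")
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    result = ROCResult(
        class_label=positive,
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        n_positive=n_pos,
        n_negative=n_neg,
        operating_point=(0.0, 0.0, np.inf),
    )
    result.operating_point = optimal_operating_point(result, costs)
    return result


def optimal_operating_point(
    roc: ROCResult, costs: tuple[float, float, float, float] = (1.0, 0.0, 1.0, 0.0)
) -> tuple[float, float, float]:
    """ROC vertex first touched by a line of slope S sweeping from top-left.

    ``costs`` is (Cost(P|N), Cost(N|N), Cost(N|P), Cost(P|P)); with the
    default equal unit costs S = N/P. The vertex maximizes TPR - S*FPR;
    ties are broken by lower FPR. Returns (fpr*, tpr*, threshold*).
    """
    c_pn, c_nn, c_np, c_pp = costs
    slope = (c_pn - c_nn) / (c_np - c_pp) * roc.n_negative / roc.n_positive
    utility = roc.tpr - slope * roc.fpr
    best = max(range(len(utility)), key=lambda i: (utility[i], -roc.fpr[i]))
    return (float(roc.fpr[best]), float(roc.tpr[best]), float(roc.thresholds[best]))


def metrics_at_point(roc: ROCResult, point: tuple[float, float, float] | None = None) -> dict[str, float]:
    """Sensitivity / specificity / PPV / NPV (in %) at an ROC vertex.

    Counts are reconstructed from the vertex rates and the class sizes;
    a zero denominator yields NaN ("not applicable").
    """
    fpr, tpr = (point or roc.operating_point)[:2]
    tp = tpr * roc.n_positive
    fp = fpr * roc.n_negative
    fn = (1.0 - tpr) * roc.n_positive
    tn = (1.0 - fpr) * roc.n_negative
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = 100.0 * tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return {
        "sensitivity": 100.0 * tpr,
        "specificity": 100.0 * (1.0 - fpr),
        "ppv": ppv,
        "npv": npv,
    }


def classify(probabilities: pd.DataFrame, rule: float | None = None) -> list[str]:
    """Assign each subject a predicted class under a decision rule.

    ``rule=None``: plain argmax over the four probabilities (UD can win).
    ``rule=t``: the highest-probability *disease* class if its probability
    exceeds ``t``, otherwise UD.
    """
    probs = probabilities[list(CLASS_ORDER)].to_numpy()
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("probabilities must sum to 1 per subject")
    if rule is None:
        return [CLASS_ORDER[i] for i in probs.argmax(axis=1)]
    predictions = []
    for row in probs:
        j = int(row[:3].argmax())
        predictions.append(CLASS_ORDER[j] if row[j] > rule else "UD")
    return predictions


def confusion(true_labels: list[str], predicted: list[str], rule: float | None = None) -> ConfusionMatrix:
    """True-class (PD/MSA/PSP) by predicted-class (PD/MSA/PSP/UD) table."""
    bad = set(true_labels) - set(DISEASES)
    if bad:
        raise ValueError(f"true labels must be diseases, got {sorted(bad)}")
    bad = set(predicted) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"unknown predicted labels: {sorted(bad)}")
    counts = pd.DataFrame(0, index=list(DISEASES), columns=list(CLASS_ORDER), dtype=int)
    for t, p in zip(true_labels, predicted):
        counts.loc[t, p] += 1
    row_totals = counts.sum(axis=1)
    pct = counts.div(row_totals.replace(0, np.nan), axis=0) * 100.0
    return ConfusionMatrix(threshold_rule=rule, counts=counts, row_percentages=pct)


def evaluate(
    model,
    volumes: list[BrainVolume],
    rules: tuple[float | None, ...] = DEFAULT_RULES,
) -> EvaluationReport:
    """Run the frozen classifier on a labeled validation cohort.

    Produces per-class ROC curves (score = predicted class probability),
    Table-style operating-point metrics, and one confusion matrix per
    decision rule.
    """
    probabilities = model.predict_volumes(volumes)
    true_labels = [v.label for v in volumes]

    roc = {
        c: roc_curve(probabilities[c].to_numpy(), true_labels, positive=c)
        for c in DISEASES
    }
    metrics = pd.DataFrame({c: metrics_at_point(roc[c]) for c in DISEASES}).T
    confusions = {}
    for rule in rules:
        key = "none" if rule is None else f"{rule:g}"
        confusions[key] = confusion(true_labels, classify(probabilities, rule), rule)
    return EvaluationReport(
        probabilities=probabilities,
        true_labels=true_labels,
        roc=roc,
        metrics=metrics,
        confusions=confusions,
    )
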