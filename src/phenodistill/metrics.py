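"""Evaluation metrics for ordinal multi-class stage classification.

The staging problem is an 8-class classification task whose classes are
ordered (emergence < tillering < ... < maturity), so the report combines
nominal agreement measures (overall accuracy, per-class precision/recall/F1,
Cohen's kappa) with an ordinal error (mean absolute stage difference, which
penalises distant-stage confusions more than adjacent ones).

Conventions: stages are 1-based integers in ``1..n_stages``; confusion-matrix
rows are true stages and columns predicted stages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

STAGE_NAMES = (
    "emergence",
    "tillering",
    "jointing",
    "booting",
    "heading",
    "anthesis",
    "filling",
    "maturity",
)

N_STAGES = 8


def _validate_labels(y_true, y_pred, n_stages: int) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=np.int64)
    yp = np.asarray(y_pred, dtype=np.int64)
    if yt.shape != yp.shape:
        raise ValueError(f"label lengths differ: {yt.shape} vs {yp.shape}")
    if yt.size == 0:
        raise ValueError("empty label vectors")
    for name, v in (("y_true", yt), ("y_pred", yp)):
        if v.min() < 1 or v.max() > n_stages:
            bad = v[(v < 1) | (v > n_stages)][0]
            raise ValueError(f"{name} contains stage {bad} outside 1..{n_stages}")
    return yt, yp


def confusion(y_true, y_pred, n_stages: int = N_STAGES) -> np.ndarray:
    """Confusion matrix ``counts[i-1, j-1] = #{t : y_t = i, yhat_t = j}``."""
    yt, yp = _validate_labels(y_true, y_pred, n_stages)
    idx = (yt - 1) * n_stages + (yp - 1)
    return np.bincount(idx, minlength=n_stages * n_stages).reshape(n_stages, n_stages)


def overall_accuracy(cm: np.ndarray) -> float:
    """Fraction of correctly classified samples: trace over total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(cm) / total)


def precision_recall_f1(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class one-vs-rest precision, recall and F1.

    A zero denominator (class never predicted, or never true) yields 0 for the
    affected quantity, with a warning; classes with no support at all are
    still reported here and excluded from the macro average downstream.
    """
    cm = np.asarray(cm, dtype=np.float64)
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if np.any((tp + fp) == 0) or np.any((tp + fn) == 0):
        warnings.warn("zero-denominator class in precision/recall; reported as 0",
                      stacklevel=2)
    return precision, recall, f1


def f1_scores(cm: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class F1 plus the macro average over classes with support.

    'Support' means the class occurs in the truth or in the predictions; a
    stage entirely absent from the evaluated sample is not averaged in.
    """
    cm = np.asarray(cm)
    _, _, f1 = precision_recall_f1(cm)
    present = (cm.sum(axis=1) + cm.sum(axis=0)) > 0
    macro = float(f1[present].mean()) if present.any() else 0.0
    return f1, macro


def micro_f1(cm: np.ndarray) -> float:
    """Micro-averaged F1 (== accuracy for single-label multi-class)."""
    return overall_accuracy(cm)


def kappa(cm: np.ndarray) -> float:
    """Multi-class Cohen's kappa: (p0 - pe) / (1 - pe).

    p0 is the observed agreement (overall accuracy) and pe the chance
    agreement from the marginal products, pe = sum_k row_k * col_k / n^2.
    For two classes this reduces exactly to the familiar binary
    TP/TN/FP/FN expression.
    """
    cm = np.asarray(cm, dtype=np.float64)
    n = cm.sum()
    if n <= 0:
        raise ValueError("confusion matrix is empty")
    p0 = np.trace(cm) / n
    pe = float(cm.sum(axis=1) @ cm.sum(axis=0)) / (n * n)
    if pe >= 1.0:
        raise ValueError("chance agreement pe == 1; kappa undefined")
    return float((p0 - pe) / (1.0 - pe))


def ordinal_mae(y_true, y_pred, n_stages: int = N_STAGES) -> float:
    """Mean absolute difference of stage indices, MAE = mean |yhat - y|."""
    yt, yp = _validate_labels(y_true, y_pred, n_stages)
    return float(np.mean(np.abs(yp - yt)))


@dataclass
class MetricReport:
    """Bundled evaluation: confusion matrix plus the headline metrics."""

    matrix: np.ndarray
    oa: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    micro_f1: float
    kappa: float
    mae: float
    n: int
    excluded_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "oa": self.oa,
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "kappa": self.kappa,
            "mae": self.mae,
            "n": self.n,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "excluded_classes": self.excluded_classes,
            "confusion": self.matrix.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def confusion_to_csv(self, path, n_stages: int | None = None) -> None:
        """Confusion matrix as CSV with stage-name headers (true in rows)."""
        import pandas as pd

        names = STAGE_NAMES[: self.matrix.shape[0]]
        pd.DataFrame(self.matrix, index=names, columns=names).to_csv(path)


def evaluate(y_true, y_pred, n_stages: int = N_STAGES) -> MetricReport:
    """Compute the full metric bundle for one set of predictions."""
    cm = confusion(y_true, y_pred, n_stages)
    precision, recall, f1 = precision_recall_f1(cm)
    _, macro = f1_scores(cm)
    present = (cm.sum(axis=1) + cm.sum(axis=0)) > 0
    excluded = [int(i + 1) for i in np.nonzero(~present)[0]]
    return MetricReport(
        matrix=cm,
        oa=overall_accuracy(cm),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=macro,
        micro_f1=micro_f1(cm),
        kappa=kappa(cm),
        mae=ordinal_mae(y_true, y_pred, n_stages),
        n=int(cm.sum()),
        excluded_classes=excluded,
    )
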