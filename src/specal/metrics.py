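"""Confusion-matrix evaluation: overall accuracy, Cohen's kappa, macro scores.

Conventions: confusion rows are true classes, columns predicted classes.
Macro-F1 is the unweighted mean of per-class F1 values (not the F1 of the
macro precision/recall pair).  Classes absent from both truth and
prediction are dropped from the macro averages with a warning; a class
never predicted scores precision 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "confusion_matrix",
    "overall_accuracy",
    "cohens_kappa",
    "macro_scores",
    "evaluate",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    confusion: np.ndarray
    oa: float
    kappa: float
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"OA": self.oa, "Kappa": self.kappa,
              "Macro": self.macro_precision, "Recall": self.macro_recall,
              "F1": self.macro_f1}])

    def __str__(self) -> str:
        return (f"OA={self.oa:.4f} kappa={self.kappa:.4f} "
                f"macroP={self.macro_precision:.4f} "
                f"macroR={self.macro_recall:.4f} macroF1={self.macro_f1:.4f}")


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """Count matrix with entry (t, p) = #{i : y_true_i = t, y_pred_i = p}."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return counts


def overall_accuracy(counts: np.ndarray) -> float:
    """Trace over total."""
    counts = np.asarray(counts)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(counts) / total)


def cohens_kappa(counts: np.ndarray) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    ``p_e`` is the chance agreement from the marginal products.  In the
    single-class degenerate case (``p_e = 1``) kappa is defined as 1 when
    agreement is perfect and 0 otherwise.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) / total) @ (counts.sum(axis=0) / total))
    if np.isclose(p_e, 1.0):
        return 1.0 if np.isclose(p_o, 1.0) else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def macro_scores(counts: np.ndarray) -> tuple[float, float, float]:
    """Unweighted class means of precision, recall and F1.

    Per-class F1 is the harmonic mean of that class's precision and recall;
    empty denominators contribute 0.  Classes with no true and no predicted
    samples are excluded from the averages (logged).
    """
    counts = np.asarray(counts, dtype=float)
    true_per_class = counts.sum(axis=1)
    pred_per_class = counts.sum(axis=0)
    present = (true_per_class > 0) | (pred_per_class > 0)
    if not present.all():
        logger.warning("dropping %d empty class(es) from macro averages",
                       int((~present).sum()))
    if not present.any():
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_per_class > 0, diag / pred_per_class, 0.0)
        recall = np.where(true_per_class > 0, diag / true_per_class, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return (float(precision[present].mean()),
            float(recall[present].mean()),
            float(f1[present].mean()))


def evaluate(y_true, y_pred, n_classes: int | None = None) -> MetricsReport:
    """All metrics from raw label vectors."""
    counts = confusion_matrix(y_true, y_pred, n_classes)
    precision, recall, f1 = macro_scores(counts)
    return MetricsReport(
        confusion=counts,
        oa=overall_accuracy(counts),
        kappa=cohens_kappa(counts),
        macro_precision=precision,
        macro_recall=recall,
        macro_f1=f1,
    )
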