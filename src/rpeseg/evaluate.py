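"""Evaluation battery: confusion-matrix metrics, AUROC, Dice summaries,
and volume agreement.

Per-patient slice classification is scored with accuracy, sensitivity,
specificity, precision, and AUROC; segmentation with the Dice coefficient
per view; and volume recovery with Pearson's r, mean absolute error (mm³),
and mean relative error (%).  Metrics whose denominator is zero are marked
undefined (NaN) and excluded from cohort means rather than imputed.

Note on the accuracy formula: the standard
``(TP+TN)/(TP+FN+FP+TN)`` is used.  A variant omitting FP from the
denominator circulates in print; it is available as
``accuracy_formula="as_printed"`` strictly for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionCounts", "PatientMetrics", "VolumeAgreement",
           "confusion_counts", "classification_metrics", "auroc",
           "volume_agreement", "summarize_classification",
           "summarize_segmentation"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class PatientMetrics:
    """Per-patient classification metrics; NaN marks an undefined value."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    auroc: float = float("nan")


@dataclass(frozen=True)
class VolumeAgreement:
    pearson_r: float
    mae_mm3: float
    mre_percent: float


def confusion_counts(pred_labels, true_labels) -> ConfusionCounts:
    p = np.asarray(pred_labels)
    t = np.asarray(true_labels)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("prediction and truth label lists must align")
    if not (np.isin(p, (0, 1)).all() and np.isin(t, (0, 1)).all()):
        raise ValueError("labels must be binary")
    return ConfusionCounts(
        tp=int(((p == 1) & (t == 1)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(counts: ConfusionCounts,
                           accuracy_formula: str = "standard") -> PatientMetrics:
    """Accuracy, sensitivity, specificity, precision from counts.

    Zero-denominator metrics come back NaN (undefined) so cohort summaries
    can exclude them.
    """
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    if accuracy_formula == "standard":
        acc = _ratio(tp + tn, tp + fn + fp + tn)
    elif accuracy_formula == "as_printed":
        acc = _ratio(tp + tn, tp + fn + tn)
    else:
        raise ValueError(f"unknown accuracy_formula {accuracy_formula!r}")
    return PatientMetrics(
        accuracy=acc,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp))


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann–Whitney formulation, ties count ½).

    Returns NaN when only one class is present.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("scores and labels must align")
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, s))


def volume_agreement(real_mm3, predicted_mm3) -> VolumeAgreement:
    """Pearson r, MAE (mm³), and MRE (%) between true and predicted volumes.

    Every real volume must be positive (only lesion-positive patients are
    evaluated), otherwise the relative error is undefined.
    """
    real = np.asarray(real_mm3, dtype=np.float64)
    pred = np.asarray(predicted_mm3, dtype=np.float64)
    if real.shape != pred.shape or real.ndim != 1 or len(real) == 0:
        raise ValueError("paired nonempty volume lists required")
    if (real <= 0).any():
        raise ValueError("real volumes must be positive for relative error")
    if len(real) < 2 or np.std(real) == 0 or np.std(pred) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(real, pred)[0, 1])
    err = np.abs(pred - real)
    return VolumeAgreement(pearson_r=r, mae_mm3=float(err.mean()),
                          mre_percent=float((err / real).mean() * 100.0))


def summarize_classification(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD per view of the five classification metrics.

    ``per_patient`` needs columns: patient, view, accuracy, sensitivity,
    specificity, precision, auroc.  Undefined (NaN) values are excluded
    metric-wise; single observations get SD 0.
    """
    metrics = ["accuracy", "sensitivity", "specificity", "precision", "auroc"]
    rows = []
    for view, grp in per_patient.groupby("view", sort=False):
        row = {"view": view}
        for m in metrics:
            vals = grp[m].dropna().to_numpy()
            row[f"{m}_mean"] = vals.mean() if len(vals) else float("nan")
            row[f"{m}_sd"] = vals.std(ddof=0) if len(vals) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_segmentation(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD, min, median, max and zero-Dice counts per view.

    ``per_patient`` needs columns: patient, view, dice.
    """
    rows = []
    for view, grp in per_patient.groupby("view", sort=False):
        d = grp["dice"].dropna().to_numpy()
        rows.append({
            "view": view,
            "dice_mean": d.mean() if len(d) else float("nan"),
            "dice_sd": d.std(ddof=0) if len(d) else float("nan"),
            "dice_min": d.min() if len(d) else float("nan"),
            "dice_median": float(np.median(d)) if len(d) else float("nan"),
            "dice_max": d.max() if len(d) else float("nan"),
            "zero_dice_patients": int((d == 0).sum()),
        })
    return pd.DataFrame(rows)
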