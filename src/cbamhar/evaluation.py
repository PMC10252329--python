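"""Per-class F1, macro F1, confusion matrices, fold summaries, tests.

Macro F1 here is the unweighted arithmetic mean of per-class F1 scores
over the *fixed* class inventory: a class absent from both truth and
prediction still contributes an F1 of 0 (with a warning), which is the
conservative reading for imbalanced activity sets.  Confusion matrices
are reported both as raw counts and row-normalised (rows with zero
support stay all-zero).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "EvaluationReport",
    "confusion_matrix",
    "per_class_f1",
    "macro_f1",
    "evaluate",
    "fold_summary",
    "one_sample_test",
    "plot_confusion",
]


def _check_labels(y_true, y_pred, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    if y_true.size == 0:
        raise ValueError("empty label arrays")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    return y_true, y_pred


def confusion_matrix(y_true, y_pred, n_classes: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Counts matrix and its row-normalised form.

    ``counts[i, j]`` is the number of samples with true class ``i``
    predicted as ``j``.
    """
    y_true, y_pred = _check_labels(y_true, y_pred, n_classes)
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    support = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalised = np.where(support > 0, counts / support, 0.0)
    return counts, normalised


def per_class_f1(counts: np.ndarray) -> np.ndarray:
    """Per-class F1 from a counts confusion matrix (0 where P + R = 0)."""
    counts = np.asarray(counts, dtype=float)
    tp = np.diag(counts)
    pred_tot = counts.sum(axis=0)
    true_tot = counts.sum(axis=1)
    denom = pred_tot + true_tot  # 2TP + FP + FN
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * tp / denom, 0.0)
    return f1


def macro_f1(y_true, y_pred, n_classes: int) -> float:
    """Unweighted mean of per-class F1 over all *n_classes* classes."""
    counts, _ = confusion_matrix(y_true, y_pred, n_classes)
    absent = (counts.sum(axis=0) + counts.sum(axis=1)) == 0
    if absent.any():
        warnings.warn(
            f"{int(absent.sum())} class(es) absent from truth and prediction "
            "contribute F1 = 0 to the macro mean",
            stacklevel=2,
        )
    return float(per_class_f1(counts).mean())


@dataclass
class EvaluationReport:
    """Everything reported for one evaluation run."""

    class_names: list[str]
    per_class_f1: np.ndarray
    macro_f1: float
    confusion_counts: np.ndarray
    confusion_normalised: np.ndarray
    support: np.ndarray
    fold_values: Optional[list[float]] = None
    fold_mean: Optional[float] = None
    fold_sstd: Optional[float] = None

    def to_dict(self) -> dict:
        d = dict(
            class_names=self.class_names,
            per_class_f1=[float(v) for v in self.per_class_f1],
            macro_f1=self.macro_f1,
            confusion_counts=self.confusion_counts.tolist(),
            confusion_normalised=self.confusion_normalised.tolist(),
            support=self.support.tolist(),
        )
        if self.fold_values is not None:
            d.update(fold_values=self.fold_values, fold_mean=self.fold_mean,
                     fold_sstd=self.fold_sstd)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate(y_true, y_pred, class_names: Sequence[str]) -> EvaluationReport:
    """Build a full report from predicted and true labels."""
    n = len(class_names)
    counts, normalised = confusion_matrix(y_true, y_pred, n)
    f1 = per_class_f1(counts)
    return EvaluationReport(
        class_names=list(class_names),
        per_class_f1=f1,
        macro_f1=float(f1.mean()),
        confusion_counts=counts,
        confusion_normalised=normalised,
        support=counts.sum(axis=1),
    )


def fold_summary(values: Sequence[float]) -> tuple[float, Optional[float]]:
    """Mean and sample standard deviation (n-1 denominator) across folds.

    With a single fold the sstd is undefined and reported as ``None``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no fold values")
    mean = float(values.mean())
    sstd = float(values.std(ddof=1)) if values.size >= 2 else None
    return mean, sstd


def one_sample_test(scores: Sequence[float], baseline: float,
                    method: str = "student_t",
                    include_baseline: bool = False) -> tuple[float, float]:
    """Two-sided one-sample test of *scores* against a baseline value.

    ``method="student_t"`` runs a one-sample t-test of the sample mean
    against *baseline*; ``method="wilcoxon"`` runs a signed-rank test of
    the differences against zero.  With ``include_baseline=True`` the
    baseline score is appended to the sample as an extra observation
    (the alternative reading of "1 baseline + 115 attention results").
    """
    scores = np.asarray(scores, dtype=float)
    if include_baseline:
        scores = np.append(scores, baseline)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    if method == "student_t":
        res = stats.ttest_1samp(scores, popmean=baseline, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if method == "wilcoxon":
        diffs = scores - baseline
        if np.all(diffs == 0):
            raise ValueError("all differences are zero; signed-rank test undefined")
        res = stats.wilcoxon(diffs, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError("method must be 'student_t' or 'wilcoxon'")


def plot_confusion(report: EvaluationReport, path, title: str = "") -> None:
    """Render the row-normalised confusion matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(report.class_names)
    fig, ax = plt.subplots(figsize=(max(4, n * 0.5),) * 2)
    im = ax.imshow(report.confusion_normalised, vmin=0, vmax=1, cmap="Blues")
    ax.set_xticks(range(n), report.class_names, rotation=90, fontsize=7)
    ax.set_yticks(range(n), report.class_names, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
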