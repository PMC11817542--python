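"""Performance measures, per-class reports, ROC/AUC and k-fold CV.

Metrics follow the standard confusion-matrix formulas:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Ratios with a zero denominator are reported as *absent* (``None``), never
silently as 0, so that fold averages are not corrupted. ROC AUC is the
Mann-Whitney concordance probability with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts for a declared positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    y_true: Sequence, y_pred: Sequence, positive
) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with ``positive`` as the positive class."""
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    if len(y_true) == 0:
        raise ValueError("cannot build a confusion matrix from empty sequences")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if p == positive:
            if t == positive:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    Undefined ratios (zero denominator) are ``None``.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.total
    prec = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    rec = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    f1 = f1_score(prec, rec)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def f1_score(precision: float | None, recall: float | None) -> float | None:
    """Harmonic mean of precision and recall; absent if either is, or both are 0."""
    if precision is None or recall is None:
        return None
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def roc_auc(scores: Sequence[float], y_true: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney, ties half-weighted)."""
    y = np.asarray(y_true)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_points(
    scores: Sequence[float], y_true: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve points (fpr, tpr, threshold) for plotting/export."""
    fpr, tpr, thr = roc_curve(np.asarray(y_true), np.asarray(scores, dtype=float))
    return fpr, tpr, thr


@dataclass
class MetricsReport:
    """Overall and per-class metrics plus the underlying confusion matrix."""

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    roc_auc: float | None
    confusion: ConfusionMatrix
    per_class: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
            "confusion": vars(self.confusion),
            "per_class": self.per_class,
        }


def per_class_report(
    y_true: Sequence, y_pred: Sequence, classes: Sequence | None = None
) -> dict[str, dict[str, float | None]]:
    """One-vs-rest confusion and metrics with each class as positive in turn."""
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred), key=str)
    report = {}
    for cls in classes:
        cm = confusion(y_true, y_pred, positive=cls)
        report[str(cls)] = metrics(cm)
    return report


def evaluate(
    y_true: Sequence,
    y_pred: Sequence,
    scores: Sequence[float] | None = None,
    positive=1,
) -> MetricsReport:
    """Full report: overall metrics, optional AUC, per-class table."""
    cm = confusion(y_true, y_pred, positive=positive)
    m = metrics(cm)
    auc = None
    if scores is not None and len(set(y_true)) == 2:
        auc = roc_auc(scores, [1 if t == positive else 0 for t in y_true])
    return MetricsReport(
        accuracy=m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        roc_auc=auc,
        confusion=cm,
        per_class=per_class_report(y_true, y_pred),
    )


def plot_roc(scores, y_true, path, label: str | None = None) -> None:
    """Write a ROC curve image (requires matplotlib, an optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr, tpr, _ = roc_points(scores, y_true)
    auc = roc_auc(scores, y_true)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(fpr, tpr, label=f"{label or 'model'} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_history(history, path) -> None:
    """Write loss/accuracy training curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
    epochs = range(1, len(history.train_loss) + 1)
    ax1.plot(epochs, history.train_loss, label="train")
    if history.val_loss:
        ax1.plot(epochs, history.val_loss, label="validation")
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("loss")
    ax1.legend()
    ax2.plot(epochs, history.train_accuracy, label="train")
    if history.val_accuracy:
        ax2.plot(epochs, history.val_accuracy, label="validation")
    ax2.set_xlabel("epoch")
    ax2.set_ylabel("accuracy")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class FoldResult:
    fold: int
    report: MetricsReport


def aggregate_reports(folds: Sequence[FoldResult]) -> dict[str, float | None]:
    """Unweighted arithmetic mean of per-fold metrics, skipping absent values."""
    out: dict[str, float | None] = {}
    for key in ("accuracy", "precision", "recall", "f1", "roc_auc"):
        vals = [getattr(f.report, key) for f in folds]
        vals = [v for v in vals if v is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return out


def kfold(
    X: Sequence,
    y: Sequence,
    model_recipe: Callable[[], object],
    k: int = 5,
    seed: int = 0,
    positive=1,
) -> tuple[list[FoldResult], dict[str, float | None]]:
    """Stratified k-fold cross-validation with per-fold retraining.

    ``model_recipe`` returns a fresh estimator exposing ``fit`` and
    ``predict`` (and optionally ``predict_proba``). Every document lands in
    exactly one test fold; the aggregate is the unweighted mean of per-fold
    metrics.
    """
    y_arr = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y_arr, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} documents, fewer than k={k}"
        )
    X_arr = np.asarray(X)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results: list[FoldResult] = []
    for i, (train_idx, test_idx) in enumerate(skf.split(X_arr, y_arr)):
        model = model_recipe()
        model.fit(X_arr[train_idx], y_arr[train_idx])
        y_pred = model.predict(X_arr[test_idx])
        scores = None
        if hasattr(model, "predict_proba"):
            proba = model.predict_proba(X_arr[test_idx])
            scores = proba[:, -1] if proba.ndim == 2 else np.asarray(proba).ravel()
        results.append(
            FoldResult(
                fold=i,
                report=evaluate(
                    y_arr[test_idx], y_pred, scores=scores, positive=positive
                ),
            )
        )
    return results, aggregate_reports(results)
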