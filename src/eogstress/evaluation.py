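"""Evaluation protocols and metrics.

Implements the confusion-matrix metrics (accuracy, precision, recall, F1,
specificity; macro-averaged across classes, one-vs-rest per class) and the
two validation protocols: stratified 10-fold cross-validation with an inner
validation split, and leave-one-subject-out (LOSO) cross-validation where
every fold holds out all windows of one subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES
from .modeling import DEFAULT_GRIDS, ModelSpec, grid_search, predict, train


@dataclass
class ConfusionMatrix:
    """Count table C[i][j] = windows of true class i predicted as class j."""

    classes: list[str]
    table: np.ndarray

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=np.int64)
        k = len(self.classes)
        if self.table.shape != (k, k):
            raise ValueError("table shape must match the class list")
        if (self.table < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.table.sum())

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for class index i."""
        tp = int(self.table[i, i])
        fp = int(self.table[:, i].sum() - tp)
        fn = int(self.table[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn


def confusion_from_predictions(
    y_true, y_pred, classes: list[str] | None = None
) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    index = {c: i for i, c in enumerate(classes)}
    table = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        table[index[t], index[p]] += 1
    return ConfusionMatrix(classes=list(classes), table=table)


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> dict:
    """Accuracy plus per-class and macro precision/recall/F1/specificity.

    Per-class values are one-vs-rest; overall values are macro averages.
    Cells with a zero denominator are reported as 0 and listed in
    ``zero_denominator_flags``.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(cm.classes):
        tp, fp, tn, fn = cm.one_vs_rest(i)
        per_class[cls] = {
            "accuracy": (tp + tn) / cm.total,
            "precision": _safe_div(tp, tp + fp, flags, f"precision[{cls}]"),
            "recall": _safe_div(tp, tp + fn, flags, f"recall[{cls}]"),
            "f1": _safe_div(2 * tp, 2 * tp + fp + fn, flags, f"f1[{cls}]"),
            "specificity": _safe_div(tn, tn + fp, flags, f"specificity[{cls}]"),
        }
    macro = {
        m: float(np.mean([per_class[c][m] for c in cm.classes]))
        for m in ("precision", "recall", "f1", "specificity")
    }
    return {
        "accuracy": float(np.trace(cm.table)) / cm.total,
        **macro,
        "per_class": per_class,
        "zero_denominator_flags": flags,
    }


@dataclass
class EvaluationReport:
    """Cross-validated performance of one classifier under one protocol."""

    protocol: str  # kfold10 | loso
    model_spec: ModelSpec
    fold_metrics: list[dict]
    mean_metrics: dict
    confusion: ConfusionMatrix  # pooled over folds
    predictions: pd.DataFrame  # columns: fold, subject_id, phase, y_true, y_pred
    per_task: dict[str, float] | None = None
    extra: dict = field(default_factory=dict)


def _mean_fold_metrics(fold_metrics: list[dict]) -> dict:
    keys = ("accuracy", "precision", "recall", "f1", "specificity")
    out = {k: float(np.mean([m[k] for m in fold_metrics])) for k in keys}
    classes = fold_metrics[0]["per_class"].keys()
    out["per_class"] = {
        c: {
            k: float(np.mean([m["per_class"][c][k] for m in fold_metrics]))
            for k in ("accuracy", "precision", "recall", "f1", "specificity")
        }
        for c in classes
    }
    return out


def _evaluate_folds(table: pd.DataFrame, spec: ModelSpec, folds, seed: int,
                    tune: bool, grids) -> tuple[list[dict], list[pd.DataFrame]]:
    label_col = spec.label_column
    fold_metrics = []
    pred_frames = []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        tr, te = table.iloc[train_idx], table.iloc[test_idx]
        params = dict(spec.hyperparameters)
        if tune:
            params = grid_search(
                spec.classifier,
                grids.get(spec.classifier) if grids else None,
                tr[FEATURE_NAMES],
                tr[label_col].to_numpy(),
                class_scheme=spec.class_scheme,
                seed=seed + fold_id,
            )
        fold_spec = ModelSpec(
            classifier=spec.classifier,
            class_scheme=spec.class_scheme,
            hyperparameters=params,
            random_seed=spec.random_seed,
        )
        model = train(fold_spec, tr, tr[label_col].to_numpy())
        y_pred = predict(model, te)
        y_true = te[label_col].to_numpy()
        cm = confusion_from_predictions(y_true, y_pred,
                                        classes=sorted(table[label_col].unique()))
        fold_metrics.append(metrics_from_confusion(cm))
        pred_frames.append(
            pd.DataFrame(
                {
                    "fold": fold_id,
                    "subject_id": te["subject_id"].to_numpy(),
                    "phase": te["phase"].to_numpy(),
                    "y_true": y_true,
                    "y_pred": y_pred,
                }
            )
        )
    return fold_metrics, pred_frames


def kfold10_evaluate(
    table: pd.DataFrame,
    spec: ModelSpec,
    seed: int = 0,
    n_folds: int = 10,
    tune: bool = False,
    grids: dict | None = None,
) -> EvaluationReport:
    """Stratified k-fold CV: every window tested exactly once.

    With ``tune=True`` a grid search with a 10% inner validation split is
    re-run on each fold's training rows.
    """
    label_col = spec.label_column
    y = table[label_col].to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < n_folds).any():
        small = counts[counts < n_folds].index.tolist()
        raise ValueError(f"classes with fewer than {n_folds} windows: {small}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    fold_metrics, pred_frames = _evaluate_folds(table, spec, folds, seed, tune,
                                                grids or DEFAULT_GRIDS)
    predictions = pd.concat(pred_frames, ignore_index=True)
    pooled = confusion_from_predictions(
        predictions["y_true"], predictions["y_pred"],
        classes=sorted(table[label_col].unique()),
    )
    report = EvaluationReport(
        protocol="kfold10",
        model_spec=spec,
        fold_metrics=fold_metrics,
        mean_metrics=_mean_fold_metrics(fold_metrics),
        confusion=pooled,
        predictions=predictions,
    )
    report.per_task = per_task_accuracy(predictions)
    return report


def loso_evaluate(
    table: pd.DataFrame,
    spec: ModelSpec,
    seed: int = 0,
    tune: bool = False,
    grids: dict | None = None,
) -> EvaluationReport:
    """Leave-one-subject-out CV: one fold per subject, no subject leakage.

    Every fold is audited: the training and test subject-id sets must be
    disjoint, otherwise the fold is rejected.
    """
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    folds = []
    for subj in subjects:
        test_mask = (table["subject_id"] == subj).to_numpy()
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        audit_loso_fold(table, train_idx, test_idx)
        folds.append((train_idx, test_idx))
    fold_metrics, pred_frames = _evaluate_folds(table, spec, folds, seed, tune,
                                                grids or DEFAULT_GRIDS)
    predictions = pd.concat(pred_frames, ignore_index=True)
    pooled = confusion_from_predictions(
        predictions["y_true"], predictions["y_pred"],
        classes=sorted(table[spec.label_column].unique()),
    )
    report = EvaluationReport(
        protocol="loso",
        model_spec=spec,
        fold_metrics=fold_metrics,
        mean_metrics=_mean_fold_metrics(fold_metrics),
        confusion=pooled,
        predictions=predictions,
        extra={"subjects": subjects},
    )
    report.per_task = per_task_accuracy(predictions)
    return report


def audit_loso_fold(table: pd.DataFrame, train_idx, test_idx) -> None:
    """Reject folds whose training rows share a subject with the test rows."""
    train_subjects = set(table.iloc[train_idx]["subject_id"])
    test_subjects = set(table.iloc[test_idx]["subject_id"])
    if train_subjects & test_subjects:
        raise ValueError(
            f"subject leakage between train and test: {train_subjects & test_subjects}"
        )


def per_task_accuracy(predictions: pd.DataFrame) -> dict[str, float]:
    """Accuracy restricted to each task's test windows plus rest windows.

    Tasks absent from the test predictions are omitted (missing, not 0).
    """
    phases = predictions["phase"].astype(str)
    rest = predictions[phases.str.startswith("rest")]
    tasks = sorted(p for p in phases.unique() if not p.startswith("rest"))
    out = {}
    for task in tasks:
        subset = pd.concat(
            [predictions[phases == task], rest], ignore_index=True
        )
        out[task] = float(np.mean(subset["y_true"] == subset["y_pred"]))
    return out


def majority_class_rate(labels) -> float:
    """Accuracy of always predicting the most frequent class."""
    labels = pd.Series(labels)
    return float(labels.value_counts(normalize=True).iloc[0])
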