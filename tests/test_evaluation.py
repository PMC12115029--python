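"""Confusion-matrix metrics and the two cross-validation protocols."""

from fractions import Fraction
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import eogstress as eog
from eogstress.evaluation import (
    ConfusionMatrix,
    audit_loso_fold,
    confusion_from_predictions,
    kfold10_evaluate,
    loso_evaluate,
    majority_class_rate,
    metrics_from_confusion,
    per_task_accuracy,
)
from eogstress.features import FEATURE_NAMES
from eogstress.modeling import ModelSpec


def synthetic_feature_table(n_per_subject=60, subjects=4, signal=2.0, seed=0,
                            phases=("rest0", "task1", "task2")):
    """Small labelled table with a separable signal in two features."""
    r = np.random.default_rng(seed)
    rows = []
    for s in range(subjects):
        for i in range(n_per_subject):
            phase = phases[i % len(phases)]
            stressed = not phase.startswith("rest")
            feats = {name: r.normal() for name in FEATURE_NAMES}
            if stressed:
                feats["blink_freq"] += signal
                feats["mean_p2p_v"] -= signal
            rows.append({
                "subject_id": f"S{s:02d}",
                "start_s": float(i),
                "phase": phase,
                "label2": "stress" if stressed else "no_stress",
                "label3": "stress1" if stressed else "no_stress",
                **feats,
            })
    return pd.DataFrame(rows)


class TestMetrics:
    def test_binary_closed_form(self):
        """TP=40 FP=10 TN=45 FN=5 reproduces the closed-form metric values."""
        cm = ConfusionMatrix(classes=["neg", "pos"],
                             table=np.array([[45, 10], [5, 40]]))
        m = metrics_from_confusion(cm)
        pos = m["per_class"]["pos"]
        assert m["accuracy"] == pytest.approx(0.85, abs=1e-12)
        assert pos["precision"] == pytest.approx(Fraction(40, 50), abs=1e-12)
        assert pos["recall"] == pytest.approx(Fraction(40, 45), abs=1e-12)
        assert pos["f1"] == pytest.approx(Fraction(80, 95), abs=1e-12)
        assert pos["specificity"] == pytest.approx(Fraction(45, 55), abs=1e-12)

    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(classes=list("abc"), table=np.diag([7, 9, 4]))
        m = metrics_from_confusion(cm)
        for key in ("accuracy", "precision", "recall", "f1", "specificity"):
            assert m[key] == 1.0

    def test_three_class_matches_brute_force(self, rng):
        table = rng.integers(0, 30, size=(3, 3))
        cm = ConfusionMatrix(classes=list("xyz"), table=table)
        m = metrics_from_confusion(cm)
        total = table.sum()
        prs, res, f1s, spes = [], [], [], []
        for i in range(3):
            tp = table[i, i]
            fp = table[:, i].sum() - tp
            fn = table[i, :].sum() - tp
            tn = total - tp - fp - fn
            prs.append(tp / (tp + fp) if tp + fp else 0.0)
            res.append(tp / (tp + fn) if tp + fn else 0.0)
            f1s.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
            spes.append(tn / (tn + fp) if tn + fp else 0.0)
        assert m["accuracy"] == pytest.approx(np.trace(table) / total, abs=1e-12)
        assert m["precision"] == pytest.approx(np.mean(prs), abs=1e-12)
        assert m["recall"] == pytest.approx(np.mean(res), abs=1e-12)
        assert m["f1"] == pytest.approx(np.mean(f1s), abs=1e-12)
        assert m["specificity"] == pytest.approx(np.mean(spes), abs=1e-12)

    def test_macro_metrics_invariant_under_relabeling(self, rng):
        table = rng.integers(0, 20, size=(3, 3))
        base = metrics_from_confusion(ConfusionMatrix(list("abc"), table))
        for perm in permutations(range(3)):
            p = list(perm)
            permuted = table[np.ix_(p, p)]
            m = metrics_from_confusion(
                ConfusionMatrix([list("abc")[i] for i in p], permuted))
            for key in ("accuracy", "precision", "recall", "f1", "specificity"):
                assert m[key] == pytest.approx(base[key], abs=1e-12)

    def test_zero_denominator_flagged_as_zero(self):
        cm = ConfusionMatrix(classes=["a", "b"], table=np.array([[5, 0], [3, 0]]))
        m = metrics_from_confusion(cm)
        assert m["per_class"]["b"]["precision"] == 0.0
        assert any("b" in f for f in m["zero_denominator_flags"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionMatrix(["a"], np.array([[0]])))

    def test_accuracy_identity_with_prediction_lists(self, rng):
        y_true = rng.choice(list("abc"), 200)
        y_pred = rng.choice(list("abc"), 200)
        cm = confusion_from_predictions(y_true, y_pred)
        m = metrics_from_confusion(cm)
        assert m["accuracy"] == pytest.approx(np.mean(y_true == y_pred), abs=1e-12)


class TestKFold:
    def test_partition_tests_every_window_exactly_once(self):
        table = synthetic_feature_table(n_per_subject=25, subjects=4)  # 100 rows
        rep = kfold10_evaluate(table, ModelSpec("dt", "two"), seed=0)
        assert len(rep.fold_metrics) == 10
        counts = rep.predictions.groupby("fold").size()
        assert (counts == 10).all()
        assert len(rep.predictions) == len(table)

    def test_too_small_class_raises_stratification_error(self):
        table = synthetic_feature_table(n_per_subject=12, subjects=1)
        table.loc[table.index[:-4], "label2"] = "no_stress"
        with pytest.raises(ValueError):
            kfold10_evaluate(table, ModelSpec("dt", "two"), seed=0)

    def test_signal_beats_baseline(self):
        table = synthetic_feature_table(signal=3.0)
        rep = kfold10_evaluate(table, ModelSpec("rf", "two"), seed=0)
        assert rep.mean_metrics["accuracy"] > majority_class_rate(table["label2"])


class TestLoso:
    def test_one_fold_per_subject_no_leakage(self):
        table = synthetic_feature_table(subjects=3)
        rep = loso_evaluate(table, ModelSpec("dt", "two"), seed=0)
        assert len(rep.fold_metrics) == 3
        for fold_id, frame in rep.predictions.groupby("fold"):
            assert frame["subject_id"].nunique() == 1

    def test_two_subjects_two_folds(self):
        table = synthetic_feature_table(subjects=2)
        rep = loso_evaluate(table, ModelSpec("dt", "two"), seed=0)
        assert len(rep.fold_metrics) == 2

    def test_single_subject_rejected(self):
        table = synthetic_feature_table(subjects=1)
        with pytest.raises(ValueError):
            loso_evaluate(table, ModelSpec("dt", "two"), seed=0)

    def test_audit_detects_subject_leakage(self):
        table = synthetic_feature_table(subjects=2)
        n = len(table)
        # a "fold" whose training rows include the test subject is rejected
        with pytest.raises(ValueError, match="leakage"):
            audit_loso_fold(table, np.arange(n), np.arange(n // 2))


class TestPerTask:
    def test_all_correct_gives_one_per_task(self):
        preds = pd.DataFrame({
            "phase": ["rest0", "task1", "task2", "rest0"],
            "y_true": ["a", "b", "b", "a"],
            "y_pred": ["a", "b", "b", "a"],
        })
        assert per_task_accuracy(preds) == {"task1": 1.0, "task2": 1.0}

    def test_misclassified_task_composition(self):
        """One task fully wrong: accuracy = rest-correct share of the subset."""
        preds = pd.DataFrame({
            "phase": ["rest0"] * 6 + ["task1"] * 2,
            "y_true": ["n"] * 6 + ["s"] * 2,
            "y_pred": ["n"] * 5 + ["s"] + ["n"] * 2,  # 5/6 rest right, task wrong
        })
        out = per_task_accuracy(preds)
        assert out["task1"] == pytest.approx(5 / 8)

    def test_absent_task_is_missing_not_zero(self):
        preds = pd.DataFrame({
            "phase": ["rest0", "task1"],
            "y_true": ["n", "s"],
            "y_pred": ["n", "s"],
        })
        assert "task2" not in per_task_accuracy(preds)
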