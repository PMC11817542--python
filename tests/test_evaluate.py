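"""Metric formulas, ROC/AUC oracle equivalence, k-fold protocol."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.tree import DecisionTreeClassifier

from misinfonet.evaluate import (
    ConfusionMatrix,
    aggregate_reports,
    confusion,
    evaluate,
    f1_score,
    kfold,
    metrics,
    per_class_report,
    roc_auc,
    roc_points,
)


class TestConfusion:
    def test_enumeration(self):
        cm = confusion([1, 1, 0, 0], [1, 0, 0, 1], positive=1)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        cm = confusion([1, 0, 1], [1, 0, 1], positive=1)
        assert cm.fp == 0 and cm.fn == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [], positive=1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1], positive=1)

    def test_total_equals_documents(self):
        cm = confusion([1, 0, 1, 0, 1], [0, 0, 1, 1, 1], positive=1)
        assert cm.total == 5


class TestMetrics:
    def test_formula_evaluation(self):
        m = metrics(ConfusionMatrix(tp=3, tn=4, fp=1, fn=2))
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.6)
        assert m["f1"] == pytest.approx(2 / 3, abs=1e-4)

    def test_perfect_positive_case(self):
        m = metrics(ConfusionMatrix(tp=7, tn=0, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominators_absent_not_zero(self):
        m = metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert m["precision"] is None and m["recall"] is None and m["f1"] is None
        assert m["accuracy"] == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_printed_class_level_f1(self):
        # misinformation-class row: precision 0.88, recall 0.94 -> F1 ~ 0.91
        assert round(f1_score(0.88, 0.94), 2) == 0.91

    @given(
        tp=st.integers(0, 50), tn=st.integers(0, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_harmonic_mean_identity(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        m = metrics(ConfusionMatrix(tp, tn, fp, fn))
        if m["precision"] is not None and m["recall"] is not None:
            expect = f1_score(m["precision"], m["recall"])
            if expect is None:
                assert m["f1"] is None
            else:
                assert abs(m["f1"] - expect) < 1e-9


def brute_force_auc(scores, y):
    """All-pairs concordance count with ties half-weighted (the AUC oracle)."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_three_quarters(self):
        assert roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @given(
        st.lists(
            st.tuples(st.floats(0, 1, width=32), st.booleans()),
            min_size=4, max_size=200,
        ).filter(lambda v: len({b for _, b in v}) == 2)
    )
    def test_equals_bruteforce_concordance(self, pairs):
        scores = [s for s, _ in pairs]
        y = [int(b) for _, b in pairs]
        assert roc_auc(scores, y) == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_roc_points_shape(self):
        fpr, tpr, thr = roc_points([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert len(fpr) == len(tpr) == len(thr)
        assert fpr[0] == 0.0 and tpr[-1] == 1.0


class TestPerClassReport:
    def test_perfect_classifier_all_ones(self):
        rep = per_class_report([1, 0, 1], [1, 0, 1])
        for cls in rep.values():
            assert cls["precision"] == cls["recall"] == cls["f1"] == 1.0

    def test_swap_symmetry(self):
        y, p = [1, 1, 0, 0], [1, 0, 0, 1]
        rep = per_class_report(y, p)
        swapped = per_class_report([1 - v for v in y], [1 - v for v in p])
        assert rep["1"] == swapped["0"] and rep["0"] == swapped["1"]

    def test_enumerated_precisions(self):
        rep = per_class_report([1, 1, 0, 0], [1, 0, 0, 1])
        assert rep["1"]["precision"] == 0.5
        assert rep["0"]["precision"] == 0.5


class TestEvaluateAndAggregate:
    def test_micro_accuracy_equals_match_fraction(self, rng):
        y = rng.integers(0, 2, 60)
        p = rng.integers(0, 2, 60)
        rep = evaluate(y, p, positive=1)
        assert rep.accuracy == pytest.approx(float(np.mean(y == p)))

    def test_fold_mean(self):
        from misinfonet.evaluate import FoldResult, MetricsReport

        reports = [
            FoldResult(i, MetricsReport(a, None, None, None, None,
                                        ConfusionMatrix(1, 1, 1, 1)))
            for i, a in enumerate([0.8, 0.9, 1.0, 0.7, 0.6])
        ]
        assert aggregate_reports(reports)["accuracy"] == pytest.approx(0.8)


class TestKFold:
    def _data(self, n=100):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((n, 5))
        y = (X[:, 0] > 0).astype(int)
        X[:, 1] = y  # make it learnable
        return X, y

    def test_every_document_tested_once(self):
        X, y = self._data(100)
        folds, _ = kfold(X, y, lambda: DecisionTreeClassifier(random_state=0), k=5, seed=1)
        assert len(folds) == 5
        assert sum(f.report.confusion.total for f in folds) == 100

    def test_seeded_fold_assignment_reproducible(self):
        X, y = self._data(60)
        a = kfold(X, y, lambda: DecisionTreeClassifier(random_state=0), k=5, seed=3)
        b = kfold(X, y, lambda: DecisionTreeClassifier(random_state=0), k=5, seed=3)
        assert [f.report.as_dict() for f in a[0]] == [f.report.as_dict() for f in b[0]]

    def test_small_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array([1, 1, 1, 1, 1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="fewer than k"):
            kfold(X, y, lambda: DecisionTreeClassifier(), k=5, seed=0)
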