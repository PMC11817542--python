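"""Classic baselines, stacking ensemble, recurrent models, overfitting flag."""

import numpy as np
import pytest

from misinfonet.balance import doc_vector
from misinfonet.baselines import (
    BaselineSpec,
    OverfitReport,
    RecurrentTextClassifier,
    build_vocabulary,
    detect_overfitting,
    encode_sequences,
    featurize_classic,
    fit_baseline,
    make_baseline,
)
from misinfonet.preprocess import TokenSequence
from misinfonet.textconvonet import TrainingHistory


def _ts(doc_id, *tokens):
    return TokenSequence(doc_id, tokens)


class TestBaselineSpec:
    def test_recurrent_fields_required_for_recurrent_kinds(self):
        with pytest.raises(ValueError):
            BaselineSpec(kind="gru")
        BaselineSpec(kind="gru", recurrent_layers=1, cells=16)

    def test_recurrent_fields_forbidden_for_classic_kinds(self):
        with pytest.raises(ValueError, match="not applicable"):
            BaselineSpec(kind="svm", cells=16)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            BaselineSpec(kind="transformer")

    @pytest.mark.parametrize("cells", [15, 256])
    def test_cell_grid_enforced(self, cells):
        with pytest.raises(ValueError):
            BaselineSpec(kind="lstm", recurrent_layers=1, cells=cells)


class TestFeaturize:
    def test_two_documents_over_union_vocabulary(self):
        X, vec = featurize_classic([_ts("a", "covid", "real"), _ts("b", "vaccine")])
        assert X.shape == (2, 3)

    def test_identical_documents_identical_vectors(self):
        X, _ = featurize_classic([_ts("a", "covid", "real"), _ts("b", "covid", "real")])
        assert (X[0] != X[1]).nnz == 0

    def test_agrees_with_balance_doc_vector(self):
        corpus = [_ts("a", "covid", "real", "covid"), _ts("b", "vaccine", "works")]
        X, vec = featurize_classic(corpus)
        v = doc_vector(corpus[0], vec)
        assert (X[0] != v).nnz == 0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            featurize_classic([])


class TestClassicBaselines:
    def test_tree_memorizes_consistent_toy_set(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([0, 0, 1, 1])
        model = fit_baseline(BaselineSpec(kind="decision_tree"), X, y)
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_baseline(BaselineSpec(kind="svm"), np.eye(3), np.zeros(3))

    def test_seeded_determinism(self, separable_corpus):
        _, toks, y = separable_corpus
        X, _ = featurize_classic(toks)
        preds = [
            fit_baseline(BaselineSpec(kind="random_forest", seed=5), X[:300], y[:300])
            .predict(X[300:])
            for _ in range(2)
        ]
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_stacking_close_to_best_base_learner(self, separable_corpus):
        _, toks, y = separable_corpus
        X, _ = featurize_classic(toks)
        Xtr, Xte, ytr, yte = X[:300], X[300:], y[:300], y[300:]
        accs = {}
        for kind in ("decision_tree", "random_forest", "svm", "stacking"):
            model = fit_baseline(BaselineSpec(kind=kind, seed=0), Xtr, ytr)
            accs[kind] = float((model.predict(Xte) == yte).mean())
        best_base = max(accs[k] for k in ("decision_tree", "random_forest", "svm"))
        assert accs["stacking"] >= best_base - 0.02

    def test_all_classic_beat_majority(self, separable_corpus):
        _, toks, y = separable_corpus
        X, _ = featurize_classic(toks)
        Xtr, Xte, ytr, yte = X[:300], X[300:], y[:300], y[300:]
        majority = max(yte.mean(), 1 - yte.mean())
        for kind in ("decision_tree", "random_forest", "svm", "stacking"):
            model = fit_baseline(BaselineSpec(kind=kind, seed=0), Xtr, ytr)
            assert (model.predict(Xte) == yte).mean() > majority


class TestEncoding:
    def test_vocabulary_reserves_padding_and_oov(self):
        vocab = build_vocabulary([_ts("a", "xx", "yy", "xx")])
        assert min(vocab.values()) == 2
        assert vocab["xx"] < vocab["yy"]  # frequency-ranked

    def test_encode_pads_and_truncates(self):
        vocab = {"xx": 2, "yy": 3}
        out = encode_sequences([_ts("a", "xx", "zz", "yy")], vocab, max_tokens=5)
        np.testing.assert_array_equal(out[0], [2, 1, 3, 0, 0])
        out = encode_sequences([_ts("a", *(["xx"] * 9))], vocab, max_tokens=4)
        assert out.shape == (1, 4)


class TestRecurrent:
    FAST = dict(max_tokens=20, embedding_dim=16, learning_rate=5e-3,
                batch_size=32, validation_fraction=0.2)

    @pytest.mark.parametrize("kind", ["gru", "lstm"])
    def test_learns_separable_task(self, separable_corpus, kind):
        _, toks, y = separable_corpus
        clf = RecurrentTextClassifier(kind=kind, cells=16, epochs=4, seed=0, **self.FAST)
        clf.fit(toks[:300], y[:300])
        acc = float((clf.predict(toks[300:]) == y[300:]).mean())
        majority = max(y[300:].mean(), 1 - y[300:].mean())
        assert acc > majority
        assert len(clf.history_) == 4
        assert len(clf.history_.val_accuracy) == 4

    def test_seeded_determinism(self, separable_corpus):
        _, toks, y = separable_corpus
        out = []
        for _ in range(2):
            clf = RecurrentTextClassifier(kind="gru", cells=16, epochs=1, seed=4, **self.FAST)
            clf.fit(toks[:200], y[:200])
            out.append(clf.predict_proba(toks[200:240]))
        np.testing.assert_array_equal(out[0], out[1])

    def test_single_class_rejected(self):
        clf = RecurrentTextClassifier()
        with pytest.raises(ValueError, match="single class"):
            clf.fit([_ts("a", "xx"), _ts("b", "yy")], [1, 1])

    def test_regularization_options_run(self, separable_corpus):
        _, toks, y = separable_corpus
        clf = RecurrentTextClassifier(
            kind="lstm", cells=16, epochs=1, seed=0,
            dropout_rate=0.3, l1=1e-5, l2=1e-4, **self.FAST,
        )
        clf.fit(toks[:100], y[:100])
        assert np.isfinite(clf.history_.train_loss).all()


class TestDetectOverfitting:
    def _hist(self, tr_acc, va_acc, tr_loss=None, va_loss=None):
        n = len(tr_acc)
        return TrainingHistory(
            train_loss=tr_loss or [1.0 / (i + 1) for i in range(n)],
            train_accuracy=list(tr_acc),
            val_loss=va_loss or [1.0 / (i + 1) for i in range(n)],
            val_accuracy=list(va_acc),
        )

    def test_converging_history_not_flagged(self):
        rep = detect_overfitting(self._hist([0.9, 0.95, 0.99], [0.88, 0.93, 0.97]))
        assert rep == OverfitReport(flag=False)

    def test_diverging_history_flagged_at_epoch_two(self):
        rep = detect_overfitting(
            self._hist([0.8, 0.95, 0.99, 0.99], [0.75, 0.70, 0.66, 0.64])
        )
        assert rep.flag and rep.first_epoch == 2

    def test_single_epoch_insufficient_evidence(self):
        rep = detect_overfitting(self._hist([0.99], [0.5]))
        assert not rep.flag

    def test_loss_divergence_rule(self):
        rep = detect_overfitting(
            self._hist(
                [0.8, 0.85, 0.9, 0.95], [0.78, 0.8, 0.82, 0.84],
                tr_loss=[1.0, 0.7, 0.5, 0.3], va_loss=[1.0, 1.1, 1.3, 1.6],
            )
        )
        assert rep.flag and rep.first_epoch == 2

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            detect_overfitting(TrainingHistory())


def test_make_baseline_covers_all_kinds():
    for kind in ("decision_tree", "random_forest", "svm", "stacking"):
        assert make_baseline(BaselineSpec(kind=kind)) is not None
    m = make_baseline(BaselineSpec(kind="lstm", recurrent_layers=2, cells=32))
    assert isinstance(m, RecurrentTextClassifier)
    assert m.recurrent_layers == 2 and m.cells == 32
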