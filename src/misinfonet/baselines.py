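"""Comparison classifiers and overfitting detection.

Six baselines accompany the convolutional model: decision tree, random
forest, support-vector machine, their stacking ensemble (logistic
meta-learner on out-of-fold base probabilities), and one/two-layer GRU and
LSTM recurrent networks. Classic models consume TF-IDF vectors (the same
weighting scheme the augmentation step uses); recurrent models consume
token-index sequences padded/truncated to the same 100-token budget as the
embedding matrices. All baselines expose the scikit-learn
fit / predict / predict_proba interface so the evaluation protocol is
model-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .balance import make_tfidf
from .nn import Adam, Dense, Embedding, GRULayer, LSTMLayer, Module, bce_with_logits
from .nn import tensor as T
from .preprocess import TokenSequence
from .textconvonet import TrainingHistory

CLASSIC_KINDS = ("decision_tree", "random_forest", "svm", "stacking")
RECURRENT_KINDS = ("gru", "lstm")


@dataclass(frozen=True)
class BaselineSpec:
    """Which baseline to build; recurrent fields apply to gru/lstm only."""

    kind: str
    recurrent_layers: int | None = None
    cells: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIC_KINDS + RECURRENT_KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        recurrent = self.kind in RECURRENT_KINDS
        if recurrent:
            if self.recurrent_layers not in (1, 2):
                raise ValueError("recurrent_layers must be 1 or 2 for gru/lstm")
            if self.cells not in (16, 32, 64, 128):
                raise ValueError("cells must be one of 16, 32, 64, 128")
        elif self.recurrent_layers is not None or self.cells is not None:
            raise ValueError(
                f"recurrent fields are not applicable to kind {self.kind!r}"
            )


def featurize_classic(
    token_sequences: Sequence[TokenSequence],
) -> tuple[sp.csr_matrix, object]:
    """TF-IDF vectors over cleaned unigrams (shared with the balance module).

    Returns ``(matrix, fitted_vectorizer)``.
    """
    if not token_sequences:
        raise ValueError("cannot featurize an empty corpus")
    vec = make_tfidf(token_sequences)
    return vec.transform(token_sequences), vec


def build_vocabulary(
    token_sequences: Sequence[TokenSequence], max_size: int = 20000
) -> dict[str, int]:
    """Frequency-ranked token -> index map; 0 is padding, 1 is out-of-vocabulary."""
    counts: dict[str, int] = {}
    for ts in token_sequences:
        for tok in ts.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    ranked = sorted(counts, key=lambda w: (-counts[w], w))[: max_size - 2]
    return {w: i + 2 for i, w in enumerate(ranked)}


def encode_sequences(
    token_sequences: Sequence[TokenSequence],
    vocab: dict[str, int],
    max_tokens: int = 100,
) -> np.ndarray:
    """Integer-encode token sequences, zero-padded/truncated to max_tokens."""
    out = np.zeros((len(token_sequences), max_tokens), dtype=np.int64)
    for i, ts in enumerate(token_sequences):
        for j, tok in enumerate(ts.tokens[:max_tokens]):
            out[i, j] = vocab.get(tok, 1)
    return out


class _RecurrentModule(Module):
    def __init__(self, kind, vocab_size, embedding_dim, cells, layers, rng):
        layer_cls = GRULayer if kind == "gru" else LSTMLayer
        self.embed = Embedding(vocab_size, embedding_dim, rng)
        self.recurrent = [
            layer_cls(embedding_dim if i == 0 else cells, cells, rng)
            for i in range(layers)
        ]
        self.head = Dense(cells, 1, rng)

    def __call__(self, idx: np.ndarray, rng, training: bool, dropout_rate: float):
        x = self.embed(idx)
        for layer in self.recurrent:
            x = layer(x)
            if dropout_rate > 0:
                x = T.dropout(x, dropout_rate, rng, training=training)
        B, Tn, H = x.data.shape
        last = T.reshape(T.narrow(x, 1, Tn - 1, 1), (B, H))
        return self.head(last)


class RecurrentTextClassifier(BaseEstimator, ClassifierMixin):
    """GRU/LSTM classifier over token-index sequences.

    Trains with the same optimizer and batch settings as the convolutional
    model (Adam, binary cross-entropy, batch 128, learning rate 1e-4) for
    comparability; dropout and L1/L2 penalties are exposed because they are
    the standard levers against the overfitting these models are prone to
    on small, imbalanced corpora.

    ``X`` may be a sequence of :class:`TokenSequence` or pre-encoded integer
    arrays of shape ``(n, max_tokens)``.
    """

    def __init__(
        self,
        kind: Literal["gru", "lstm"] = "gru",
        recurrent_layers: int = 1,
        cells: int = 16,
        embedding_dim: int = 32,
        max_tokens: int = 100,
        vocab_size: int = 20000,
        learning_rate: float = 1e-4,
        batch_size: int = 128,
        epochs: int = 5,
        dropout_rate: float = 0.0,
        l1: float = 0.0,
        l2: float = 0.0,
        seed: int = 0,
        validation_fraction: float = 0.1,
    ):
        self.kind = kind
        self.recurrent_layers = recurrent_layers
        self.cells = cells
        self.embedding_dim = embedding_dim
        self.max_tokens = max_tokens
        self.vocab_size = vocab_size
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout_rate = dropout_rate
        self.l1 = l1
        self.l2 = l2
        self.seed = seed
        self.validation_fraction = validation_fraction

    def _encode(self, X) -> np.ndarray:
        first = X[0] if len(X) else None
        if isinstance(first, TokenSequence):
            return encode_sequences(X, self.vocab_, self.max_tokens)
        arr = np.asarray(X)
        if arr.dtype == object and len(arr) and isinstance(arr.ravel()[0], TokenSequence):
            return encode_sequences(list(arr.ravel()), self.vocab_, self.max_tokens)
        return arr.astype(np.int64)

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set contains a single class")
        if len(self.classes_) > 2:
            raise ValueError("binary classifier: y has more than two classes")
        first = X[0] if len(X) else None
        arr = np.asarray(X) if not isinstance(first, TokenSequence) else None
        if isinstance(first, TokenSequence):
            self.vocab_ = build_vocabulary(X, self.vocab_size)
        elif arr is not None and arr.dtype == object:
            self.vocab_ = build_vocabulary(list(arr.ravel()), self.vocab_size)
        else:
            self.vocab_ = {}
        idx = self._encode(X)
        y_bin = (y == self.classes_[1]).astype(np.float32)

        if self.validation_fraction > 0:
            idx, idx_v, y_bin, yv = train_test_split(
                idx,
                y_bin,
                test_size=self.validation_fraction,
                stratify=y_bin,
                random_state=self.seed,
            )
        else:
            idx_v, yv = None, None

        n_embed = max(len(self.vocab_) + 2, int(idx.max(initial=1)) + 1)
        rng = np.random.Generator(np.random.PCG64(self.seed))
        self.model_ = _RecurrentModule(
            self.kind, n_embed, self.embedding_dim, self.cells,
            self.recurrent_layers, rng,
        )
        opt = Adam(self.model_.parameters(), lr=self.learning_rate)
        self.history_ = TrainingHistory()
        n = idx.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                b = order[start : start + self.batch_size]
                logits = self.model_(
                    idx[b], rng, training=True, dropout_rate=self.dropout_rate
                )
                loss = bce_with_logits(logits, y_bin[b][:, None])
                opt.zero_grad()
                loss.backward()
                if self.l1 > 0 or self.l2 > 0:
                    for p in self.model_.parameters():
                        if p.grad is None:
                            continue
                        if self.l2 > 0:
                            p.grad += np.float32(self.l2) * p.data
                        if self.l1 > 0:
                            p.grad += np.float32(self.l1) * np.sign(p.data)
                opt.step()
                losses.append(float(loss.data.ravel()[0]) * len(b))
                preds = (logits.data.ravel() > 0).astype(np.float32)
                correct += int((preds == y_bin[b]).sum())
            self.history_.train_loss.append(sum(losses) / n)
            self.history_.train_accuracy.append(correct / n)
            if idx_v is not None and len(idx_v):
                z = self._logits(idx_v).astype(np.float64)
                softplus = np.where(z > 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
                self.history_.val_loss.append(float(np.mean(softplus - yv * z)))
                self.history_.val_accuracy.append(
                    float(((z > 0).astype(np.float32) == yv).mean())
                )
        return self

    def _logits(self, idx: np.ndarray) -> np.ndarray:
        rng = np.random.Generator(np.random.PCG64(0))
        out = []
        with T.no_grad():
            for start in range(0, idx.shape[0], self.batch_size):
                z = self.model_(
                    idx[start : start + self.batch_size],
                    rng,
                    training=False,
                    dropout_rate=0.0,
                )
                out.append(z.data.ravel())
        return np.concatenate(out) if out else np.zeros(0, dtype=np.float32)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        z = self._logits(self._encode(X)).astype(np.float64)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]


def make_baseline(spec: BaselineSpec):
    """Instantiate an unfitted baseline estimator from its spec.

    Classic models use the scikit-learn defaults (recorded via
    ``get_params`` for provenance); the stacking ensemble trains DT, RF and
    SVM base learners and a logistic meta-classifier on their out-of-fold
    predicted probabilities (5-fold).
    """
    seed = spec.seed
    if spec.kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if spec.kind == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if spec.kind == "svm":
        return SVC(probability=True, random_state=seed)
    if spec.kind == "stacking":
        return StackingClassifier(
            estimators=[
                ("dt", DecisionTreeClassifier(random_state=seed)),
                ("rf", RandomForestClassifier(random_state=seed)),
                ("svm", SVC(probability=True, random_state=seed)),
            ],
            final_estimator=LogisticRegression(max_iter=1000),
            cv=5,
            stack_method="predict_proba",
        )
    return RecurrentTextClassifier(
        kind=spec.kind,
        recurrent_layers=spec.recurrent_layers or 1,
        cells=spec.cells or 16,
        seed=seed,
    )


def fit_baseline(spec: BaselineSpec, X, y):
    """Build and train a baseline; errors on single-class input."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    model = make_baseline(spec)
    model.fit(X, y)
    return model


@dataclass(frozen=True)
class OverfitReport:
    flag: bool
    first_epoch: int | None = None


def detect_overfitting(
    history: TrainingHistory, gap: float = 0.15, patience: int = 2
) -> OverfitReport:
    """Flag train/validation divergence in a training history.

    Flags when the train-validation accuracy gap exceeds ``gap`` for at
    least ``patience`` consecutive epochs, or when validation loss rises
    while training loss falls for at least ``patience`` consecutive epochs.
    ``first_epoch`` is the (0-based) epoch at which the patience run
    completes.
    """
    if len(history) == 0:
        raise ValueError("history is empty")
    n = len(history.train_accuracy)
    if history.val_accuracy:
        run = 0
        for i in range(min(n, len(history.val_accuracy))):
            run = run + 1 if history.train_accuracy[i] - history.val_accuracy[i] > gap else 0
            if run >= patience:
                return OverfitReport(flag=True, first_epoch=i)
    if history.val_loss and len(history.train_loss) >= 2:
        run = 0
        m = min(len(history.train_loss), len(history.val_loss))
        for i in range(1, m):
            diverging = (
                history.val_loss[i] > history.val_loss[i - 1]
                and history.train_loss[i] < history.train_loss[i - 1]
            )
            run = run + 1 if diverging else 0
            if run >= patience:
                return OverfitReport(flag=True, first_epoch=i)
    return OverfitReport(flag=False)
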