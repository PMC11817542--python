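"""The four-pathway 2-D convolutional short-text classifier.

The network reads a document as a ``tokens x dims`` embedding plane (default
100 x 100) and runs four parallel convolutional pathways over it. Kernel
shapes target different text structure: a wide 12x12 main kernel and a 2x2
sub kernel capture patterns spanning token rows (inter-sentence), while
11x2 and 1x3 kernels capture patterns within and along individual rows
(intra-sentence). Each pathway stacks three same-padded convolutions,
applies dropout *before* its single ReLU (an overfitting countermeasure),
then 2x2 max pooling. The intra pair and inter pair of pathway outputs are
concatenated, the two concatenations joined, flattened, passed through one
ReLU dense layer and a single sigmoid output giving P(misinformation).

Training uses Adam with binary cross-entropy, learning rate 1e-4, batch
size 128 and 5 epochs by default; all randomness (initialization, epoch
shuffling, dropout) derives from the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, Conv2D, Dense, Module, Tensor, bce_with_logits
from .nn import tensor as T


@dataclass(frozen=True)
class TextConvoNetConfig:
    """Architecture and training hyperparameters.

    Kernel sizes, dense width, loss, optimizer, learning rate and batch size
    follow the published configuration; filter count, padding, stride and
    pooling geometry are exposed here because the publication leaves them
    open. The default of 4 filters per convolution keeps a desk-scale run
    (a few thousand documents on one CPU) inside minutes while remaining
    comfortably above the capacity the synthetic two-topic task needs.
    """

    input_shape: tuple[int, int] = (100, 100)
    kernel_inter_main: tuple[int, int] = (12, 12)
    kernel_inter_sub: tuple[int, int] = (2, 2)
    kernel_intra_main: tuple[int, int] = (11, 2)
    kernel_intra_sub: tuple[int, int] = (1, 3)
    convs_per_pathway: int = 3
    filters_per_conv: int = 4
    dropout_rate: float = 0.5
    dense_units: int = 128
    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 5
    pool_size: int = 2
    seed: int = 0
    conv_method: str = "auto"

    def __post_init__(self) -> None:
        h, w = self.input_shape
        for name in ("kernel_inter_main", "kernel_inter_sub",
                     "kernel_intra_main", "kernel_intra_sub"):
            kh, kw = getattr(self, name)
            if kh > h or kw > w:
                raise ValueError(
                    f"{name} {kh}x{kw} does not fit input plane {h}x{w}"
                )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.convs_per_pathway < 1:
            raise ValueError("convs_per_pathway must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch losses and accuracies on train and validation data."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


class _Pathway(Module):
    def __init__(self, kernel, config: TextConvoNetConfig, rng):
        f = config.filters_per_conv
        chans = [1] + [f] * config.convs_per_pathway
        self.kernel = tuple(kernel)
        self.convs = [
            Conv2D(chans[i], chans[i + 1], kernel, rng, method=config.conv_method)
            for i in range(config.convs_per_pathway)
        ]
        self.dropout_rate = config.dropout_rate
        self.pool_size = config.pool_size

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        for conv in self.convs:
            x = conv(x)
        x = T.dropout(x, self.dropout_rate, rng, training=training)
        x = T.relu(x)
        x = T.maxpool2d(x, self.pool_size)
        return T.reshape(x, (x.data.shape[0], -1))


class _TextConvoNetModule(Module):
    def __init__(self, config: TextConvoNetConfig, rng):
        self.config = config
        # intra-sentence pair and inter-sentence pair over the shared plane
        self.intra = [
            _Pathway(config.kernel_intra_main, config, rng),
            _Pathway(config.kernel_intra_sub, config, rng),
        ]
        self.inter = [
            _Pathway(config.kernel_inter_main, config, rng),
            _Pathway(config.kernel_inter_sub, config, rng),
        ]
        h, w = config.input_shape
        hp, wp = h // config.pool_size, w // config.pool_size
        per_pathway = config.filters_per_conv * hp * wp
        self.dense = Dense(4 * per_pathway, config.dense_units, rng)
        self.head = Dense(config.dense_units, 1, rng)

    def __call__(self, x: np.ndarray, rng, training: bool) -> Tensor:
        xt = Tensor(x[:, None, :, :])  # single-channel plane
        intra = T.concat([p(xt, rng, training) for p in self.intra], axis=1)
        inter = T.concat([p(xt, rng, training) for p in self.inter], axis=1)
        merged = T.concat([intra, inter], axis=1)
        hidden = T.relu(self.dense(merged))
        return self.head(hidden)  # logits


def build_model(config: TextConvoNetConfig) -> tuple[_TextConvoNetModule, dict]:
    """Construct an untrained network and its architecture summary."""
    rng = np.random.Generator(np.random.PCG64(config.seed))
    model = _TextConvoNetModule(config, rng)
    h, w = config.input_shape
    hp, wp = h // config.pool_size, w // config.pool_size
    f = config.filters_per_conv
    pathways = []
    for group, paths in (("intra", model.intra), ("inter", model.inter)):
        for p in paths:
            pathways.append(
                {
                    "group": group,
                    "kernel": list(p.kernel),
                    "convs": config.convs_per_pathway,
                    "filters": f,
                    "conv_output_shape": [f, h, w],
                    "pooled_output_shape": [f, hp, wp],
                }
            )
    summary = {
        "input_shape": list(config.input_shape),
        "pathways": pathways,
        "concatenated_features": 4 * f * hp * wp,
        "dense_units": config.dense_units,
        "output_units": 1,
        "total_parameters": model.n_parameters(),
    }
    return model, summary


def summary_text(summary: dict) -> str:
    lines = [f"input plane: {summary['input_shape'][0]}x{summary['input_shape'][1]}"]
    for p in summary["pathways"]:
        lines.append(
            f"pathway ({p['group']}): {p['convs']} x conv {p['kernel'][0]}x{p['kernel'][1]}"
            f" ({p['filters']} filters) -> dropout -> relu -> maxpool"
            f" -> {p['pooled_output_shape']}"
        )
    lines.append(f"concat -> {summary['concatenated_features']} features")
    lines.append(f"dense({summary['dense_units']}, relu) -> dense(1, sigmoid)")
    lines.append(f"total parameters: {summary['total_parameters']}")
    return "\n".join(lines)


class TextConvoNetClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style estimator around the four-pathway network.

    Parameters mirror :class:`TextConvoNetConfig`; ``fit`` expects
    ``X`` of shape ``(n_docs, tokens, dims)`` and binary ``y`` where the
    positive class (1) is *misinformation*.

    Attributes
    ----------
    model_ : the trained network module
    history_ : TrainingHistory
    summary_ : architecture summary dict
    classes_ : array of class labels seen in ``y``
    """

    def __init__(
        self,
        input_shape: tuple[int, int] = (100, 100),
        filters_per_conv: int = 4,
        convs_per_pathway: int = 3,
        dropout_rate: float = 0.5,
        dense_units: int = 128,
        learning_rate: float = 1e-4,
        batch_size: int = 128,
        epochs: int = 5,
        seed: int = 0,
        conv_method: str = "auto",
        validation_fraction: float = 0.1,
        micro_batch_size: int = 32,
    ):
        self.input_shape = input_shape
        self.filters_per_conv = filters_per_conv
        self.convs_per_pathway = convs_per_pathway
        self.dropout_rate = dropout_rate
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.conv_method = conv_method
        self.validation_fraction = validation_fraction
        self.micro_batch_size = micro_batch_size

    def _config(self) -> TextConvoNetConfig:
        return TextConvoNetConfig(
            input_shape=tuple(self.input_shape),
            filters_per_conv=self.filters_per_conv,
            convs_per_pathway=self.convs_per_pathway,
            dropout_rate=self.dropout_rate,
            dense_units=self.dense_units,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
            conv_method=self.conv_method,
        )

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        h, w = self.input_shape
        if X.ndim != 3 or X.shape[1:] != (h, w):
            raise ValueError(
                f"X must have shape (n, {h}, {w}); got {X.shape}"
            )
        return X

    def fit(self, X, y, validation_data=None):
        config = self._config()
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set contains a single class")
        if len(self.classes_) > 2:
            raise ValueError("binary classifier: y has more than two classes")
        y_bin = (y == self.classes_[1]).astype(np.float32)

        if validation_data is None and self.validation_fraction > 0:
            X, Xv, y_bin, yv = train_test_split(
                X,
                y_bin,
                test_size=self.validation_fraction,
                stratify=y_bin,
                random_state=config.seed,
            )
        elif validation_data is not None:
            Xv = self._check_X(validation_data[0])
            yv = (np.asarray(validation_data[1]) == self.classes_[1]).astype(
                np.float32
            )
        else:
            Xv, yv = None, None

        self.model_, self.summary_ = build_model(config)
        rng = np.random.Generator(np.random.PCG64(config.seed + 1))
        opt = Adam(self.model_.parameters(), lr=config.learning_rate)
        self.history_ = TrainingHistory()
        n = X.shape[0]
        micro = max(1, int(self.micro_batch_size))
        for _ in range(config.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                opt.zero_grad()
                # gradient accumulation over micro-batches: identical update
                # to a full batch of config.batch_size, but bounded memory
                for ms in range(0, len(idx), micro):
                    midx = idx[ms : ms + micro]
                    logits = self.model_(X[midx], rng, training=True)
                    loss = bce_with_logits(logits, y_bin[midx][:, None])
                    T.scale(loss, len(midx) / len(idx)).backward()
                    losses.append(float(loss.data.ravel()[0]) * len(midx))
                    preds = (logits.data.ravel() > 0).astype(np.float32)
                    correct += int((preds == y_bin[midx]).sum())
                opt.step()
            self.history_.train_loss.append(sum(losses) / n)
            self.history_.train_accuracy.append(correct / n)
            if Xv is not None and len(Xv):
                vl, va = self._eval_loss_acc(Xv, yv)
                self.history_.val_loss.append(vl)
                self.history_.val_accuracy.append(va)
        return self

    def _forward_eval(self, X: np.ndarray) -> np.ndarray:
        rng = np.random.Generator(np.random.PCG64(0))  # unused in eval mode
        logits = []
        chunk = max(1, int(self.micro_batch_size))
        with T.no_grad():
            for start in range(0, X.shape[0], chunk):
                out = self.model_(X[start : start + chunk], rng, training=False)
                logits.append(out.data.ravel())
        return np.concatenate(logits) if logits else np.zeros(0, dtype=np.float32)

    def _eval_loss_acc(self, X: np.ndarray, y_bin: np.ndarray) -> tuple[float, float]:
        z = self._forward_eval(X).astype(np.float64)
        softplus = np.where(z > 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
        loss = float(np.mean(softplus - y_bin * z))
        acc = float(((z > 0).astype(np.float32) == y_bin).mean())
        return loss, acc

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self._forward_eval(self._check_X(X))

    def predict_proba(self, X) -> np.ndarray:
        """Column 0: P(classes_[0]); column 1: P(classes_[1]=misinformation)."""
        z = self.decision_function(X).astype(np.float64)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        return self.classes_[(p1 > 0.5).astype(int)]

    def summary_json(self) -> str:
        check_is_fitted(self, "summary_")
        return json.dumps(self.summary_, indent=2)


def train(
    model: TextConvoNetClassifier,
    X_train: np.ndarray,
    y_train: Sequence,
    validation_data: tuple[np.ndarray, Sequence] | None = None,
) -> tuple[TextConvoNetClassifier, TrainingHistory]:
    """Functional wrapper: fit and return (estimator, history)."""
    model.fit(X_train, y_train, validation_data=validation_data)
    return model, model.history_


def predict(model: TextConvoNetClassifier, X: np.ndarray) -> np.ndarray:
    """Per-document probability of the misinformation class."""
    return model.predict_proba(X)[:, 1]
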