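"""End-to-end orchestration: simulate -> calibrate -> augment -> train -> evaluate.

The desk-scale run reproduces the study protocol on a synthetic corpus:
generate an imbalanced two-class tweet corpus plus a verified seed sample
and candidate pool, calibrate the cosine-similarity threshold on the
verified sample, inject qualifying candidates into the trustworthy class,
embed every document as a 100 x 100 matrix, train the convolutional
classifier, and report the full metric set against a stratified held-out
test split. Because augmentation rebalances the data used "for training
and testing purposes", the train/test split is taken *after* injection;
the majority-class baseline refers to that test split. An unaugmented
control arm quantifies what the injection buys.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .balance import CosineSimilarityAugmenter
from .corpus import MISINFORMATION, TRUSTWORTHY, Document
from .embeddings import DocumentMatrixVectorizer
from .evaluate import MetricsReport, evaluate
from .preprocess import clean_corpus
from .synth import CorpusSpec, generate_corpus, generate_seed_sets
from .textconvonet import TextConvoNetClassifier

#: canonical label -> binary target (misinformation is the positive class)
LABEL_TO_INT = {TRUSTWORTHY: 0, MISINFORMATION: 1}


def labels_to_binary(docs: Sequence[Document]) -> np.ndarray:
    """Map canonical labels to {0: trustworthy, 1: misinformation}."""
    out = []
    for d in docs:
        if d.label not in LABEL_TO_INT:
            raise ValueError(f"document {d.id!r} is unlabeled")
        out.append(LABEL_TO_INT[d.label])
    return np.asarray(out)


@dataclass
class DeskRunResult:
    """Everything the end-to-end desk run measured."""

    threshold: float
    calibration_rows: list[dict]
    n_injected: int
    minority_share_before: float
    minority_share_after: float
    majority_baseline: float
    report: MetricsReport
    control_report: MetricsReport | None
    control_majority_baseline: float | None
    minority_recall: float | None
    control_minority_recall: float | None
    pipeline_seconds: float
    control_seconds: float | None
    history: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_injected": self.n_injected,
            "minority_share_before": self.minority_share_before,
            "minority_share_after": self.minority_share_after,
            "majority_baseline": self.majority_baseline,
            "metrics": self.report.as_dict(),
            "control_metrics": (
                self.control_report.as_dict() if self.control_report else None
            ),
            "minority_recall": self.minority_recall,
            "control_minority_recall": self.control_minority_recall,
            "pipeline_seconds": self.pipeline_seconds,
            "control_seconds": self.control_seconds,
            "calibration": self.calibration_rows,
            "history": self.history,
        }


def _train_and_score(
    docs: Sequence[Document],
    seed: int,
    clf_params: dict,
    test_fraction: float,
) -> tuple[MetricsReport, float, float, dict]:
    """Embed, stratified-split, train, evaluate. Returns (report, majority, minority_recall, history)."""
    toks = clean_corpus(docs)
    X = DocumentMatrixVectorizer(seed=seed).fit(toks).transform(toks)
    y = labels_to_binary(docs)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    clf = TextConvoNetClassifier(seed=seed, **clf_params)
    clf.fit(X_tr, y_tr)
    y_pred = clf.predict(X_te)
    scores = clf.predict_proba(X_te)[:, 1]
    report = evaluate(y_te, y_pred, scores=scores, positive=1)
    majority = float(max(np.mean(y_te == 1), np.mean(y_te == 0)))
    minority_recall = report.per_class.get("0", {}).get("recall")
    history = {
        "train_loss": clf.history_.train_loss,
        "train_accuracy": clf.history_.train_accuracy,
        "val_loss": clf.history_.val_loss,
        "val_accuracy": clf.history_.val_accuracy,
    }
    return report, majority, minority_recall, history


def desk_run(
    seed: int = 0,
    spec: CorpusSpec | None = None,
    pool_size: int = 1500,
    pool_trust_fraction: float = 2 / 3,
    test_fraction: float = 0.2,
    with_control: bool = True,
    clf_params: dict | None = None,
) -> DeskRunResult:
    """Run the full pipeline on a synthetic corpus; optionally an unaugmented control.

    Defaults follow the study conditions: 2,000 documents, 15% trustworthy
    minority, topic purity 0.9, verified sample of 180 + 70, candidate pool
    of 1,500 (two thirds truly trustworthy).
    """
    clf_params = dict(clf_params or {})
    spec = spec or CorpusSpec(
        n_docs=2000, minority_fraction=0.15, topic_purity=0.9, seed=seed
    )
    t0 = time.time()
    docs, _ = generate_corpus(spec)
    verified, pool, _ = generate_seed_sets(
        spec, pool_size=pool_size, pool_trust_fraction=pool_trust_fraction
    )
    corpus_toks = clean_corpus(docs)
    verified_toks = clean_corpus(verified)
    pool_toks = clean_corpus(pool)

    augmenter = CosineSimilarityAugmenter()
    augmenter.fit(
        corpus_toks + pool_toks,
        [(ts, d.label) for ts, d in zip(verified_toks, verified)],
    )
    augmented, injection = augmenter.transform(docs, pool, pool_toks)

    share_before = float(np.mean([d.label == TRUSTWORTHY for d in docs]))
    share_after = float(np.mean([d.label == TRUSTWORTHY for d in augmented]))

    report, majority, minority_recall, history = _train_and_score(
        augmented, seed, clf_params, test_fraction
    )
    pipeline_seconds = time.time() - t0

    control_report = control_majority = control_recall = control_seconds = None
    if with_control:
        t1 = time.time()
        control_report, control_majority, control_recall, _ = _train_and_score(
            docs, seed, clf_params, test_fraction
        )
        control_seconds = time.time() - t1

    return DeskRunResult(
        threshold=augmenter.threshold_,
        calibration_rows=augmenter.calibration_.as_rows(),
        n_injected=len(injection.injected),
        minority_share_before=share_before,
        minority_share_after=share_after,
        majority_baseline=majority,
        report=report,
        control_report=control_report,
        control_majority_baseline=control_majority,
        minority_recall=minority_recall,
        control_minority_recall=control_recall,
        pipeline_seconds=pipeline_seconds,
        control_seconds=control_seconds,
        history=history,
    )
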