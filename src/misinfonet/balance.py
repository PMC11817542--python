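"""Cosine-similarity augmentation of the minority "trustworthy" class.

The minority class is enlarged by scoring unlabeled candidate documents
against a small verified seed set of trustworthy documents: each candidate's
score is its maximum TF-IDF cosine similarity to any seed, a similarity
threshold is calibrated on verified documents by precision (the fraction of
documents exceeding the threshold whose verified label is trustworthy), and
every candidate scoring strictly above the chosen threshold is injected into
the corpus with the trustworthy label and an ``injected`` provenance flag.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import TRUSTWORTHY, Document
from .preprocess import TokenSequence

#: Candidate similarity thresholds examined during calibration.
DEFAULT_THRESHOLD_GRID = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4)


def _token_analyzer(ts) -> list[str]:
    """Pass cleaned tokens through unchanged (picklable, unlike a lambda)."""
    return list(ts.tokens) if isinstance(ts, TokenSequence) else str(ts).split()


def make_tfidf(token_sequences: Sequence[TokenSequence]) -> TfidfVectorizer:
    """Fit the shared smoothed TF-IDF scheme over cleaned unigrams.

    Tokens are already cleaned, so the analyzer is a plain whitespace split
    with no further lowercasing or token filtering.
    """
    if not token_sequences:
        raise ValueError("cannot fit TF-IDF on an empty corpus")
    vec = TfidfVectorizer(
        analyzer=_token_analyzer,
        smooth_idf=True,
        sublinear_tf=False,
        norm=None,
    )
    vec.fit(token_sequences)
    if not vec.vocabulary_:
        raise ValueError("corpus vocabulary is empty after cleaning")
    return vec


def doc_vector(tokens: TokenSequence, vectorizer: TfidfVectorizer) -> sp.csr_matrix:
    """Sparse nonnegative TF-IDF weight vector of one document."""
    return vectorizer.transform([tokens])


def cosine(u: sp.spmatrix | np.ndarray, v: sp.spmatrix | np.ndarray) -> float:
    """Cosine similarity of two nonnegative weight vectors, in [0, 1]."""
    u = np.asarray(u.todense()).ravel() if sp.issparse(u) else np.asarray(u, float).ravel()
    v = np.asarray(v.todense()).ravel() if sp.issparse(v) else np.asarray(v, float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for an empty (zero) document")
    return float(np.dot(u, v) / (nu * nv))


def similarity_to_seeds(
    doc: sp.spmatrix | np.ndarray,
    seeds: sp.spmatrix | np.ndarray,
    aggregation: Literal["max", "mean"] = "max",
) -> float:
    """Aggregate cosine similarity of one document to a seed set.

    ``max`` (default) scores a document by its nearest trustworthy example;
    ``mean`` averages over all seeds.
    """
    seeds_m = sp.csr_matrix(seeds) if not sp.issparse(seeds) else seeds.tocsr()
    if seeds_m.shape[0] == 0:
        raise ValueError("seed set is empty")
    sims = [cosine(doc, seeds_m[i]) for i in range(seeds_m.shape[0])]
    return max(sims) if aggregation == "max" else float(np.mean(sims))


def _batch_scores(
    docs: sp.spmatrix, seeds: sp.spmatrix, aggregation: str = "max"
) -> np.ndarray:
    """Vectorized similarity-to-seeds for a whole candidate matrix."""
    docs = sp.csr_matrix(docs)
    seeds = sp.csr_matrix(seeds)
    dn = np.asarray(np.sqrt(docs.multiply(docs).sum(axis=1))).ravel()
    sn = np.asarray(np.sqrt(seeds.multiply(seeds).sum(axis=1))).ravel()
    if (sn == 0).any():
        raise ValueError("seed set contains an empty (zero) document")
    sims = (docs @ seeds.T).toarray()
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = sims / np.outer(dn, sn)
    sims[dn == 0, :] = 0.0  # empty candidates are dissimilar to everything
    agg = sims.max(axis=1) if aggregation == "max" else sims.mean(axis=1)
    return np.clip(agg, 0.0, 1.0)


@dataclass
class SimilarityCalibration:
    """Per-threshold verified counts, precision, and the chosen threshold.

    ``true_counts[i]`` / ``false_counts[i]`` are the numbers of verified
    trustworthy / misinformation documents whose score strictly exceeds
    ``thresholds[i]``; ``precision[i] = true/(true+false)`` where defined
    (``nan`` marks empty cells).
    """

    thresholds: tuple[float, ...]
    true_counts: tuple[int, ...]
    false_counts: tuple[int, ...]
    precision: tuple[float, ...]
    chosen: float | None = None

    def as_rows(self) -> list[dict]:
        return [
            {
                "threshold": t,
                "true_count": tc,
                "false_count": fc,
                "precision": p,
                "chosen": t == self.chosen,
            }
            for t, tc, fc, p in zip(
                self.thresholds, self.true_counts, self.false_counts, self.precision
            )
        ]

    def write_csv(self, path: str | Path) -> None:
        rows = self.as_rows()
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)


def calibrate_threshold(
    scored_verified: Sequence[tuple[float, str]],
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    min_injected: int = 1,
) -> SimilarityCalibration:
    """Tally verified documents above each threshold and pick by precision.

    For each threshold ``t`` count verified documents with score > t split by
    verified label; precision is the trustworthy fraction. The chosen
    threshold maximizes precision, ties broken toward the threshold injecting
    more verified-trustworthy documents, then toward the smaller threshold
    (which maximizes actual injection), subject to at least ``min_injected``
    trustworthy documents above it. Thresholds with no documents above them
    are excluded from the argmax.
    """
    thresholds = tuple(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    for _, label in scored_verified:
        if label not in (TRUSTWORTHY, "misinformation"):
            raise ValueError(f"verified label must be binary, got {label!r}")
    true_counts, false_counts, precisions = [], [], []
    for t in thresholds:
        tc = sum(1 for s, lab in scored_verified if s > t and lab == TRUSTWORTHY)
        fc = sum(1 for s, lab in scored_verified if s > t and lab != TRUSTWORTHY)
        true_counts.append(tc)
        false_counts.append(fc)
        precisions.append(tc / (tc + fc) if tc + fc > 0 else math.nan)
    candidates = [
        (p, tc, t)
        for t, tc, fc, p in zip(thresholds, true_counts, false_counts, precisions)
        if not math.isnan(p) and tc >= min_injected
    ]
    if candidates:
        chosen = max(candidates, key=lambda c: (c[0], c[1], -c[2]))[2]
    else:
        chosen = None
        warnings.warn(
            "no verified document exceeds any candidate threshold; "
            "calibration left without a chosen threshold",
            stacklevel=2,
        )
    return SimilarityCalibration(
        thresholds=thresholds,
        true_counts=tuple(true_counts),
        false_counts=tuple(false_counts),
        precision=tuple(precisions),
        chosen=chosen,
    )


@dataclass
class InjectionReport:
    """Ids and scores of injected candidates, plus skipped duplicates."""

    threshold: float
    injected: list[tuple[str, float]] = field(default_factory=list)
    skipped_existing: list[str] = field(default_factory=list)

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for doc_id, score in self.injected:
                fh.write(json.dumps({"id": doc_id, "score": score}) + "\n")


def inject_trustworthy(
    corpus: Sequence[Document],
    candidates: Sequence[tuple[Document, float]],
    threshold: float,
) -> tuple[list[Document], InjectionReport]:
    """Append candidates scoring strictly above ``threshold`` as trustworthy.

    Pre-existing documents are never altered, removed or relabeled;
    candidates whose id is already present are skipped and logged. A
    threshold of 1 or more is allowed and injects nothing (cosine scores
    never exceed 1).
    """
    if threshold <= 0.0:
        raise ValueError("threshold must be positive")
    existing = {d.id for d in corpus}
    out = list(corpus)
    report = InjectionReport(threshold=threshold)
    for doc, score in candidates:
        if score <= threshold:
            continue
        if doc.id in existing:
            report.skipped_existing.append(doc.id)
            continue
        out.append(replace(doc, label=TRUSTWORTHY, injected=True))
        existing.add(doc.id)
        report.injected.append((doc.id, float(score)))
    return out, report


class CosineSimilarityAugmenter(BaseEstimator):
    """Calibrated cosine-similarity injection of minority-class candidates.

    Fit on cleaned token sequences: verified seed documents with binary
    trust labels calibrate the similarity threshold; transform then scores
    candidate documents against the trustworthy seeds and injects those
    exceeding the threshold into a corpus.

    Parameters
    ----------
    thresholds : sequence of float
        Strictly increasing candidate threshold grid.
    aggregation : {"max", "mean"}
        How a document's similarities to individual seeds are combined.
    min_injected : int
        Smallest verified-trustworthy count a threshold needs to be eligible.
    threshold : float or None
        Fixed threshold; when set, calibration is skipped.

    Attributes
    ----------
    vectorizer_ : TfidfVectorizer
        Shared TF-IDF scheme fitted over corpus + seeds + candidates.
    calibration_ : SimilarityCalibration
        Per-threshold tallies (absent when ``threshold`` was fixed).
    threshold_ : float
        The operating threshold.
    """

    def __init__(
        self,
        thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
        aggregation: Literal["max", "mean"] = "max",
        min_injected: int = 1,
        threshold: float | None = None,
    ):
        self.thresholds = thresholds
        self.aggregation = aggregation
        self.min_injected = min_injected
        self.threshold = threshold

    def fit(
        self,
        corpus_tokens: Sequence[TokenSequence],
        verified: Sequence[tuple[TokenSequence, str]] | None = None,
    ) -> "CosineSimilarityAugmenter":
        all_tokens = list(corpus_tokens) + [ts for ts, _ in (verified or [])]
        self.vectorizer_ = make_tfidf(all_tokens)
        seeds = [ts for ts, lab in (verified or []) if lab == TRUSTWORTHY]
        if not seeds:
            raise ValueError("fit requires at least one verified trustworthy seed")
        self.seed_matrix_ = self.vectorizer_.transform(seeds)
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
        else:
            scores = _batch_scores(
                self.vectorizer_.transform([ts for ts, _ in verified]),
                self.seed_matrix_,
                self.aggregation,
            )
            scored = list(zip(scores.tolist(), [lab for _, lab in verified]))
            self.calibration_ = calibrate_threshold(
                scored, self.thresholds, self.min_injected
            )
            if self.calibration_.chosen is None:
                raise ValueError("calibration produced no usable threshold")
            self.threshold_ = self.calibration_.chosen
        return self

    def score_candidates(
        self, candidate_tokens: Sequence[TokenSequence]
    ) -> np.ndarray:
        if not candidate_tokens:
            return np.zeros(0)
        return _batch_scores(
            self.vectorizer_.transform(candidate_tokens),
            self.seed_matrix_,
            self.aggregation,
        )

    def transform(
        self,
        corpus: Sequence[Document],
        candidates: Sequence[Document],
        candidate_tokens: Sequence[TokenSequence],
    ) -> tuple[list[Document], InjectionReport]:
        """Inject qualifying candidates into ``corpus``; returns (corpus, report)."""
        scores = self.score_candidates(candidate_tokens)
        return inject_trustworthy(
            corpus, list(zip(candidates, scores.tolist())), self.threshold_
        )
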