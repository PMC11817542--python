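"""Synthetic tweet-like corpora with controlled class structure.

The generator emulates the statistical features the analysis pipeline
relies on — short documents (<= 40 tokens), two topically separated classes
with a shared background vocabulary, configurable class imbalance and label
noise — without modeling real language. Tokens are synthetic alphabetic
word-like strings (``wabcd``) disjoint from the stop-word list and immune
to the cleaning cascade, so pipeline behavior is isolated from linguistic
artifacts. Class sizes follow the configured
fractions exactly (deterministic allocation), and everything is reproducible
bit-for-bit from the seed.

The verified seed-set generator stands in for a small fact-checked sample
(by default 250 documents: 180 trustworthy, 70 misinformation) together with
an unlabeled candidate pool carrying hidden ground truth, so that threshold
calibration and injection can be tested against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .corpus import MISINFORMATION, TRUSTWORTHY, UNLABELED, Document

_PUNCT_BURSTS = ("!!!", "???", "...", "!?", "#", "@@")


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    Parameters
    ----------
    n_docs : int
        Corpus size.
    minority_fraction : float in (0, 0.5]
        Exact share of trustworthy (minority) documents.
    vocab_size_per_class : int
        Number of class-specific word types per class.
    shared_vocab_size : int
        Number of background word types common to both classes.
    doc_length_range : (int, int)
        Inclusive token-count range per document; max <= 40 (tweet-scale).
    topic_purity : float in [0, 1]
        Probability a token is drawn from the class vocabulary rather than
        the background; 0 makes classes indistinguishable.
    cross_topic_rate : float in [0, 1]
        Share of the background (non-pure) token mass drawn from the *other*
        class's vocabulary instead of the shared one. Real fact-checked
        streams contain misinformation that quotes trustworthy wording; this
        leakage makes class-conditional similarity distributions overlap, so
        threshold calibration sees declining false-positive counts across
        the grid instead of a degenerate all-or-nothing split.
    label_noise : float in [0, 0.5)
        Exact fraction of observed labels flipped (ground truth retained).
    seed : int
        Seed controlling every random draw.
    duplicate_fraction, numeric_token_rate, punctuation_burst_rate : float
        Optional noise switches (off by default) exercising the cleaning
        rules: appended duplicate documents, inserted digit tokens, and
        punctuation bursts glued onto tokens.
    """

    n_docs: int = 2000
    minority_fraction: float = 0.15
    vocab_size_per_class: int = 300
    shared_vocab_size: int = 200
    doc_length_range: tuple[int, int] = (8, 30)
    topic_purity: float = 0.9
    cross_topic_rate: float = 0.2
    label_noise: float = 0.0
    seed: int = 0
    duplicate_fraction: float = 0.0
    numeric_token_rate: float = 0.0
    punctuation_burst_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be positive")
        if not (0 < self.minority_fraction <= 0.5):
            raise ValueError("minority_fraction must lie in (0, 0.5]")
        lo, hi = self.doc_length_range
        if not (1 <= lo <= hi <= 40):
            raise ValueError("doc_length_range must satisfy 1 <= min <= max <= 40")
        if not (0 <= self.topic_purity <= 1):
            raise ValueError("topic_purity must lie in [0, 1]")
        if not (0 <= self.cross_topic_rate <= 1):
            raise ValueError("cross_topic_rate must lie in [0, 1]")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.vocab_size_per_class < 1:
            raise ValueError("vocab_size_per_class must be positive")


def _word(i: int) -> str:
    """Synthetic alphabetic word: survives cleaning (no digits, length > 1)."""
    letters = []
    for _ in range(4):
        letters.append(chr(ord("a") + i % 26))
        i //= 26
    return "w" + "".join(reversed(letters))


def _vocab(spec: CorpusSpec) -> tuple[list[str], list[str], list[str]]:
    v, s = spec.vocab_size_per_class, spec.shared_vocab_size
    words = [_word(i) for i in range(2 * v + s)]
    return words[:v], words[v : 2 * v], words[2 * v :]


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / (np.arange(n) + 2.0)  # mild Zipf-like frequency skew
    return w / w.sum()


def _sample_doc(
    rng: np.random.Generator,
    spec: CorpusSpec,
    class_vocab: Sequence[str],
    shared_vocab: Sequence[str],
    other_vocab: Sequence[str] = (),
) -> str:
    lo, hi = spec.doc_length_range
    length = int(rng.integers(lo, hi + 1))
    cw = _zipf_weights(len(class_vocab))
    tokens: list[str] = []
    for _ in range(length):
        r = rng.random()
        if r < spec.topic_purity or (not other_vocab and spec.shared_vocab_size == 0):
            tokens.append(class_vocab[int(rng.choice(len(class_vocab), p=cw))])
        elif other_vocab and rng.random() < spec.cross_topic_rate:
            ow = _zipf_weights(len(other_vocab))
            tokens.append(other_vocab[int(rng.choice(len(other_vocab), p=ow))])
        elif spec.shared_vocab_size > 0:
            tokens.append(shared_vocab[int(rng.integers(len(shared_vocab)))])
        else:
            tokens.append(class_vocab[int(rng.choice(len(class_vocab), p=cw))])
        if spec.numeric_token_rate > 0 and rng.random() < spec.numeric_token_rate:
            tokens.append(str(int(rng.integers(0, 10000))))
        if spec.punctuation_burst_rate > 0 and rng.random() < spec.punctuation_burst_rate:
            tokens[-1] = tokens[-1] + _PUNCT_BURSTS[int(rng.integers(len(_PUNCT_BURSTS)))]
    return " ".join(tokens)


def generate_corpus(
    spec: CorpusSpec,
) -> tuple[list[Document], dict[str, str]]:
    """Generate a labeled corpus plus its ground-truth record.

    Returns ``(documents, ground_truth)`` where ``ground_truth`` maps id to
    the true class even when ``label_noise`` flipped the observed label.
    Class allocation is exact: ``round(n_docs * minority_fraction)``
    documents are trustworthy.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    trust_vocab, mis_vocab, shared_vocab = _vocab(spec)
    n_minority = int(round(spec.n_docs * spec.minority_fraction))
    truth_labels = [TRUSTWORTHY] * n_minority + [MISINFORMATION] * (
        spec.n_docs - n_minority
    )
    order = rng.permutation(spec.n_docs)
    docs: list[Document] = []
    ground_truth: dict[str, str] = {}
    for i, idx in enumerate(order):
        true_label = truth_labels[idx]
        own = true_label == TRUSTWORTHY
        vocab = trust_vocab if own else mis_vocab
        other = mis_vocab if own else trust_vocab
        text = _sample_doc(rng, spec, vocab, shared_vocab, other)
        doc_id = f"syn-{i:06d}"
        docs.append(
            Document(id=doc_id, text=text, raw_label=true_label, label=true_label,
                     source="synthetic")
        )
        ground_truth[doc_id] = true_label

    n_flip = int(round(spec.label_noise * spec.n_docs))
    if n_flip:
        flip_idx = rng.choice(spec.n_docs, size=n_flip, replace=False)
        for j in flip_idx:
            d = docs[j]
            flipped = MISINFORMATION if d.label == TRUSTWORTHY else TRUSTWORTHY
            docs[j] = replace(d, label=flipped)

    if spec.duplicate_fraction > 0:
        n_dup = int(round(spec.duplicate_fraction * spec.n_docs))
        dup_idx = rng.choice(spec.n_docs, size=n_dup, replace=True)
        for k, j in enumerate(dup_idx):
            d = docs[j]
            doc_id = f"syn-dup-{k:06d}"
            docs.append(replace(d, id=doc_id))
            ground_truth[doc_id] = ground_truth[d.id]
    return docs, ground_truth


def generate_seed_sets(
    spec: CorpusSpec,
    n_verified: int = 250,
    verified_split: tuple[int, int] = (180, 70),
    pool_size: int = 1500,
    pool_trust_fraction: float = 2 / 3,
) -> tuple[list[Document], list[Document], dict[str, str]]:
    """Generate a verified seed sample and an unlabeled candidate pool.

    Returns ``(verified, pool, pool_truth)``: ``verified`` documents carry
    their trust labels (``verified_split = (true_count, false_count)`` must
    sum to ``n_verified``); ``pool`` documents are unlabeled, with hidden
    ground truth in ``pool_truth`` for calibration-recovery tests.
    """
    n_true, n_false = verified_split
    if n_true + n_false > n_verified:
        raise ValueError(
            f"verified_split {verified_split} exceeds n_verified={n_verified}"
        )
    if n_true + n_false < n_verified:
        raise ValueError(
            f"verified_split {verified_split} does not cover n_verified={n_verified}"
        )
    if n_true < 1:
        raise ValueError("at least one verified trustworthy seed is required")
    rng = np.random.Generator(np.random.PCG64(spec.seed + 1))
    trust_vocab, mis_vocab, shared_vocab = _vocab(spec)

    verified: list[Document] = []
    for i in range(n_true + n_false):
        label = TRUSTWORTHY if i < n_true else MISINFORMATION
        own = label == TRUSTWORTHY
        vocab = trust_vocab if own else mis_vocab
        other = mis_vocab if own else trust_vocab
        verified.append(
            Document(
                id=f"seed-{i:04d}",
                text=_sample_doc(rng, spec, vocab, shared_vocab, other),
                raw_label=label,
                label=label,
                source="verified",
            )
        )

    n_pool_trust = int(round(pool_size * pool_trust_fraction))
    pool: list[Document] = []
    pool_truth: dict[str, str] = {}
    order = rng.permutation(pool_size)
    for i, idx in enumerate(order):
        true_label = TRUSTWORTHY if idx < n_pool_trust else MISINFORMATION
        own = true_label == TRUSTWORTHY
        vocab = trust_vocab if own else mis_vocab
        other = mis_vocab if own else trust_vocab
        doc_id = f"cand-{i:05d}"
        pool.append(
            Document(
                id=doc_id,
                text=_sample_doc(rng, spec, vocab, shared_vocab, other),
                label=UNLABELED,
                source="candidate-pool",
            )
        )
        pool_truth[doc_id] = true_label
    return verified, pool, pool_truth
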