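"""Word vectors and fixed-shape document embedding matrices.

A document is represented to the convolutional classifier as a
``max_tokens x dimension`` matrix (default 100 x 100): row *i* holds the
vector of token *i*, rows past the end of the document are zero, and tokens
past ``max_tokens`` are ignored. Vectors come either from a pre-trained
GloVe/word2vec plain-text file or from a seeded hashing provider that needs
no download and is bit-reproducible across machines.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import TokenSequence


class EmbeddingProvider:
    """Deterministic word -> fixed-dimension vector lookup."""

    dimension: int

    def vector(self, word: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class TableProvider(EmbeddingProvider):
    """Lookup backed by an explicit table; out-of-vocabulary words are zero."""

    dimension: int
    table: Mapping[str, np.ndarray]

    def vector(self, word: str) -> np.ndarray:
        vec = self.table.get(word)
        if vec is None:
            return np.zeros(self.dimension, dtype=np.float32)
        return vec


def load_vectors(path: str | Path) -> TableProvider:
    """Read GloVe/word2vec plain-text vectors (token then D floats per line).

    A leading word2vec header line ("<count> <dim>") is tolerated and
    skipped. Inconsistent row widths raise with the offending line number.
    """
    path = Path(path)
    table: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if not line.strip():
                continue
            if lineno == 1 and len(parts) == 2:
                try:  # word2vec-style header
                    int(parts[0]), int(parts[1])
                    continue
                except ValueError:
                    pass
            word, values = parts[0], parts[1:]
            try:
                vec = np.asarray([float(v) for v in values], dtype=np.float32)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric vector entry") from exc
            if dim is None:
                dim = len(vec)
                if dim == 0:
                    raise ValueError(f"{path}:{lineno}: row has no vector values")
            elif len(vec) != dim:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} values, found {len(vec)}"
                )
            table[word] = vec
    if dim is None:
        raise ValueError(f"{path}: no vectors found")
    return TableProvider(dimension=dim, table=table)


@dataclass
class HashingProvider(EmbeddingProvider):
    """Seeded hash of each word to a unit-norm pseudo-random vector.

    The word together with the seed keys a BLAKE2 digest that seeds a local
    PCG64 generator, so the same (word, seed) pair yields the same vector on
    every machine and in every process, with no stored vocabulary.
    """

    dimension: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self._cache: dict[str, np.ndarray] = {}

    def vector(self, word: str) -> np.ndarray:
        cached = self._cache.get(word)
        if cached is not None:
            return cached
        digest = hashlib.blake2b(
            word.encode("utf-8"), digest_size=8, key=str(self.seed).encode()
        ).digest()
        rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest, "little")))
        vec = rng.standard_normal(self.dimension)
        vec /= np.linalg.norm(vec)  # float64: unit norm to ~1e-15
        self._cache[word] = vec
        return vec


def hash_provider(dimension: int = 100, seed: int = 0) -> HashingProvider:
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    return HashingProvider(dimension=dimension, seed=seed)


def build_matrix(
    tokens: TokenSequence | Sequence[str],
    provider: EmbeddingProvider,
    max_tokens: int = 100,
    dimension: int | None = None,
) -> np.ndarray:
    """Stack token vectors into a fixed ``max_tokens x dimension`` matrix.

    Row *i* (for ``i < min(len(tokens), max_tokens)``) is the vector of token
    *i*; all remaining rows are zero. ``dimension``, when given, must match
    the provider's.
    """
    if dimension is not None and dimension != provider.dimension:
        raise ValueError(
            f"provider dimension {provider.dimension} != requested {dimension}"
        )
    toks = tokens.tokens if isinstance(tokens, TokenSequence) else tuple(tokens)
    out = np.zeros((max_tokens, provider.dimension), dtype=np.float32)
    for i, tok in enumerate(toks[:max_tokens]):
        out[i] = provider.vector(tok)
    return out


class DocumentMatrixVectorizer(BaseEstimator, TransformerMixin):
    """Transform token sequences into stacked document embedding matrices.

    Parameters
    ----------
    provider : EmbeddingProvider, optional
        Word-vector source; defaults to a seeded :class:`HashingProvider`.
    max_tokens : int
        Number of leading tokens represented per document (matrix height).
    dimension : int
        Vector length per word (matrix width); must equal the provider's.
    seed : int
        Seed for the default hashing provider.

    ``transform`` returns an array of shape ``(n_docs, max_tokens, dimension)``.
    """

    def __init__(
        self,
        provider: EmbeddingProvider | None = None,
        max_tokens: int = 100,
        dimension: int = 100,
        seed: int = 0,
    ):
        self.provider = provider
        self.max_tokens = max_tokens
        self.dimension = dimension
        self.seed = seed

    def fit(self, X: Iterable[TokenSequence], y=None) -> "DocumentMatrixVectorizer":
        provider = self.provider or hash_provider(self.dimension, self.seed)
        if provider.dimension != self.dimension:
            raise ValueError(
                f"provider dimension {provider.dimension} != configured {self.dimension}"
            )
        self.provider_ = provider
        return self

    def transform(self, X: Iterable[TokenSequence]) -> np.ndarray:
        if not hasattr(self, "provider_"):
            self.fit(X)
        mats = [
            build_matrix(ts, self.provider_, max_tokens=self.max_tokens) for ts in X
        ]
        if not mats:
            return np.zeros((0, self.max_tokens, self.dimension), dtype=np.float32)
        return np.stack(mats)
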