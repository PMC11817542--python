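"""Text cleaning, tokenization and duplicate removal for tweet-like corpora.

Cleaning applies a fixed ordered cascade: strip URLs and @-mentions,
lowercase, replace punctuation by spaces, strip digits character-wise,
whitespace-tokenize, drop stop words, drop single-character tokens. The
cascade is idempotent, so cleaned text passed through again is unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Document

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")


def _strip_nonletters(text: str) -> str:
    """Punctuation becomes a space (keeps word boundaries in hashtags and
    hyphenations, so "covid-19" yields "covid", not "covid19"); digit
    characters — Unicode-aware — are deleted in place."""
    out = []
    for c in text:
        if c.isalpha() or c.isspace():
            out.append(c)
        elif c.isdigit() or c.isnumeric():
            continue
        else:
            out.append(" ")
    return "".join(out)


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stop-word list (one word per line, UTF-8).

    With no path, the standard English list shipped with the package is used.
    """
    if path is None:
        ref = resources.files("misinfonet").joinpath("data/stopwords_en.txt")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


DEFAULT_STOPWORDS = load_stopwords()


@dataclass(frozen=True)
class TokenSequence:
    """Ordered cleaned tokens of one document.

    Invariants: no token is empty, purely numeric, a single character, or a
    member of the active stop-word list.
    """

    doc_id: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


def clean_text(text: str, stopwords: frozenset[str] | None = None) -> str:
    """Clean one raw text into space-separated lowercase alphabetic tokens.

    Steps, in order: remove URLs/@-mentions, lowercase, punctuation->space,
    remove digit characters, split on whitespace, drop stop words, drop
    single-character tokens.
    """
    if stopwords is None:
        stopwords = DEFAULT_STOPWORDS
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    text = text.lower()
    text = _strip_nonletters(text)
    kept = [
        tok
        for tok in text.split()
        if len(tok) > 1 and tok not in stopwords
    ]
    return " ".join(kept)


def tokenize(cleaned: str, doc_id: str = "") -> TokenSequence:
    """Whitespace-split an already-cleaned string, preserving order."""
    return TokenSequence(doc_id=doc_id, tokens=tuple(cleaned.split()))


def clean_and_tokenize(
    doc: Document, stopwords: frozenset[str] | None = None
) -> TokenSequence:
    return tokenize(clean_text(doc.text, stopwords), doc_id=doc.id)


def deduplicate(
    docs: Sequence[Document], stopwords: frozenset[str] | None = None
) -> list[Document]:
    """Drop documents whose cleaned text duplicates an earlier document's.

    The first occurrence (input order) wins. Documents cleaning to the empty
    string are all treated as duplicates of the first empty one.
    """
    seen: set[str] = set()
    kept: list[Document] = []
    for d in docs:
        key = clean_text(d.text, stopwords)
        if key not in seen:
            seen.add(key)
            kept.append(d)
    return kept


def clean_corpus(
    docs: Iterable[Document], stopwords: frozenset[str] | None = None
) -> list[TokenSequence]:
    """Clean and tokenize every document, preserving corpus order."""
    return [clean_and_tokenize(d, stopwords) for d in docs]
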