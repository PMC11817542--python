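"""Reading, harmonizing, merging and writing labeled short-text corpora.

A corpus is a list of :class:`Document`. Raw source labels are kept verbatim;
the canonical label takes one of three values: ``trustworthy``,
``misinformation`` or ``unlabeled``. Mapping from heterogeneous source labels
to the two supervised classes is driven by per-dataset :class:`LabelMap`
config files so that evolving upstream datasets only require editing data,
not code.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

TRUSTWORTHY = "trustworthy"
MISINFORMATION = "misinformation"
UNLABELED = "unlabeled"
CANONICAL_LABELS = (TRUSTWORTHY, MISINFORMATION, UNLABELED)

_FIELDS = ("id", "text", "raw_label", "label", "source")


class CorpusFormatError(ValueError):
    """A corpus file violates the record contract (missing/duplicate ids...)."""


@dataclass(frozen=True)
class Document:
    """One short text with identity, labels and provenance.

    Attributes
    ----------
    id : str
        Non-empty identifier, unique within a corpus.
    text : str
        The document body (e.g. a tweet), unmodified.
    raw_label : str
        The label string exactly as the source dataset provided it
        (empty when the source is unlabeled).
    label : str
        Canonical label: ``trustworthy``, ``misinformation`` or ``unlabeled``.
    source : str
        Tag of the originating dataset.
    injected : bool
        True when the document was added by similarity-based augmentation
        rather than present in the source data.
    """

    id: str
    text: str
    raw_label: str = ""
    label: str = UNLABELED
    source: str = ""
    injected: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Document id must be non-empty")
        if self.label not in CANONICAL_LABELS:
            raise ValueError(
                f"label must be one of {CANONICAL_LABELS}, got {self.label!r}"
            )


def _canon(s: str) -> str:
    return " ".join(s.strip().lower().split())


@dataclass(frozen=True)
class LabelMap:
    """Disjoint sets of source-label strings mapping to the two classes.

    Matching is case-insensitive after whitespace normalization.
    """

    trustworthy_set: frozenset[str]
    misinformation_set: frozenset[str]

    def __post_init__(self) -> None:
        t = frozenset(_canon(s) for s in self.trustworthy_set)
        m = frozenset(_canon(s) for s in self.misinformation_set)
        if t & m:
            raise ValueError(f"label sets overlap on {sorted(t & m)}")
        object.__setattr__(self, "trustworthy_set", t)
        object.__setattr__(self, "misinformation_set", m)

    @classmethod
    def from_file(cls, path: str | Path) -> "LabelMap":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            trustworthy_set=frozenset(data.get("trustworthy_set") or ()),
            misinformation_set=frozenset(data.get("misinformation_set") or ()),
        )

    def resolve(self, raw_label: str) -> str:
        key = _canon(raw_label)
        if key and key in self.trustworthy_set:
            return TRUSTWORTHY
        if key and key in self.misinformation_set:
            return MISINFORMATION
        return UNLABELED


def bundled_label_map(dataset: str) -> LabelMap:
    """Load one of the label maps shipped with the package.

    Available names: facov, fakecovid, checkcovid, esoc, who_mythbusters,
    healthfeedback, lopez_gallemore.
    """
    ref = resources.files("misinfonet").joinpath(f"data/label_maps/{dataset}.yaml")
    with resources.as_file(ref) as path:
        return LabelMap.from_file(path)


def read_corpus(path: str | Path, format: str = "delimited") -> list[Document]:
    """Read a corpus from CSV (``delimited``) or JSON-lines (``record-per-line``).

    Records need at least ``id`` and ``text``; other fields default.
    Unknown canonical labels and missing/duplicate ids are rejected with the
    offending record identified by line number.
    """
    path = Path(path)
    docs: list[Document] = []
    seen: dict[str, int] = {}

    def add(rec: Mapping[str, object], lineno: int) -> None:
        rid = str(rec.get("id") or "")
        if not rid:
            raise CorpusFormatError(f"{path}:{lineno}: record has no id")
        if rid in seen:
            raise CorpusFormatError(
                f"{path}:{lineno}: duplicate id {rid!r} (first seen on line {seen[rid]})"
            )
        if "text" not in rec or rec["text"] is None:
            raise CorpusFormatError(f"{path}:{lineno}: record {rid!r} has no text")
        seen[rid] = lineno
        docs.append(
            Document(
                id=rid,
                text=str(rec["text"]),
                raw_label=str(rec.get("raw_label") or ""),
                label=str(rec.get("label") or UNLABELED),
                source=str(rec.get("source") or ""),
                injected=bool(rec.get("injected", False)),
            )
        )

    if format == "delimited":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            for i, row in enumerate(reader, start=2):
                add(row, i)
    elif format == "record-per-line":
        with open(path, "r", encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{i}: malformed JSON: {exc}") from exc
                add(rec, i)
    else:
        raise ValueError(f"unknown format {format!r}")
    return docs


def write_corpus(docs: Sequence[Document], path: str | Path, format: str = "delimited") -> None:
    """Write a corpus as CSV or JSON-lines; round-trips exactly via read_corpus."""
    path = Path(path)
    if format == "delimited":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_FIELDS) + ["injected"])
            writer.writeheader()
            for d in docs:
                row = {f: getattr(d, f) for f in _FIELDS}
                row["injected"] = "true" if d.injected else ""
                writer.writerow(row)
    elif format == "record-per-line":
        with open(path, "w", encoding="utf-8") as fh:
            for d in docs:
                rec = {f: getattr(d, f) for f in _FIELDS}
                rec["injected"] = d.injected
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def normalize_labels(doc: Document, label_map: LabelMap) -> Document:
    """Map a document's raw source label onto the canonical binary label.

    Unmapped raw labels yield ``unlabeled`` (the record is retained but is
    excluded from supervised use); this is idempotent.
    """
    return replace(doc, label=label_map.resolve(doc.raw_label))


def normalize_corpus(docs: Iterable[Document], label_map: LabelMap) -> list[Document]:
    return [normalize_labels(d, label_map) for d in docs]


@dataclass
class MergeSummary:
    """Per-source and per-label document counts after a merge."""

    total: int = 0
    by_source: dict[str, int] = field(default_factory=dict)
    by_label: dict[str, int] = field(default_factory=dict)


def merge_corpora(
    corpora: Mapping[str, Sequence[Document]] | Sequence[Sequence[Document]],
) -> tuple[list[Document], MergeSummary]:
    """Pool several corpora into one, prefixing ids with their source tag.

    ``corpora`` maps source tag -> documents (a plain sequence uses each
    corpus's position as its tag). Ids must be unique after prefixing.
    Returns the merged corpus and a :class:`MergeSummary`.
    """
    if not isinstance(corpora, Mapping):
        corpora = {str(i): c for i, c in enumerate(corpora)}
    merged: list[Document] = []
    seen: set[str] = set()
    summary = MergeSummary()
    for tag, docs in corpora.items():
        for d in docs:
            new_id = f"{tag}:{d.id}"
            if new_id in seen:
                raise CorpusFormatError(f"id collision after prefixing: {new_id!r}")
            seen.add(new_id)
            merged.append(replace(d, id=new_id, source=d.source or tag))
            summary.by_source[tag] = summary.by_source.get(tag, 0) + 1
            summary.by_label[d.label] = summary.by_label.get(d.label, 0) + 1
    summary.total = len(merged)
    return merged, summary
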