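"""Read annotated corpora and build the filtered concept vocabulary.

A corpus is a UTF-8 JSON-lines file, one document per line::

    {"doc_id": "d1", "source": "forum",
     "mentions": [{"concept_id": "C0003467", "name": "Anxiety",
                   "semantic_types": ["finding"], "score": 0.92}, ...]}

Documents are the unit of context throughout the pipeline: a concept
"occurs" in a document if at least one of its mentions survives the
linker-score cutoff, and repeated mentions within one document count once.
The vocabulary keeps concepts whose first-listed semantic type is on a
configurable allowlist and that occur in at least ``min_doc_count``
documents; the condition concepts (the anchor of every downstream graph)
bypass the type and count filters so they always survive.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import (
    ConditionAbsentError,
    ConfigError,
    CorpusFormatError,
    EmptyCorpusError,
    EmptyVocabularyError,
)

__all__ = [
    "ConceptMention",
    "AnnotatedDocument",
    "FilterConfig",
    "VocabEntry",
    "ConceptVocabulary",
    "default_semantic_types",
    "normalize_type",
    "read_annotated_corpus",
    "write_annotated_corpus",
    "filter_condition_documents",
    "build_vocabulary",
]

_WS = re.compile(r"\s+")


def normalize_type(name: str) -> str:
    """Canonical form of a semantic-type name: lowercase, single spaces,
    en/em dashes folded to hyphens."""
    return _WS.sub(" ", name.replace("–", "-").replace("—", "-")).strip().lower()


def default_semantic_types() -> frozenset[str]:
    """The packaged 26-type allowlist of disorder-relevant semantic types."""
    text = resources.files("conceptkg.data").joinpath("semantic_types.txt").read_text("utf-8")
    return frozenset(
        normalize_type(line)
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )


@dataclass(frozen=True)
class ConceptMention:
    """One linked concept occurrence in a document."""

    concept_id: str
    name: str
    semantic_types: tuple[str, ...]
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise CorpusFormatError(
                f"mention {self.concept_id!r}: score {self.score} outside [0, 1]"
            )
        if not self.semantic_types:
            raise CorpusFormatError(f"mention {self.concept_id!r}: empty semantic_types")


@dataclass(frozen=True)
class AnnotatedDocument:
    """A document reduced to its concept mentions; the co-occurrence context."""

    doc_id: str
    source: str
    mentions: tuple[ConceptMention, ...]


@dataclass(frozen=True)
class FilterConfig:
    """Concept- and document-filter settings.

    score_cutoff
        Mentions with linker score <= cutoff are discarded (strictly
        "greater than" semantics). Default 0.7.
    min_doc_count
        Minimum number of distinct documents a concept must occur in.
        Default 10.
    allowed_semantic_types
        Allowlist applied to each concept's first-listed type; ``None``
        means the packaged 26-type default.
    condition_merge_map
        Synonym concept ids rewritten to the canonical condition id before
        document filtering (e.g. Asperger syndrome -> ASD).
    condition_ids
        Canonical condition concept ids; documents not mentioning any of
        them are dropped, and these concepts bypass type/count filters.
    condition_labels
        Optional display name per condition id, used when synonym merging
        makes the first-seen mention name misleading.
    blocklist
        Concept ids removed outright (stands in for manual false-positive
        review).
    """

    score_cutoff: float = 0.7
    min_doc_count: int = 10
    allowed_semantic_types: frozenset[str] | None = None
    condition_merge_map: Mapping[str, str] = field(default_factory=dict)
    condition_ids: frozenset[str] = frozenset()
    condition_labels: Mapping[str, str] = field(default_factory=dict)
    blocklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 <= self.score_cutoff <= 1.0):
            raise ConfigError(f"score_cutoff {self.score_cutoff} outside [0, 1]")
        if self.min_doc_count < 1:
            raise ConfigError(f"min_doc_count {self.min_doc_count} < 1")
        clash = set(self.condition_ids) & set(self.blocklist)
        if clash:
            raise ConfigError(f"condition ids present in blocklist: {sorted(clash)}")

    @property
    def effective_types(self) -> frozenset[str]:
        if self.allowed_semantic_types is None:
            return default_semantic_types()
        return frozenset(normalize_type(t) for t in self.allowed_semantic_types)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        types = d.get("allowed_semantic_types")
        return cls(
            score_cutoff=float(d.get("score_cutoff", 0.7)),
            min_doc_count=int(d.get("min_doc_count", 10)),
            allowed_semantic_types=None if types is None else frozenset(types),
            condition_merge_map=dict(d.get("condition_merge_map", {})),
            condition_ids=frozenset(d.get("condition_ids", ())),
            condition_labels=dict(d.get("condition_labels", {})),
            blocklist=frozenset(d.get("blocklist", ())),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)


@dataclass(frozen=True)
class VocabEntry:
    concept_id: str
    name: str
    semantic_type: str
    index: int
    doc_count: int


@dataclass
class ConceptVocabulary:
    """Surviving concepts with dense 0-based indices.

    Indices are assigned by descending document count, ties broken by
    lexicographic concept id, so a vocabulary is a pure function of the
    filtered corpus. ``score_cutoff`` records the mention-level cutoff the
    counts were computed under; downstream occurrence counting reuses it so
    that co-occurrence diagonals equal these document counts.
    """

    entries: list[VocabEntry]
    score_cutoff: float
    condition_ids: frozenset[str]

    def __post_init__(self) -> None:
        by_id = {e.concept_id: e for e in self.entries}
        if len(by_id) != len(self.entries):
            raise ValueError("duplicate concept_id in vocabulary")
        self._by_id = by_id

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def concept_ids(self) -> list[str]:
        return [e.concept_id for e in self.entries]

    def index_of(self, concept_id: str) -> int:
        return self._by_id[concept_id].index

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._by_id

    def entry(self, concept_id: str) -> VocabEntry:
        return self._by_id[concept_id]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "index": e.index,
                    "concept_id": e.concept_id,
                    "name": e.name,
                    "semantic_type": e.semantic_type,
                    "doc_count": e.doc_count,
                }
                for e in self.entries
            ]
        )


def _parse_document(line: str, lineno: int, seen: set[str]) -> AnnotatedDocument:
    try:
        rec = json.loads(line)
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(f"line {lineno}: not valid JSON ({exc})") from exc
    try:
        doc_id = rec["doc_id"]
        source = rec.get("source", "")
        raw_mentions = rec["mentions"]
    except (KeyError, TypeError) as exc:
        raise CorpusFormatError(f"line {lineno}: missing doc_id/mentions field") from exc
    if doc_id in seen:
        raise CorpusFormatError(f"line {lineno}: duplicate doc_id {doc_id!r}")
    seen.add(doc_id)
    mentions = []
    for m in raw_mentions:
        try:
            mention = ConceptMention(
                concept_id=m["concept_id"],
                name=m.get("name", m["concept_id"]),
                semantic_types=tuple(m["semantic_types"]),
                score=float(m["score"]),
            )
        except CorpusFormatError as exc:
            raise CorpusFormatError(f"doc {doc_id!r}: {exc}") from exc
        except (KeyError, TypeError, ValueError) as exc:
            raise CorpusFormatError(f"doc {doc_id!r}: malformed mention record ({m!r})") from exc
        mentions.append(mention)
    return AnnotatedDocument(doc_id=doc_id, source=source, mentions=tuple(mentions))


def read_annotated_corpus(path: str | Path) -> list[AnnotatedDocument]:
    """Read a JSON-lines corpus, preserving file order.

    Malformed records raise :class:`CorpusFormatError` naming the offending
    document rather than being skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"corpus file not found: {path}")
    docs: list[AnnotatedDocument] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            docs.append(_parse_document(line, lineno, seen))
    return docs


def write_annotated_corpus(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    """Write documents in the same JSON-lines format ``read_annotated_corpus`` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec = {
                "doc_id": doc.doc_id,
                "source": doc.source,
                "mentions": [
                    {
                        "concept_id": m.concept_id,
                        "name": m.name,
                        "semantic_types": list(m.semantic_types),
                        "score": m.score,
                    }
                    for m in doc.mentions
                ],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def filter_condition_documents(
    docs: list[AnnotatedDocument], cfg: FilterConfig
) -> list[AnnotatedDocument]:
    """Merge condition synonyms, then keep only condition-mentioning documents.

    Synonym mentions (per ``cfg.condition_merge_map``) are rewritten to the
    canonical condition id *before* filtering, so a document that only
    mentions a synonym is retained. A document mentioning several conditions
    is retained once and counts toward each condition downstream.
    """
    if not cfg.condition_ids:
        raise ConfigError("condition_ids is empty; cannot filter documents")
    merge = cfg.condition_merge_map
    out: list[AnnotatedDocument] = []
    for doc in docs:
        if merge and any(m.concept_id in merge for m in doc.mentions):
            mentions = tuple(
                ConceptMention(
                    concept_id=merge.get(m.concept_id, m.concept_id),
                    name=cfg.condition_labels.get(merge[m.concept_id], m.name)
                    if m.concept_id in merge
                    else m.name,
                    semantic_types=m.semantic_types,
                    score=m.score,
                )
                for m in doc.mentions
            )
            doc = AnnotatedDocument(doc.doc_id, doc.source, mentions)
        if any(m.concept_id in cfg.condition_ids for m in doc.mentions):
            out.append(doc)
    return out


def build_vocabulary(docs: list[AnnotatedDocument], cfg: FilterConfig) -> ConceptVocabulary:
    """Apply the concept filters and assign vocabulary indices.

    Filter order: linker-score cutoff (strict ``>``), first-listed semantic
    type against the allowlist, blocklist, then the ``min_doc_count``
    document-frequency threshold computed over distinct documents. Condition
    concepts bypass the type and count filters. Raises if filtering empties
    the vocabulary or a condition occurs in no document.
    """
    if not docs:
        raise EmptyCorpusError("cannot build a vocabulary from zero documents")
    allowed = cfg.effective_types
    doc_count: dict[str, int] = {}
    first_name: dict[str, str] = {}
    first_type: dict[str, str] = {}
    for doc in docs:
        seen_here: set[str] = set()
        for m in doc.mentions:
            if m.score <= cfg.score_cutoff:
                continue
            cid = m.concept_id
            if cid not in first_name:
                first_name[cid] = m.name
                first_type[cid] = normalize_type(m.semantic_types[0])
            if cid not in seen_here:
                seen_here.add(cid)
                doc_count[cid] = doc_count.get(cid, 0) + 1

    missing = [c for c in sorted(cfg.condition_ids) if doc_count.get(c, 0) == 0]
    if missing:
        raise ConditionAbsentError(
            f"condition concept(s) absent from all documents: {missing}"
        )

    survivors: list[tuple[str, int]] = []
    for cid, count in doc_count.items():
        if cid in cfg.condition_ids:
            survivors.append((cid, count))
            continue
        if cid in cfg.blocklist:
            continue
        if first_type[cid] not in allowed:
            continue
        if count < cfg.min_doc_count:
            continue
        survivors.append((cid, count))

    if not survivors:
        raise EmptyVocabularyError(
            "no concepts survive the filters "
            f"(score_cutoff={cfg.score_cutoff}, min_doc_count={cfg.min_doc_count})"
        )

    survivors.sort(key=lambda item: (-item[1], item[0]))
    entries = [
        VocabEntry(
            concept_id=cid,
            name=cfg.condition_labels.get(cid, first_name[cid]),
            semantic_type=first_type[cid],
            index=i,
            doc_count=count,
        )
        for i, (cid, count) in enumerate(survivors)
    ]
    return ConceptVocabulary(
        entries=entries,
        score_cutoff=cfg.score_cutoff,
        condition_ids=frozenset(cfg.condition_ids),
    )
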