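"""Synthetic annotated corpora with planted co-occurrence structure.

The generator emulates a condition-focused corpus (forum posts or abstracts
reduced to concept annotations): each document draws one latent topic, emits
that topic's concepts independently with their in-topic probabilities, emits
every other topical concept with a small out-of-topic probability, and adds
background concepts that are topic-independent. Because the condition
belongs to exactly one topic, its topic-mates co-occur with it far more
often than out-of-topic concepts do, which fixes the ground-truth
relatedness ordering the downstream ranking must recover.

A subtlety the defaults encode: if every retained document mentioned the
one condition, the condition's marginal probability would be 1 and its
whole PPMI row would vanish (ln(c_j/d_j) = 0 for all j), leaving nothing to
rank. Real condition-focused corpora are collected around *several*
conditions at once (e.g. ASD and ADHD pooled), so each condition covers
only part of the filtered corpus. ``default_spec`` therefore plants a
second condition anchor in the other topic, and ``study_filter_config``
retains documents mentioning either anchor.

Generation is a pure function of (spec, seed): a dedicated
``numpy.random.Generator`` is built from the spec's seed and consumed in a
fixed document/concept order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import AnnotatedDocument, ConceptMention
from .errors import ConfigError

__all__ = [
    "TopicSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_corpus",
    "annotate_with_dictionary",
    "default_spec",
    "study_filter_config",
]


@dataclass(frozen=True)
class TopicSpec:
    """One latent topic: member concepts and their in-topic emission rates."""

    topic_id: str
    emissions: Mapping[str, float]  # concept_id -> P(emit | topic drawn)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-topic corpus.

    Defaults reflect the regime the pipeline is evaluated in: two topics of
    eight concepts, strong in-topic emission (0.8), rare out-of-topic leakage
    (0.02), and linker scores above the 0.7 cutoff so no mention is lost to
    score filtering unless ``decoy_fraction`` is raised.
    """

    n_docs: int
    topics: tuple[TopicSpec, ...]
    condition_id: str
    condition_topic: str
    out_topic_emission: float = 0.02
    background_concepts: Mapping[str, float] = field(default_factory=dict)
    semantic_type_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    score_distribution: tuple[float, float] = (0.75, 1.0)
    decoy_fraction: float = 0.0  # fraction of mentions given a sub-cutoff score
    topic_weights: tuple[float, ...] | None = None
    source: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ConfigError(f"n_docs must be >= 1, got {self.n_docs}")
        topic_ids = [t.topic_id for t in self.topics]
        if self.condition_topic not in topic_ids:
            raise ConfigError(f"unknown condition_topic {self.condition_topic!r}")
        members = [c for t in self.topics for c in t.emissions]
        if len(set(members)) != len(members):
            raise ConfigError("topic member sets must be disjoint")
        if set(members) & set(self.background_concepts):
            raise ConfigError("background concepts must be disjoint from topic members")
        for t in self.topics:
            for cid, p in t.emissions.items():
                if not (0.0 <= p <= 1.0):
                    raise ConfigError(f"emission probability for {cid!r} outside [0, 1]")
        lo, hi = self.score_distribution
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("score_distribution bounds must satisfy 0 <= lo <= hi <= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Which concepts share the condition's topic (the planted 'related' set)."""

    in_topic_concepts: frozenset[str]
    out_topic_concepts: frozenset[str]


def _types_for(spec: SyntheticSpec, cid: str) -> tuple[str, ...]:
    return tuple(spec.semantic_type_map.get(cid, ("finding",)))


def generate_corpus(spec: SyntheticSpec) -> tuple[list[AnnotatedDocument], GroundTruth]:
    """Sample a corpus from the planted-topic model.

    Per document: draw one topic (uniform unless ``topic_weights`` given);
    emit each concept of that topic with its in-topic probability and each
    concept of the other topics with ``out_topic_emission``; emit background
    concepts with their own rates. Every mention gets a linker score sampled
    uniformly from ``score_distribution`` (or below the conventional 0.7
    cutoff with probability ``decoy_fraction``) and its semantic types from
    ``semantic_type_map`` (default type "finding").
    """
    rng = np.random.default_rng(spec.seed)
    topic_ids = [t.topic_id for t in spec.topics]
    weights = None
    if spec.topic_weights is not None:
        w = np.asarray(spec.topic_weights, dtype=float)
        weights = w / w.sum()
    # fixed concept order: topic order then background order
    all_topic_concepts = [(t.topic_id, cid, p) for t in spec.topics for cid, p in t.emissions.items()]
    background = list(spec.background_concepts.items())
    lo, hi = spec.score_distribution

    docs: list[AnnotatedDocument] = []
    width = len(str(spec.n_docs - 1))
    for d in range(spec.n_docs):
        topic = topic_ids[int(rng.choice(len(topic_ids), p=weights))]
        mentions: list[ConceptMention] = []
        for topic_id, cid, p_in in all_topic_concepts:
            p = p_in if topic_id == topic else spec.out_topic_emission
            if rng.random() < p:
                mentions.append(_mention(spec, rng, cid, lo, hi))
        for cid, p in background:
            if rng.random() < p:
                mentions.append(_mention(spec, rng, cid, lo, hi))
        docs.append(
            AnnotatedDocument(
                doc_id=f"{spec.source}-{d:0{width}d}",
                source=spec.source,
                mentions=tuple(mentions),
            )
        )

    condition_topic = next(t for t in spec.topics if t.topic_id == spec.condition_topic)
    in_topic = frozenset(condition_topic.emissions) - {spec.condition_id}
    out_topic = (
        frozenset(cid for _, cid, _ in all_topic_concepts)
        | frozenset(spec.background_concepts)
    ) - in_topic - {spec.condition_id}
    return docs, GroundTruth(in_topic_concepts=in_topic, out_topic_concepts=frozenset(out_topic))


def _mention(spec, rng, cid: str, lo: float, hi: float) -> ConceptMention:
    if spec.decoy_fraction > 0.0 and rng.random() < spec.decoy_fraction:
        score = float(rng.uniform(0.0, min(0.7, lo)))
    else:
        score = float(rng.uniform(lo, hi))
    return ConceptMention(
        concept_id=cid,
        name=cid.replace("_", " "),
        semantic_types=_types_for(spec, cid),
        score=score,
    )


def default_spec(
    n_docs: int = 1000,
    seed: int = 0,
    source: str = "synthetic",
    in_topic_emission: float = 0.8,
    out_topic_emission: float = 0.02,
    concepts_per_topic: int = 8,
) -> SyntheticSpec:
    """The standard two-topic evaluation corpus.

    Topic A carries the condition of interest (``C_COND``) plus
    ``concepts_per_topic - 1`` related concepts; topic B mirrors it with a
    second condition anchor (``C_COND2``) and unrelated concepts, emulating
    a corpus collected around two conditions at once. Two background
    concepts emulate high-frequency generic chatter; they carry the generic
    semantic types ("qualitative concept", "functional concept") that the
    default allowlist excludes, because topic-independent concepts acquire
    spurious bloc-aligned PPMI noise and must be filtered out — the reason
    the type allowlist exists. Topical concepts carry allowlisted types.
    """
    cond, cond2 = "C_COND", "C_COND2"
    type_cycle = ("sign or symptom", "individual behavior", "mental process", "finding")
    topic_a: dict[str, float] = {cond: in_topic_emission}
    topic_b: dict[str, float] = {cond2: in_topic_emission}
    type_map: dict[str, tuple[str, ...]] = {
        cond: ("mental or behavioral dysfunction",),
        cond2: ("mental or behavioral dysfunction",),
    }
    for i in range(concepts_per_topic - 1):
        a, b = f"C_A{i:02d}", f"C_B{i:02d}"
        topic_a[a] = in_topic_emission
        topic_b[b] = in_topic_emission
        type_map[a] = (type_cycle[i % len(type_cycle)],)
        type_map[b] = (type_cycle[(i + 1) % len(type_cycle)],)
    background = {"C_BG00": 0.9, "C_BG01": 0.5}
    type_map["C_BG00"] = ("qualitative concept",)
    type_map["C_BG01"] = ("functional concept",)
    return SyntheticSpec(
        n_docs=n_docs,
        topics=(TopicSpec("topicA", topic_a), TopicSpec("topicB", topic_b)),
        condition_id=cond,
        condition_topic="topicA",
        out_topic_emission=out_topic_emission,
        background_concepts=background,
        semantic_type_map=type_map,
        source=source,
        seed=seed,
    )


def study_filter_config(min_doc_count: int = 1, **overrides) -> "FilterConfig":
    """Filter settings matched to :func:`default_spec` corpora.

    Documents are retained when they mention either condition anchor, and
    the analysis condition is ``C_COND``. ``min_doc_count`` defaults to 1:
    at the default out-of-topic leakage (0.02) an unrelated concept lands in
    only a handful of condition documents, and the ranking evaluation needs
    those concepts present, not filtered away.
    """
    from .corpus_io import FilterConfig

    kwargs = dict(
        min_doc_count=min_doc_count,
        condition_ids=frozenset({"C_COND", "C_COND2"}),
    )
    kwargs.update(overrides)
    return FilterConfig(**kwargs)


def annotate_with_dictionary(
    texts: Sequence[tuple[str, str]],
    lexicon: Mapping[str, tuple[str, Sequence[str]]],
    source: str = "dictionary",
) -> list[AnnotatedDocument]:
    """Greedy longest-match dictionary annotator over whitespace tokens.

    A minimal stand-in for a biomedical entity linker, useful for turning
    small hand-written texts into fixtures. Matching is case-insensitive and
    exact at token granularity; matched spans become mentions with score 1.0
    and unmatched text is ignored.
    """
    if not lexicon:
        raise ConfigError("lexicon is empty")
    norm_lex = {
        tuple(surface.lower().split()): (cid, tuple(types))
        for surface, (cid, types) in lexicon.items()
    }
    max_len = max(len(k) for k in norm_lex)
    docs = []
    for doc_id, text in texts:
        tokens = text.lower().split()
        mentions: list[ConceptMention] = []
        i = 0
        while i < len(tokens):
            match = None
            for span in range(min(max_len, len(tokens) - i), 0, -1):
                key = tuple(tokens[i : i + span])
                if key in norm_lex:
                    match = (span, norm_lex[key])
                    break
            if match is None:
                i += 1
                continue
            span, (cid, types) = match
            mentions.append(
                ConceptMention(
                    concept_id=cid,
                    name=" ".join(tokens[i : i + span]),
                    semantic_types=types,
                    score=1.0,
                )
            )
            i += span
        docs.append(AnnotatedDocument(doc_id=doc_id, source=source, mentions=tuple(mentions)))
    return docs
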