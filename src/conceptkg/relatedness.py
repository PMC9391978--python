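"""Cosine relatedness to the condition and top-k ranking per semantic type.

Relatedness between concepts i and j is the cosine of their embedding
vectors, relatedness_ij = C_i . C_j / (||C_i|| ||C_j||), in [-1, 1]. Each
concept additionally carries a frequency: the proportion of
condition-mentioning documents it co-occurs with the condition in (or of
all filtered documents, if configured), which downstream becomes the node
size in the knowledge graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import AnnotatedDocument, ConceptVocabulary
from .embedding import EmbeddingMatrix, incidence_matrix
from .errors import ConditionAbsentError, ZeroVectorError

__all__ = [
    "RelatednessTable",
    "RankedConcept",
    "RankedSelection",
    "cosine_relatedness",
    "condition_frequency",
    "relatedness_to_condition",
    "rank_by_semantic_type",
]


@dataclass
class RelatednessTable:
    """Per-concept relatedness to the condition plus co-occurrence frequency.

    ``df`` columns: concept_id, name, semantic_type, relatedness, frequency.
    One row per vocabulary concept (condition included, relatedness 1).
    """

    df: pd.DataFrame
    condition_id: str
    source: str


@dataclass(frozen=True)
class RankedConcept:
    concept_id: str
    name: str
    relatedness: float
    frequency: float


#: semantic_type -> concepts sorted by relatedness (desc), at most top_k each
RankedSelection = dict[str, list[RankedConcept]]


def cosine_relatedness(emb: EmbeddingMatrix, i: int, j: int) -> float:
    """Cosine of the angle between concept vectors i and j, clipped to [-1, 1].

    A zero-norm vector makes the cosine undefined and raises
    :class:`ZeroVectorError` naming the concept rather than returning a
    silent 0.
    """
    vi, vj = emb.vectors[i], emb.vectors[j]
    ni, nj = np.linalg.norm(vi), np.linalg.norm(vj)
    for idx, norm in ((i, ni), (j, nj)):
        if norm == 0.0:
            cid = emb.vocab.entries[idx].concept_id
            raise ZeroVectorError(f"concept {cid!r} has a zero embedding vector")
    return float(np.clip(vi @ vj / (ni * nj), -1.0, 1.0))


def condition_frequency(
    docs: list[AnnotatedDocument],
    vocab: ConceptVocabulary,
    condition_id: str,
    denominator: str = "condition_docs",
) -> dict[str, float]:
    """Per-concept co-occurrence frequency with the condition.

    frequency(c) = #documents containing both c and the condition, divided
    by the number of condition-mentioning documents (default) or by the
    whole filtered corpus (``denominator="all_docs"``). The condition's own
    frequency is 1 under the default denominator.
    """
    if condition_id not in vocab:
        raise ConditionAbsentError(f"condition {condition_id!r} not in vocabulary")
    X = incidence_matrix(docs, vocab)
    cond_col = np.asarray(X[:, vocab.index_of(condition_id)].todense()).ravel()
    n_cond = int(cond_col.sum())
    if n_cond == 0:
        raise ConditionAbsentError(f"condition {condition_id!r} occurs in no document")
    co = np.asarray((X.T @ cond_col)).ravel()  # per concept: docs shared with condition
    if denominator == "condition_docs":
        denom = n_cond
    elif denominator == "all_docs":
        denom = len(docs)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return {e.concept_id: float(co[e.index]) / denom for e in vocab.entries}


def relatedness_to_condition(
    emb: EmbeddingMatrix,
    docs: list[AnnotatedDocument],
    condition_id: str,
    source: str,
    frequency_denominator: str = "condition_docs",
) -> RelatednessTable:
    """Build the full relatedness table of every concept against the condition."""
    vocab = emb.vocab
    freq = condition_frequency(docs, vocab, condition_id, frequency_denominator)
    ci = vocab.index_of(condition_id)
    rows = []
    for e in vocab.entries:
        rows.append(
            {
                "concept_id": e.concept_id,
                "name": e.name,
                "semantic_type": e.semantic_type,
                "relatedness": 1.0
                if e.index == ci
                else cosine_relatedness(emb, e.index, ci),
                "frequency": freq[e.concept_id],
            }
        )
    return RelatednessTable(df=pd.DataFrame(rows), condition_id=condition_id, source=source)


def rank_by_semantic_type(table: RelatednessTable, top_k: int = 25) -> RankedSelection:
    """Top ``top_k`` concepts per semantic type by relatedness to the condition.

    The condition itself is excluded (it is the hub, never a leaf). Ties in
    relatedness break lexicographically by concept id; semantic types left
    with no concepts are omitted.
    """
    if table.df.empty:
        raise ValueError("relatedness table is empty")
    df = table.df[table.df["concept_id"] != table.condition_id]
    sel: RankedSelection = {}
    for stype, group in df.groupby("semantic_type", sort=True):
        ordered = group.sort_values(
            ["relatedness", "concept_id"], ascending=[False, True], kind="mergesort"
        ).head(top_k)
        if len(ordered):
            sel[stype] = [
                RankedConcept(
                    concept_id=r.concept_id,
                    name=r.name,
                    relatedness=float(r.relatedness),
                    frequency=float(r.frequency),
                )
                for r in ordered.itertuples(index=False)
            ]
    return sel
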