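"""Shared fixtures: tiny hand-built corpora and a standard synthetic corpus."""

from __future__ import annotations

import pytest

from conceptkg.corpus_io import AnnotatedDocument, ConceptMention, FilterConfig
from conceptkg.synthetic import default_spec, generate_corpus, study_filter_config


def mention(cid: str, score: float = 0.9, stype: str = "finding", name: str | None = None):
    return ConceptMention(
        concept_id=cid, name=name or cid, semantic_types=(stype,), score=score
    )


def doc(doc_id: str, *cids: str, source: str = "test", score: float = 0.9):
    return AnnotatedDocument(
        doc_id=doc_id, source=source, mentions=tuple(mention(c, score) for c in cids)
    )


@pytest.fixture
def make_mention():
    return mention


@pytest.fixture
def make_doc():
    return doc


@pytest.fixture
def toy_cfg():
    """Condition COND, no count/type pruning beyond the essentials."""
    return FilterConfig(min_doc_count=1, condition_ids=frozenset({"COND"}))


@pytest.fixture(scope="session")
def synth_corpus():
    """One medium planted-topic corpus plus its ground truth and filter config."""
    spec = default_spec(n_docs=600, seed=7)
    docs, truth = generate_corpus(spec)
    return spec, docs, truth, study_filter_config()
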