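"""Corpus reading, document/concept filters, and vocabulary construction."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conceptkg import corpus_io
from conceptkg.corpus_io import (
    AnnotatedDocument,
    ConceptMention,
    FilterConfig,
    build_vocabulary,
    default_semantic_types,
    filter_condition_documents,
    normalize_type,
    read_annotated_corpus,
    write_annotated_corpus,
)
from conceptkg.errors import (
    ConditionAbsentError,
    ConfigError,
    CorpusFormatError,
    EmptyCorpusError,
    EmptyVocabularyError,
)

from conftest import doc, mention


def _record(doc_id, cids, score=0.9):
    return {
        "doc_id": doc_id,
        "source": "t",
        "mentions": [
            {"concept_id": c, "name": c, "semantic_types": ["finding"], "score": score}
            for c in cids
        ],
    }


class TestReadCorpus:
    def test_reads_records_in_file_order(self, tmp_path):
        path = tmp_path / "c.jsonl"
        recs = [_record(f"d{i}", ["A", "B"]) for i in range(3)]
        path.write_text("\n".join(json.dumps(r) for r in recs) + "\n")
        docs = read_annotated_corpus(path)
        assert [d.doc_id for d in docs] == ["d0", "d1", "d2"]
        assert docs[0].mentions[0].concept_id == "A"

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text("")
        assert read_annotated_corpus(path) == []

    def test_out_of_range_score_names_document(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(json.dumps(_record("bad-doc", ["A"], score=1.3)) + "\n")
        with pytest.raises(CorpusFormatError, match="bad-doc"):
            read_annotated_corpus(path)

    def test_duplicate_doc_id_rejected(self, tmp_path):
        path = tmp_path / "c.jsonl"
        rec = json.dumps(_record("d1", ["A"]))
        path.write_text(rec + "\n" + rec + "\n")
        with pytest.raises(CorpusFormatError, match="duplicate"):
            read_annotated_corpus(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_annotated_corpus(tmp_path / "nope.jsonl")

    def test_write_read_round_trip(self, tmp_path):
        docs = [doc("d1", "A", "B"), doc("d2", "B")]
        path = tmp_path / "c.jsonl"
        write_annotated_corpus(docs, path)
        assert read_annotated_corpus(path) == docs


class TestDocumentFilter:
    def test_synonym_merged_then_retained(self):
        """A document mentioning only a condition synonym survives, rewritten."""
        cfg = FilterConfig(
            condition_ids=frozenset({"C_ASD"}),
            condition_merge_map={"C_ASP": "C_ASD"},
            condition_labels={"C_ASD": "autism spectrum disorder"},
        )
        d = AnnotatedDocument(
            "d1", "t", (mention("C_ASP", name="Asperger syndrome"),)
        )
        out = filter_condition_documents([d], cfg)
        assert len(out) == 1
        assert out[0].mentions[0].concept_id == "C_ASD"
        assert out[0].mentions[0].name == "autism spectrum disorder"

    def test_document_without_condition_dropped(self, toy_cfg):
        assert filter_condition_documents([doc("d1", "A", "B")], toy_cfg) == []

    def test_exact_survivor_set(self, toy_cfg):
        docs = [doc(f"d{i}", "X") for i in range(6)] + [
            doc(f"c{i}", "COND", "X") for i in range(4)
        ]
        out = filter_condition_documents(docs, toy_cfg)
        assert [d.doc_id for d in out] == ["c0", "c1", "c2", "c3"]

    def test_empty_condition_set_is_config_error(self):
        with pytest.raises(ConfigError):
            filter_condition_documents([doc("d1", "A")], FilterConfig())


class TestVocabulary:
    def test_score_cutoff_is_strict(self, toy_cfg):
        """Scores must be strictly greater than the 0.7 cutoff to count."""
        docs = [
            AnnotatedDocument(
                "d1", "t", (mention("COND"), mention("LOW", 0.69), mention("EDGE", 0.7))
            )
        ]
        vocab = build_vocabulary(docs, toy_cfg)
        assert "LOW" not in vocab and "EDGE" not in vocab

    def test_min_doc_count_boundary(self):
        cfg = FilterConfig(min_doc_count=10, condition_ids=frozenset({"COND"}))
        docs = [doc(f"d{i}", "COND", "NINE") for i in range(9)] + [
            doc(f"e{i}", "COND", "TEN") for i in range(10)
        ]
        vocab = build_vocabulary(docs, cfg)
        assert "TEN" in vocab and "NINE" not in vocab

    def test_index_order_and_tie_break(self):
        """Indices: descending doc count, ties lexicographic by concept id."""
        cfg = FilterConfig(min_doc_count=10, condition_ids=frozenset({"COND"}))
        docs = (
            [doc(f"d{i}", "COND", "B", "A") for i in range(12)]
            + [doc(f"e{i}", "COND", "C") for i in range(3)]
        )
        vocab = build_vocabulary(docs, cfg)
        assert "C" not in vocab
        # COND is in 15 docs -> index 0; A and B tie at 12 docs
        assert vocab.index_of("COND") == 0
        assert vocab.index_of("A") == 1
        assert vocab.index_of("B") == 2

    def test_first_semantic_type_and_allowlist(self, toy_cfg):
        d = AnnotatedDocument(
            "d1",
            "t",
            (
                mention("COND"),
                ConceptMention("GEN", "GEN", ("qualitative concept", "finding"), 0.9),
            ),
        )
        vocab = build_vocabulary([d], toy_cfg)
        assert "GEN" not in vocab  # first type decides, and it is not allowlisted

    def test_condition_bypasses_type_and_count_filters(self):
        cfg = FilterConfig(min_doc_count=10, condition_ids=frozenset({"COND"}))
        d = AnnotatedDocument(
            "d1", "t", (ConceptMention("COND", "COND", ("qualitative concept",), 0.9),)
        )
        vocab = build_vocabulary([d], cfg)
        assert "COND" in vocab and vocab.entry("COND").doc_count == 1

    def test_blocklist_removes_concept(self):
        cfg = FilterConfig(
            min_doc_count=1, condition_ids=frozenset({"COND"}), blocklist=frozenset({"FP"})
        )
        vocab = build_vocabulary([doc("d1", "COND", "FP", "OK")], cfg)
        assert "FP" not in vocab and "OK" in vocab

    def test_condition_in_blocklist_rejected(self):
        with pytest.raises(ConfigError):
            FilterConfig(condition_ids=frozenset({"C"}), blocklist=frozenset({"C"}))

    def test_condition_absent_errors(self, toy_cfg):
        with pytest.raises(ConditionAbsentError):
            build_vocabulary([doc("d1", "A")], toy_cfg)

    def test_empty_docs_error(self, toy_cfg):
        with pytest.raises(EmptyCorpusError):
            build_vocabulary([], toy_cfg)

    def test_everything_filtered_is_explicit_error(self):
        cfg = FilterConfig(condition_ids=frozenset({"COND"}), score_cutoff=0.99)
        with pytest.raises(ConditionAbsentError):
            build_vocabulary([doc("d1", "COND", "A")], cfg)

    def test_repeated_mentions_count_once(self, toy_cfg):
        d = AnnotatedDocument("d1", "t", (mention("COND"), mention("A"), mention("A")))
        vocab = build_vocabulary([d], toy_cfg)
        assert vocab.entry("A").doc_count == 1


class TestFilterProperties:
    def test_filtering_is_idempotent(self, synth_corpus):
        """Re-deriving the vocabulary from already-surviving concepts changes nothing."""
        _, docs, _, cfg = synth_corpus
        filtered = filter_condition_documents(docs, cfg)
        vocab1 = build_vocabulary(filtered, cfg)
        kept = set(vocab1.concept_ids)
        pruned = [
            AnnotatedDocument(
                d.doc_id, d.source, tuple(m for m in d.mentions if m.concept_id in kept)
            )
            for d in filtered
        ]
        pruned = [d for d in pruned if d.mentions]
        vocab2 = build_vocabulary(filter_condition_documents(pruned, cfg), cfg)
        assert [(e.concept_id, e.doc_count) for e in vocab1.entries] == [
            (e.concept_id, e.doc_count) for e in vocab2.entries
        ]

    @settings(derandomize=True, max_examples=40)
    @given(
        cutoff=st.floats(0.0, 0.95),
        min_count=st.integers(1, 6),
        data=st.lists(
            st.lists(st.sampled_from("ABCDE"), min_size=0, max_size=4), min_size=1, max_size=20
        ),
    )
    def test_filters_are_monotone(self, cutoff, min_count, data):
        """Raising score_cutoff or min_doc_count never grows the vocabulary."""
        docs = [doc(f"d{i}", "COND", *cids) for i, cids in enumerate(data)]
        base = FilterConfig(
            score_cutoff=cutoff, min_doc_count=min_count, condition_ids=frozenset({"COND"})
        )
        stricter = FilterConfig(
            score_cutoff=min(cutoff + 0.04, 1.0),
            min_doc_count=min_count + 1,
            condition_ids=frozenset({"COND"}),
        )
        try:
            n_base = build_vocabulary(docs, base).n
        except (EmptyVocabularyError, ConditionAbsentError):
            return
        try:
            n_strict = build_vocabulary(docs, stricter).n
        except (EmptyVocabularyError, ConditionAbsentError):
            n_strict = 0
        assert n_strict <= n_base
        distinct = {c for cids in data for c in cids} | {"COND"}
        assert n_base <= len(distinct)


def test_default_semantic_types_has_26_entries():
    types = default_semantic_types()
    assert len(types) == 26
    assert normalize_type("Mental  or Behavioral Dysfunction") in types
    assert normalize_type("health care–related organization") in types  # en dash folded
    assert "qualitative concept" not in types


def test_filter_config_yaml_round_trip(tmp_path):
    path = tmp_path / "f.yaml"
    path.write_text(
        "score_cutoff: 0.8\nmin_doc_count: 3\ncondition_ids: [C1]\n"
        "condition_merge_map: {C9: C1}\nblocklist: [BAD]\n"
    )
    cfg = FilterConfig.from_yaml(path)
    assert cfg.score_cutoff == 0.8
    assert cfg.min_doc_count == 3
    assert cfg.condition_merge_map == {"C9": "C1"}
    assert cfg.effective_types == default_semantic_types()
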