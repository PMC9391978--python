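"""End-to-end orchestration: corpus -> vocabulary -> embeddings -> KG (-> comparison).

A single :class:`PipelineConfig` drives every stage with the method's
defaults (score cutoff 0.7, >=10 documents, 26-type allowlist, k=300,
top 25 per type, µ ± 2σ). Each run writes its artifacts plus a manifest
(config hash, seed, per-stage counts) into the output directory; manifests
and tables are written deterministically so identical config+seed runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import comparison as cmp
from . import corpus_io, embedding, kg_builder, relatedness
from .errors import ConceptKGError, ConfigError

__all__ = ["PipelineConfig", "StageError", "SingleSourceResult", "run_single_source", "run_comparison"]

log = logging.getLogger("conceptkg")


class StageError(ConceptKGError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML.

    ``corpora`` maps a source tag (e.g. "forum", "pubmed") to a corpus
    path; ``condition_id`` names the canonical condition concept all stages
    anchor on. The comparison stage requires exactly two corpora.
    """

    corpora: dict[str, str]
    condition_id: str
    filter: corpus_io.FilterConfig = field(default_factory=corpus_io.FilterConfig)
    k: int = 300
    top_k: int = 25
    frequency_denominator: str = "condition_docs"
    compare_scope: str = "selected"  # selected | all
    seed: int = 0
    out_dir: str = "runs/out"

    def __post_init__(self) -> None:
        if not self.corpora:
            raise ConfigError("at least one corpus path is required")
        if self.condition_id and self.condition_id not in self.filter.condition_ids:
            self.filter = corpus_io.FilterConfig(
                score_cutoff=self.filter.score_cutoff,
                min_doc_count=self.filter.min_doc_count,
                allowed_semantic_types=self.filter.allowed_semantic_types,
                condition_merge_map=self.filter.condition_merge_map,
                condition_ids=self.filter.condition_ids | {self.condition_id},
                condition_labels=self.filter.condition_labels,
                blocklist=self.filter.blocklist,
            )
        if self.compare_scope not in ("selected", "all"):
            raise ConfigError(f"compare_scope must be 'selected' or 'all', got {self.compare_scope!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        return cls(
            corpora=dict(data["corpora"]),
            condition_id=data["condition_id"],
            filter=corpus_io.FilterConfig.from_dict(data.get("filter", {})),
            k=int(data.get("k", 300)),
            top_k=int(data.get("top_k", 25)),
            frequency_denominator=data.get("frequency_denominator", "condition_docs"),
            compare_scope=data.get("compare_scope", "selected"),
            seed=int(data.get("seed", 0)),
            out_dir=data.get("out_dir", "runs/out"),
        )

    def canonical_dict(self) -> dict:
        f = self.filter
        return {
            "corpora": dict(sorted(self.corpora.items())),
            "condition_id": self.condition_id,
            "filter": {
                "score_cutoff": f.score_cutoff,
                "min_doc_count": f.min_doc_count,
                "allowed_semantic_types": sorted(f.effective_types),
                "condition_merge_map": dict(sorted(f.condition_merge_map.items())),
                "condition_ids": sorted(f.condition_ids),
                "condition_labels": dict(sorted(f.condition_labels.items())),
                "blocklist": sorted(f.blocklist),
            },
            "k": self.k,
            "top_k": self.top_k,
            "frequency_denominator": self.frequency_denominator,
            "compare_scope": self.compare_scope,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()


@dataclass
class SingleSourceResult:
    source: str
    vocab: corpus_io.ConceptVocabulary
    emb: embedding.EmbeddingMatrix
    table: relatedness.RelatednessTable
    selection: relatedness.RankedSelection
    kg: kg_builder.KnowledgeGraph
    docs_filtered: list
    manifest: dict


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ConceptKGError as exc:
            raise StageError(name, exc) from exc

    return wrap


def _write_manifest(manifest: dict, path: Path) -> None:
    path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n", encoding="utf-8")


def run_single_source(
    cfg: PipelineConfig, source: str, out_dir: str | Path | None = None
) -> SingleSourceResult:
    """Run corpus -> filters -> embedding -> relatedness -> KG for one source.

    Writes vocabulary/relatedness/selection tables, the GraphML + CSV graph
    exports, and a ``manifest.json`` with before/after counts at each filter
    stage. Any stage failure raises :class:`StageError` naming the stage.
    """
    if source not in cfg.corpora:
        raise ConfigError(f"source {source!r} not in configured corpora {sorted(cfg.corpora)}")
    out = Path(out_dir if out_dir is not None else Path(cfg.out_dir) / source)
    out.mkdir(parents=True, exist_ok=True)

    docs = _stage("read_annotated_corpus")(corpus_io.read_annotated_corpus, cfg.corpora[source])
    log.info("%s: %d documents read", source, len(docs))
    filtered = _stage("filter_condition_documents")(
        corpus_io.filter_condition_documents, docs, cfg.filter
    )
    log.info("%s: %d documents mention the condition", source, len(filtered))
    vocab = _stage("build_vocabulary")(corpus_io.build_vocabulary, filtered, cfg.filter)
    log.info("%s: vocabulary of %d concepts", source, vocab.n)
    cooc = _stage("build_cooccurrence")(embedding.build_cooccurrence, filtered, vocab)
    ppmi = _stage("compute_ppmi")(embedding.compute_ppmi, cooc)
    emb = _stage("embed_svd")(embedding.embed_svd, ppmi, cfg.k, cfg.seed)
    log.info("%s: embedded at effective k=%d", source, emb.k)
    table = _stage("relatedness_to_condition")(
        relatedness.relatedness_to_condition,
        emb,
        filtered,
        cfg.condition_id,
        source,
        cfg.frequency_denominator,
    )
    selection = _stage("rank_by_semantic_type")(
        relatedness.rank_by_semantic_type, table, cfg.top_k
    )
    kg = _stage("build_kg")(
        kg_builder.build_kg,
        selection,
        cfg.condition_id,
        source,
        cfg.filter.condition_labels.get(cfg.condition_id),
        cfg.top_k,
    )

    vocab.to_frame().to_csv(out / "vocabulary.tsv", sep="\t", index=False)
    table.df.to_csv(out / "relatedness.tsv", sep="\t", index=False)
    _selection_frame(selection).to_csv(out / "selection.tsv", sep="\t", index=False)
    kg_builder.export_graph(kg, out / "kg.graphml", "graphml")
    kg_builder.export_graph(kg, out / "kg", "csv_pair")

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "source": source,
        "documents_in": len(docs),
        "documents_after_condition_filter": len(filtered),
        "vocabulary_size": vocab.n,
        "effective_k": emb.k,
        "semantic_types_selected": len(selection),
        "kg_nodes": len(kg.nodes),
        "kg_edges": len(kg.edges),
    }
    _write_manifest(manifest, out / "manifest.json")
    return SingleSourceResult(
        source=source,
        vocab=vocab,
        emb=emb,
        table=table,
        selection=selection,
        kg=kg,
        docs_filtered=filtered,
        manifest=manifest,
    )


def _selection_frame(selection: relatedness.RankedSelection):
    import pandas as pd

    rows = []
    for stype in sorted(selection):
        for rank, c in enumerate(selection[stype], start=1):
            rows.append(
                {
                    "semantic_type": stype,
                    "rank": rank,
                    "concept_id": c.concept_id,
                    "name": c.name,
                    "relatedness": c.relatedness,
                    "frequency": c.frequency,
                }
            )
    return pd.DataFrame(rows)


def run_comparison(cfg: PipelineConfig) -> dict:
    """Run both sources, link their KGs with sameAs edges, and classify concepts.

    Returns a dict with the two single-source results, the merged graph, and
    the classified :class:`~conceptkg.comparison.ComparisonTable`; writes the
    merged GraphML, the comparison table, and a summary block (µ, σ,
    thresholds, per-category counts).
    """
    if len(cfg.corpora) != 2:
        raise ConfigError(f"comparison needs exactly two corpora, got {len(cfg.corpora)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    src_a, src_b = sorted(cfg.corpora)
    res = {s: run_single_source(cfg, s) for s in (src_a, src_b)}

    merged = _stage("link_same_as")(kg_builder.link_same_as, res[src_a].kg, res[src_b].kg)
    kg_builder.export_graph(merged, out / "merged_kg.graphml", "graphml")

    # "forum" side is the first source alphabetically unless a tag named
    # forum/pubmed disambiguates; FR - PR follows that orientation.
    forum_src = "forum" if "forum" in cfg.corpora else src_a
    pubmed_src = next(s for s in (src_a, src_b) if s != forum_src)
    restrict = None
    if cfg.compare_scope == "selected":
        restrict = {
            c.concept_id
            for r in res.values()
            for concepts in r.selection.values()
            for c in concepts
        }
    table = _stage("score_differences")(
        cmp.score_differences, res[forum_src].table, res[pubmed_src].table, restrict
    )
    table = cmp.classify_concepts(table)

    table.df.to_csv(out / "comparison.tsv", sep="\t", index=False)
    lo, hi = table.thresholds
    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "forum_source": forum_src,
        "pubmed_source": pubmed_src,
        "mu": table.mu,
        "sigma": table.sigma,
        "lower_threshold": lo,
        "upper_threshold": hi,
        "category_counts": table.category_counts(),
        "n_compared": int(len(table.df)),
        "only_forum": table.only_forum,
        "only_pubmed": table.only_pubmed,
        "same_as_edges": sum(1 for e in merged.edges if e.relation == "sameAs"),
    }
    _write_manifest(summary, out / "comparison_summary.json")
    return {"results": res, "merged_kg": merged, "comparison": table, "summary": summary}
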