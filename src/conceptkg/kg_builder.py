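"""Property-graph construction, cross-source linking, and export.

Schema: one *condition* node (frequency 1) is the hub; each semantic type
with selected concepts gets a *semantic_type* node connected to the
condition by an unweighted ``isRelatedTo`` edge; each selected concept gets
a *concept* node connected to its semantic type by an ``isA`` edge whose
weight is the concept's relatedness to the condition. Node frequency is the
concept's co-occurrence frequency with the condition; a semantic-type
node's frequency is the mean over its selected concepts. Two single-source
graphs are merged by adding one unweighted ``sameAs`` edge per concept
selected in both (direction carries no meaning).

Node ids are namespaced ``source:kind:key`` so the same concept id can
exist on both sides of a merged graph.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import SchemaError
from .relatedness import RankedSelection

__all__ = [
    "KGNode",
    "KGEdge",
    "KnowledgeGraph",
    "build_kg",
    "link_same_as",
    "validate_kg",
    "export_graph",
    "load_graphml",
    "load_csv_pair",
]


@dataclass(frozen=True)
class KGNode:
    node_id: str
    kind: str  # condition | semantic_type | concept
    label: str
    frequency: float
    source: str


@dataclass(frozen=True)
class KGEdge:
    edge_id: str
    from_node: str
    to_node: str
    relation: str  # isA | isRelatedTo | sameAs
    weight: float | None = None


@dataclass
class KnowledgeGraph:
    nodes: dict[str, KGNode]
    edges: list[KGEdge]
    condition_id: str
    source: str
    top_k: int = 25
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sources:
            self.sources = frozenset({self.source})

    def concept_ids(self, source: str | None = None) -> set[str]:
        """Concept ids of concept nodes, optionally restricted to one source."""
        return {
            n.node_id.split(":", 2)[2]
            for n in self.nodes.values()
            if n.kind == "concept" and (source is None or n.source == source)
        }


def _nid(source: str, kind: str, key: str) -> str:
    return f"{source}:{kind}:{key}"


def build_kg(
    sel: RankedSelection,
    condition_id: str,
    source: str,
    condition_label: str | None = None,
    top_k: int = 25,
) -> KnowledgeGraph:
    """Materialize the property graph from a ranked per-type selection."""
    if not sel:
        raise SchemaError("ranked selection is empty; nothing to build")
    nodes: dict[str, KGNode] = {}
    edges: list[KGEdge] = []
    cond_nid = _nid(source, "condition", condition_id)
    nodes[cond_nid] = KGNode(
        node_id=cond_nid,
        kind="condition",
        label=condition_label or condition_id,
        frequency=1.0,
        source=source,
    )
    for stype in sorted(sel):
        concepts = sel[stype]
        if not concepts:
            continue
        type_nid = _nid(source, "semantic_type", stype)
        mean_freq = sum(c.frequency for c in concepts) / len(concepts)
        nodes[type_nid] = KGNode(type_nid, "semantic_type", stype, mean_freq, source)
        edges.append(
            KGEdge(f"isRelatedTo:{type_nid}->{cond_nid}", type_nid, cond_nid, "isRelatedTo")
        )
        for c in concepts:
            c_nid = _nid(source, "concept", c.concept_id)
            nodes[c_nid] = KGNode(c_nid, "concept", c.name, c.frequency, source)
            edges.append(
                KGEdge(
                    f"isA:{c_nid}->{type_nid}",
                    c_nid,
                    type_nid,
                    "isA",
                    weight=c.relatedness,
                )
            )
    kg = KnowledgeGraph(
        nodes=nodes, edges=edges, condition_id=condition_id, source=source, top_k=top_k
    )
    validate_kg(kg)
    return kg


def link_same_as(kg_a: KnowledgeGraph, kg_b: KnowledgeGraph) -> KnowledgeGraph:
    """Merge two single-source graphs, adding one ``sameAs`` edge per shared concept.

    The two graphs must come from different sources; node ids are already
    namespaced by source so the union is disjoint. ``sameAs`` edges are
    stored once, from the lexicographically smaller source, with undirected
    semantics and no weight.
    """
    if kg_a.sources & kg_b.sources:
        raise SchemaError(
            f"cannot link graphs sharing a source: {sorted(kg_a.sources & kg_b.sources)}"
        )
    first, second = sorted((kg_a, kg_b), key=lambda g: g.source)
    nodes = {**first.nodes, **second.nodes}
    edges = list(first.edges) + list(second.edges)
    shared = sorted(first.concept_ids(first.source) & second.concept_ids(second.source))
    for cid in shared:
        a_nid = _nid(first.source, "concept", cid)
        b_nid = _nid(second.source, "concept", cid)
        edges.append(KGEdge(f"sameAs:{a_nid}<->{b_nid}", a_nid, b_nid, "sameAs"))
    merged = KnowledgeGraph(
        nodes=nodes,
        edges=edges,
        condition_id=first.condition_id,
        source=f"{first.source}+{second.source}",
        top_k=max(first.top_k, second.top_k),
        sources=first.sources | second.sources,
    )
    validate_kg(merged)
    return merged


def validate_kg(kg: KnowledgeGraph) -> None:
    """Check every schema invariant; raise :class:`SchemaError` on the first hit.

    Invariants: node frequencies in [0, 1]; weights present exactly on isA
    edges; isA connects concept -> semantic_type (exactly one per concept
    node); isRelatedTo connects semantic_type -> condition (exactly one per
    type node); sameAs connects concept nodes of different sources, at most
    one per concept id pair; at most ``top_k`` concepts per semantic type
    within a source.
    """
    for n in kg.nodes.values():
        if not (0.0 <= n.frequency <= 1.0):
            raise SchemaError(f"node {n.node_id}: frequency {n.frequency} outside [0, 1]")
        if n.kind not in ("condition", "semantic_type", "concept"):
            raise SchemaError(f"node {n.node_id}: unknown kind {n.kind!r}")

    isa_count: dict[str, int] = {}
    rel_count: dict[str, int] = {}
    sameas_seen: set[frozenset[str]] = set()
    per_type: dict[str, int] = {}
    for e in kg.edges:
        if e.from_node not in kg.nodes or e.to_node not in kg.nodes:
            raise SchemaError(f"edge {e.edge_id}: endpoint missing from node set")
        src, dst = kg.nodes[e.from_node], kg.nodes[e.to_node]
        if e.relation == "isA":
            if e.weight is None:
                raise SchemaError(f"edge {e.edge_id}: isA edge missing weight")
            if (src.kind, dst.kind) != ("concept", "semantic_type"):
                raise SchemaError(f"edge {e.edge_id}: isA must connect concept->semantic_type")
            isa_count[e.from_node] = isa_count.get(e.from_node, 0) + 1
            per_type[e.to_node] = per_type.get(e.to_node, 0) + 1
        elif e.relation == "isRelatedTo":
            if e.weight is not None:
                raise SchemaError(f"edge {e.edge_id}: isRelatedTo must carry no weight")
            if (src.kind, dst.kind) != ("semantic_type", "condition"):
                raise SchemaError(
                    f"edge {e.edge_id}: isRelatedTo must connect semantic_type->condition"
                )
            rel_count[e.from_node] = rel_count.get(e.from_node, 0) + 1
        elif e.relation == "sameAs":
            if e.weight is not None:
                raise SchemaError(f"edge {e.edge_id}: sameAs must carry no weight")
            if src.kind != "concept" or dst.kind != "concept":
                raise SchemaError(f"edge {e.edge_id}: sameAs must connect concept nodes")
            if src.source == dst.source:
                raise SchemaError(f"edge {e.edge_id}: sameAs must cross sources")
            key = frozenset((e.from_node, e.to_node))
            if key in sameas_seen:
                raise SchemaError(f"edge {e.edge_id}: duplicate sameAs pair")
            sameas_seen.add(key)
        else:
            raise SchemaError(f"edge {e.edge_id}: unknown relation {e.relation!r}")

    for nid, node in kg.nodes.items():
        if node.kind == "concept" and isa_count.get(nid, 0) != 1:
            raise SchemaError(
                f"concept node {nid} has {isa_count.get(nid, 0)} isA edges (expected 1)"
            )
        if node.kind == "semantic_type" and rel_count.get(nid, 0) != 1:
            raise SchemaError(
                f"semantic-type node {nid} has {rel_count.get(nid, 0)} "
                "isRelatedTo edges (expected 1)"
            )
    for type_nid, count in per_type.items():
        if count > kg.top_k:
            raise SchemaError(
                f"semantic-type node {type_nid} has {count} concepts (> top_k={kg.top_k})"
            )


def _to_networkx(kg: KnowledgeGraph) -> nx.DiGraph:
    g = nx.DiGraph(condition_id=kg.condition_id, source=kg.source, top_k=kg.top_k)
    for n in kg.nodes.values():
        g.add_node(n.node_id, kind=n.kind, label=n.label, frequency=n.frequency, source=n.source)
    for e in kg.edges:
        attrs = {"relation": e.relation, "edge_id": e.edge_id}
        if e.weight is not None:  # weight attribute absent on unweighted relations
            attrs["weight"] = e.weight
        g.add_edge(e.from_node, e.to_node, **attrs)
    return g


def _from_networkx(g: nx.DiGraph) -> KnowledgeGraph:
    nodes = {
        nid: KGNode(
            node_id=nid,
            kind=d["kind"],
            label=d["label"],
            frequency=float(d["frequency"]),
            source=d["source"],
        )
        for nid, d in g.nodes(data=True)
    }
    edges = [
        KGEdge(
            edge_id=d.get("edge_id", f"{d['relation']}:{u}->{v}"),
            from_node=u,
            to_node=v,
            relation=d["relation"],
            weight=float(d["weight"]) if "weight" in d else None,
        )
        for u, v, d in g.edges(data=True)
    ]
    sources = frozenset(n.source for n in nodes.values())
    return KnowledgeGraph(
        nodes=nodes,
        edges=edges,
        condition_id=g.graph.get("condition_id", ""),
        source=g.graph.get("source", ""),
        top_k=int(g.graph.get("top_k", 25)),
        sources=sources,
    )


def export_graph(kg: KnowledgeGraph, path: str | Path, fmt: str = "graphml") -> list[Path]:
    """Write the graph as GraphML or a bulk-import friendly node/edge CSV pair.

    GraphML goes to ``path`` itself; ``csv_pair`` writes ``<path>.nodes.csv``
    and ``<path>.edges.csv``. Unweighted edges serialize without a weight
    attribute (empty field in CSV), never as 0.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_to_networkx(kg), path)
        return [path]
    if fmt == "csv_pair":
        nodes_path = path.with_suffix(path.suffix + ".nodes.csv")
        edges_path = path.with_suffix(path.suffix + ".edges.csv")
        with open(nodes_path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node_id", "kind", "label", "frequency", "source"])
            for n in sorted(kg.nodes.values(), key=lambda x: x.node_id):
                w.writerow([n.node_id, n.kind, n.label, repr(n.frequency), n.source])
        with open(edges_path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["from", "to", "relation", "weight"])
            for e in kg.edges:
                w.writerow(
                    [e.from_node, e.to_node, e.relation, "" if e.weight is None else repr(e.weight)]
                )
        return [nodes_path, edges_path]
    raise ValueError(f"unknown export format {fmt!r}")


def load_graphml(path: str | Path) -> KnowledgeGraph:
    """Inverse of GraphML export; round-trips nodes, edges, and attributes."""
    return _from_networkx(nx.read_graphml(Path(path)))


def load_csv_pair(nodes_path: str | Path, edges_path: str | Path) -> KnowledgeGraph:
    """Load a graph from the node/edge CSV pair written by ``export_graph``."""
    nodes: dict[str, KGNode] = {}
    with open(nodes_path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            nodes[row["node_id"]] = KGNode(
                node_id=row["node_id"],
                kind=row["kind"],
                label=row["label"],
                frequency=float(row["frequency"]),
                source=row["source"],
            )
    edges: list[KGEdge] = []
    with open(edges_path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            edges.append(
                KGEdge(
                    edge_id=f"{row['relation']}:{row['from']}->{row['to']}",
                    from_node=row["from"],
                    to_node=row["to"],
                    relation=row["relation"],
                    weight=float(row["weight"]) if row["weight"] else None,
                )
            )
    conditions = [n for n in nodes.values() if n.kind == "condition"]
    sources = frozenset(n.source for n in nodes.values())
    return KnowledgeGraph(
        nodes=nodes,
        edges=edges,
        condition_id=conditions[0].node_id.split(":", 2)[2] if conditions else "",
        source="+".join(sorted(sources)),
        sources=sources,
    )
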