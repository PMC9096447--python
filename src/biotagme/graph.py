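"""Typed knowledge graph: assembly, queries, incremental updates.

Nodes are biological entities; each unordered node pair can carry up to
three typed edges: a BIOTAGME edge (predicted, weighted by the BioTG
score and backed by supporting documents), a STRING edge (protein
association with its combined score) and a LITERATURE edge (present in at
least one curated database, with the contributing origins recorded).
Queries are the echo network (seed plus its top-n scored neighbours) and
minimum-hop shortest paths; updates fold a dated document batch into the
graph, re-projecting scores locally over the supporting documents.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import logging
from collections import defaultdict, deque
from typing import Iterable, Sequence

from .annotator import Annotation, AnnotationParams, annotate_corpus
from .corpus import Document, ReferenceEdge, SynonymTable
from .errors import IntegrityError, LookupFailure, ValidationError
from .scoring import (
    ScoredPair,
    ScoringConfig,
    biotagme_score,
    bipartite_from_mentions,
    dthybrid_scores,
    make_relatedness,
    supporting_documents,
)
from .wiki import WikiSnapshot

logger = logging.getLogger(__name__)


class NodeType(str, enum.Enum):
    GENE = "GENE"
    PROTEIN = "PROTEIN"
    DISEASE = "DISEASE"
    DRUG = "DRUG"
    MIRNA = "MIRNA"
    LNCRNA = "LNCRNA"
    PATHWAY = "PATHWAY"
    ENZYME = "ENZYME"
    OTHER = "OTHER"


class EdgeType(str, enum.Enum):
    BIOTAGME = "BIOTAGME"
    LITERATURE = "LITERATURE"
    STRING = "STRING"


#: node type implied by the database a name first appears in
ORIGIN_TYPES: dict[str, NodeType] = {
    "DisGeNET": NodeType.DISEASE,
    "DiseaseOntology": NodeType.DISEASE,
    "DiseaseEnhancer": NodeType.DISEASE,
    "DrugBank": NodeType.DRUG,
    "PharmGKB": NodeType.DRUG,
    "HGNC": NodeType.GENE,
    "ENSEMBL": NodeType.GENE,
    "LNCipedia": NodeType.LNCRNA,
    "miRcode": NodeType.MIRNA,
    "miRBase": NodeType.MIRNA,
    "miRTarBase": NodeType.MIRNA,
    "miRCancer": NodeType.MIRNA,
    "Reactome": NodeType.PATHWAY,
    "PathBank": NodeType.PATHWAY,
    "UniProt": NodeType.PROTEIN,
    "STRING": NodeType.PROTEIN,
    "BRENDA": NodeType.ENZYME,
}


@dataclasses.dataclass(frozen=True)
class Node:
    node_id: int
    name: str
    wiki_page_id: int | None = None
    type: NodeType = NodeType.OTHER
    aliases: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("node name must be non-empty")


@dataclasses.dataclass(frozen=True)
class Edge:
    source: int
    target: int
    edge_type: EdgeType
    biotagme_score: float | None = None
    string_score: float | None = None
    literature_flag: int = 0
    doc_ids: frozenset[str] = frozenset()
    origins: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValidationError("self-loop edges are not allowed")
        if self.source > self.target:
            raise ValidationError("edge endpoints must be ordered source < target")
        if self.edge_type is EdgeType.BIOTAGME and self.biotagme_score is None:
            raise ValidationError("BIOTAGME edge requires biotagme_score")
        if self.edge_type is EdgeType.STRING and self.string_score is None:
            raise ValidationError("STRING edge requires string_score")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.source, self.target)


class KnowledgeGraph:
    """Nodes plus at most one edge per (pair, edge type).

    ``doc_mentions`` retains which entity pages each document contributed,
    so incremental updates can re-project scores over the union of a
    pair's supporting documents.
    """

    def __init__(self, build_date: datetime.date | None = None):
        self.nodes: dict[int, Node] = {}
        self.edges: dict[tuple[int, int, EdgeType], Edge] = {}
        self.build_date = build_date
        self.doc_mentions: dict[str, frozenset[int]] = {}
        self._name_index: dict[str, int] = {}

    # -- construction -----------------------------------------------------

    def add_node(self, node: Node) -> None:
        if node.node_id in self.nodes:
            raise IntegrityError(f"duplicate node_id {node.node_id}")
        self.nodes[node.node_id] = node
        self._name_index[node.name.casefold()] = node.node_id
        for alias in node.aliases:
            self._name_index.setdefault(alias.casefold(), node.node_id)

    def replace_node(self, node: Node) -> None:
        self.nodes[node.node_id] = node
        self._name_index[node.name.casefold()] = node.node_id
        for alias in node.aliases:
            self._name_index.setdefault(alias.casefold(), node.node_id)

    def add_edge(self, edge: Edge) -> None:
        if edge.source not in self.nodes or edge.target not in self.nodes:
            raise IntegrityError("edge endpoints must exist as nodes")
        self.edges[(edge.source, edge.target, edge.edge_type)] = edge

    # -- access -----------------------------------------------------------

    def resolve_name(self, name: str) -> int:
        try:
            return self._name_index[name.casefold()]
        except KeyError:
            raise LookupFailure(f"unknown entity name {name!r}") from None

    def edges_between(self, u: int, v: int) -> list[Edge]:
        a, b = min(u, v), max(u, v)
        return [self.edges[(a, b, t)] for t in EdgeType if (a, b, t) in self.edges]

    def neighbors(self, node_id: int) -> dict[int, list[Edge]]:
        out: dict[int, list[Edge]] = defaultdict(list)
        for (u, v, _t), edge in self.edges.items():
            if u == node_id:
                out[v].append(edge)
            elif v == node_id:
                out[u].append(edge)
        return dict(out)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def copy(self) -> "KnowledgeGraph":
        clone = KnowledgeGraph(build_date=self.build_date)
        clone.nodes = dict(self.nodes)
        clone.edges = dict(self.edges)
        clone.doc_mentions = dict(self.doc_mentions)
        clone._name_index = dict(self._name_index)
        return clone

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.doc_mentions == other.doc_mentions
        )


# ---------------------------------------------------------------------------
# assembly


def build_graph(
    predictions: Sequence[ScoredPair],
    literature: Sequence[ReferenceEdge],
    string_edges: Sequence[ReferenceEdge],
    aliases: SynonymTable,
    annotations: Sequence[Annotation],
    wiki: WikiSnapshot | None = None,
    build_date: datetime.date | None = None,
) -> KnowledgeGraph:
    """Merge predicted pairs with curated reference edges into one graph.

    Nodes are matched by canonical name (via the synonym table); a pair
    may carry up to all three edge types.  A name seen only in a reference
    database still becomes a node, typed after its origin; entities seen
    only via annotation default to OTHER.
    """
    graph = KnowledgeGraph(build_date=build_date)
    support = supporting_documents(annotations)

    def canonical(name: str) -> str:
        return aliases.canonical_of(name) or name

    def page_name(pid: int) -> str:
        return canonical(wiki.title_of(pid)) if wiki is not None else str(pid)

    next_id = 0
    by_name: dict[str, int] = {}

    def ensure_node(name: str, page_id: int | None, node_type: NodeType) -> int:
        nonlocal next_id
        key = name.casefold()
        if key in by_name:
            nid = by_name[key]
            node = graph.nodes[nid]
            updated = node
            if node.type is NodeType.OTHER and node_type is not NodeType.OTHER:
                updated = dataclasses.replace(updated, type=node_type)
            if node.wiki_page_id is None and page_id is not None:
                updated = dataclasses.replace(updated, wiki_page_id=page_id)
            if updated is not node:
                graph.replace_node(updated)
            return nid
        nid = next_id
        next_id += 1
        node = Node(
            node_id=nid,
            name=name,
            wiki_page_id=page_id,
            type=node_type,
            aliases=aliases.aliases_of(name),
        )
        graph.add_node(node)
        by_name[key] = nid
        return nid

    # predicted entities first, in page-id order, so ids are deterministic
    predicted_pages = sorted({p for pred in predictions for p in pred.pair})
    for pid in predicted_pages:
        ensure_node(page_name(pid), pid, NodeType.OTHER)

    for edge in literature:
        for name in (edge.source_name, edge.target_name):
            ensure_node(canonical(name), None, ORIGIN_TYPES.get(edge.origin, NodeType.OTHER))
    for edge in string_edges:
        for name in (edge.source_name, edge.target_name):
            ensure_node(canonical(name), None, ORIGIN_TYPES.get(edge.origin, NodeType.OTHER))

    for pred in predictions:
        u = by_name[page_name(pred.entity_i).casefold()]
        v = by_name[page_name(pred.entity_j).casefold()]
        a, b = min(u, v), max(u, v)
        graph.add_edge(
            Edge(
                source=a,
                target=b,
                edge_type=EdgeType.BIOTAGME,
                biotagme_score=pred.biotg,
                doc_ids=frozenset(support.get(pred.pair, ())),
            )
        )

    lit_pairs: dict[tuple[int, int], set[str]] = defaultdict(set)
    for edge in literature:
        u = by_name[canonical(edge.source_name).casefold()]
        v = by_name[canonical(edge.target_name).casefold()]
        if u == v:
            continue
        lit_pairs[(min(u, v), max(u, v))].add(edge.origin)
    for (a, b), origins in sorted(lit_pairs.items()):
        graph.add_edge(
            Edge(
                source=a,
                target=b,
                edge_type=EdgeType.LITERATURE,
                literature_flag=1,
                origins=frozenset(origins),
            )
        )

    string_pairs: dict[tuple[int, int], float] = {}
    for edge in string_edges:
        u = by_name[canonical(edge.source_name).casefold()]
        v = by_name[canonical(edge.target_name).casefold()]
        if u == v:
            continue
        key = (min(u, v), max(u, v))
        score = edge.score if edge.score is not None else 0.0
        string_pairs[key] = max(string_pairs.get(key, 0.0), score)
    for (a, b), score in sorted(string_pairs.items()):
        graph.add_edge(
            Edge(
                source=a,
                target=b,
                edge_type=EdgeType.STRING,
                string_score=score,
                origins=frozenset({"STRING"}),
            )
        )

    per_doc: dict[str, set[int]] = defaultdict(set)
    for a in annotations:
        per_doc[a.doc_id].add(a.page_id)
    graph.doc_mentions = {doc: frozenset(pages) for doc, pages in per_doc.items()}
    return graph


# ---------------------------------------------------------------------------
# queries


def _edge_rank_score(edge: Edge) -> float:
    return max(
        edge.biotagme_score or 0.0,
        edge.string_score or 0.0,
        float(edge.literature_flag),
    )


def echo_network(
    graph: KnowledgeGraph,
    name: str,
    source_type: NodeType | None = None,
    neighbor_types: Iterable[NodeType] | None = None,
    n: int = 30,
) -> KnowledgeGraph:
    """Seed node plus its top-n neighbours of the requested types.

    Neighbours rank by the best evidence on any edge to the seed
    (max of BioTG score, STRING score, literature flag), ties by node id.
    ``n`` must lie in [10, 200].
    """
    if not (10 <= n <= 200):
        raise ValidationError("n must lie in [10, 200]")
    seed_id = graph.resolve_name(name)
    seed = graph.nodes[seed_id]
    if source_type is not None and seed.type is not source_type:
        raise LookupFailure(f"entity {name!r} is not of type {source_type.value}")

    wanted = set(neighbor_types) if neighbor_types is not None else None
    ranked: list[tuple[float, int]] = []
    for neighbor_id, edges in graph.neighbors(seed_id).items():
        if wanted is not None and graph.nodes[neighbor_id].type not in wanted:
            continue
        ranked.append((max(_edge_rank_score(e) for e in edges), neighbor_id))
    ranked.sort(key=lambda item: (-item[0], item[1]))
    selected = {seed_id} | {nid for _, nid in ranked[:n]}

    sub = KnowledgeGraph(build_date=graph.build_date)
    for nid in sorted(selected):
        sub.add_node(graph.nodes[nid])
    for (u, v, _t), edge in sorted(graph.edges.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)):
        if u in selected and v in selected:
            sub.add_edge(edge)
    return sub


def shortest_path(
    graph: KnowledgeGraph,
    src_name: str,
    src_type: NodeType | None = None,
    dst_name: str = "",
    dst_type: NodeType | None = None,
) -> list[tuple[Node, Edge | None]]:
    """Minimum-hop undirected path; deterministic among equal-hop paths.

    All edge types are traversable.  Among minimum-hop paths the one with
    the lexicographically smallest node-id sequence is returned; each step
    carries one representative edge (fixed edge-type order).  Returns []
    when the endpoints are disconnected.
    """
    src = graph.resolve_name(src_name)
    dst = graph.resolve_name(dst_name)
    for nid, wanted in ((src, src_type), (dst, dst_type)):
        if wanted is not None and graph.nodes[nid].type is not wanted:
            raise LookupFailure(f"node {graph.nodes[nid].name!r} is not of type {wanted.value}")
    if src == dst:
        return [(graph.nodes[src], None)]

    adjacency: dict[int, set[int]] = defaultdict(set)
    for u, v, _t in graph.edges:
        adjacency[u].add(v)
        adjacency[v].add(u)

    # BFS from the destination gives distances; a greedy walk from the
    # source picking the smallest-id neighbour one hop closer then yields
    # the lexicographically smallest minimum-hop node sequence.
    dist = {dst: 0}
    queue = deque([dst])
    while queue:
        node = queue.popleft()
        for nxt in adjacency[node]:
            if nxt not in dist:
                dist[nxt] = dist[node] + 1
                queue.append(nxt)
    if src not in dist:
        return []

    path: list[tuple[Node, Edge | None]] = [(graph.nodes[src], None)]
    current = src
    while current != dst:
        step = min(n for n in adjacency[current] if dist.get(n, -1) == dist[current] - 1)
        edge = graph.edges_between(current, step)[0]
        path.append((graph.nodes[step], edge))
        current = step
    return path


def edge_provenance(graph: KnowledgeGraph, edge: Edge) -> dict:
    """Pair-level provenance record for one edge of the graph.

    Collects, across all typed edges of the pair: both endpoint names and
    wiki page ids, the BioTG and STRING scores, the literature-evidence
    bit (1 iff a curated database reports the pair) and the supporting
    documents of the prediction.
    """
    if (edge.source, edge.target, edge.edge_type) not in graph.edges:
        raise LookupFailure("edge not in graph")
    pair_edges = {e.edge_type: e for e in graph.edges_between(edge.source, edge.target)}
    biotg = pair_edges.get(EdgeType.BIOTAGME)
    string = pair_edges.get(EdgeType.STRING)
    literature = pair_edges.get(EdgeType.LITERATURE)
    src, dst = graph.nodes[edge.source], graph.nodes[edge.target]
    return {
        "source_name": src.name,
        "target_name": dst.name,
        "source_wiki_page_id": src.wiki_page_id,
        "target_wiki_page_id": dst.wiki_page_id,
        "biotagme_score": biotg.biotagme_score if biotg else None,
        "string_score": string.string_score if string else None,
        "literature_evidence": 1 if literature else 0,
        "doc_ids": sorted(biotg.doc_ids) if biotg else [],
        "origins": sorted((literature.origins if literature else frozenset()) | (string.origins if string else frozenset())),
    }


# ---------------------------------------------------------------------------
# incremental update


@dataclasses.dataclass(frozen=True)
class UpdateConfig:
    """Parameters of an incremental update run.

    ``global_reprojection`` switches from the local re-scoring (only the
    sub-network of each affected pair's supporting documents) to a full
    re-projection over every known document.
    """

    annotation: AnnotationParams = AnnotationParams()
    scoring: ScoringConfig = ScoringConfig()
    global_reprojection: bool = False


def update_graph(
    base: KnowledgeGraph,
    new_docs: Sequence[Document],
    mindate: datetime.date,
    maxdate: datetime.date,
    wiki: WikiSnapshot,
    config: UpdateConfig = UpdateConfig(),
) -> KnowledgeGraph:
    """Fold a dated batch of documents into the graph incrementally.

    Documents outside [mindate, maxdate] (or undated) are ignored.  The
    batch is annotated and its co-occurring pairs re-scored over the union
    of old and new supporting documents; doc_ids are unioned, new entities
    get fresh node ids, and the merge is idempotent.
    """
    if mindate > maxdate:
        raise ValidationError("mindate must not exceed maxdate")
    selected = [d for d in new_docs if d.date is not None and mindate <= d.date <= maxdate]
    if not selected:
        logger.info("update: no documents in [%s, %s]; graph unchanged", mindate, maxdate)
        return base

    annotations = annotate_corpus(selected, wiki, config.annotation)
    graph = base.copy()
    graph.build_date = maxdate

    merged: dict[str, frozenset[int]] = dict(graph.doc_mentions)
    delta_mentions: dict[str, set[int]] = defaultdict(set)
    for a in annotations:
        delta_mentions[a.doc_id].add(a.page_id)
    for doc_id, pages in delta_mentions.items():
        merged[doc_id] = frozenset(merged.get(doc_id, frozenset()) | pages)
    graph.doc_mentions = merged

    # new entities get fresh node ids, appended in page-id order
    known_pages = {n.wiki_page_id for n in graph.nodes.values() if n.wiki_page_id is not None}
    known_names = {n.name.casefold() for n in graph.nodes.values()}
    new_pages = sorted(
        {p for pages in delta_mentions.values() for p in pages
         if p not in known_pages and wiki.title_of(p).casefold() not in known_names}
    )
    next_id = max(graph.nodes, default=-1) + 1
    for pid in new_pages:
        graph.add_node(Node(node_id=next_id, name=wiki.title_of(pid), wiki_page_id=pid))
        next_id += 1
    page_to_node = {n.wiki_page_id: n.node_id for n in graph.nodes.values() if n.wiki_page_id is not None}

    affected = set(supporting_documents(annotations))
    rel = make_relatedness(wiki)
    if config.global_reprojection:
        net = bipartite_from_mentions(merged)
        all_scores = dthybrid_scores(net, config.scoring)
        score_of = lambda pair: all_scores.get(pair, 0.0)  # noqa: E731
    else:
        def score_of(pair: tuple[int, int]) -> float:
            union_docs = [d for d, pages in merged.items() if pair[0] in pages and pair[1] in pages]
            sub = bipartite_from_mentions(merged, union_docs)
            return dthybrid_scores(sub, config.scoring).get(pair, 0.0)

    for pair in sorted(affected):
        i, j = pair
        if i not in page_to_node or j not in page_to_node:
            continue
        s = score_of(pair)
        if s <= 0:
            continue
        biotg = biotagme_score(s, rel(i, j))
        if biotg < config.scoring.min_biotg:
            continue
        u, v = page_to_node[i], page_to_node[j]
        a, b = min(u, v), max(u, v)
        union_docs = frozenset(d for d, pages in merged.items() if i in pages and j in pages)
        existing = graph.edges.get((a, b, EdgeType.BIOTAGME))
        doc_ids = union_docs | (existing.doc_ids if existing else frozenset())
        graph.add_edge(
            Edge(source=a, target=b, edge_type=EdgeType.BIOTAGME, biotagme_score=biotg, doc_ids=doc_ids)
        )
    return graph


__all__ = [
    "NodeType",
    "EdgeType",
    "ORIGIN_TYPES",
    "Node",
    "Edge",
    "KnowledgeGraph",
    "build_graph",
    "echo_network",
    "shortest_path",
    "edge_provenance",
    "UpdateConfig",
    "update_graph",
]
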