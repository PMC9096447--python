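"""Corpus and reference-database I/O.

Documents are carried as JSON Lines (one record per line with keys
``doc_id``, ``title``, ``abstract``, ``date``).  Sentence-level exports of
PubMed-style records (title/abstract split into numbered sentences) are
aggregated back into whole documents.  Reference edge sets from curated
databases are read from TSV and harmonized onto a shared nomenclature via a
synonym table, mirroring how heterogeneous sources (DisGeNET, DrugBank,
STRING, ...) name the same biological entity differently.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

from .errors import IntegrityError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: sections of a PubMed-like record a sentence can belong to
SECTIONS = ("TI", "AB")


@dataclasses.dataclass(frozen=True)
class Document:
    """One PubMed-like record: identifier, title, abstract and date.

    ``date`` is None when absent or unparseable; such documents are skipped
    by date-range incremental updates.
    """

    doc_id: str
    title: str = ""
    abstract: str = ""
    date: datetime.date | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("doc_id must be non-empty")

    @property
    def ti_ab(self) -> str:
        """Title and abstract joined: the unit of annotation."""
        return f"{self.title} {self.abstract}".strip()


@dataclasses.dataclass(frozen=True)
class SentenceRow:
    """One sentence of a sentence-table export."""

    doc_id: str
    section: str  # "TI" or "AB"
    sentence_index: int  # 1-based
    text: str

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise ValidationError(f"section must be one of {SECTIONS}, got {self.section!r}")
        if self.sentence_index < 1:
            raise ValidationError("sentence_index must be >= 1")


@dataclasses.dataclass(frozen=True)
class ReferenceEdge:
    """A curated relation between two named entities from one database.

    ``score`` is present exactly for STRING edges (their combined
    interaction score in [0,1]); curated literature databases carry none.
    """

    source_name: str
    target_name: str
    origin: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.origin:
            raise ValidationError("origin must be non-empty")
        if self.source_name == self.target_name:
            raise ValidationError("reference edge endpoints must differ")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0,1]")


class SynonymTable:
    """Maps alias names (case-insensitively) to a canonical entity name.

    Alias sets of distinct canonicals must be disjoint after case-folding;
    when two sources claim the same alias for different canonicals the
    first-loaded claim wins and the conflict is logged.
    """

    def __init__(self, aliases: dict[str, Iterable[str]] | None = None):
        self._canonical_to_aliases: dict[str, set[str]] = {}
        self._lookup: dict[str, str] = {}  # casefolded name -> canonical
        if aliases:
            for canonical, names in aliases.items():
                self.add(canonical, names)

    def add(self, canonical: str, aliases: Iterable[str] = ()) -> None:
        key = canonical.casefold()
        if key in self._lookup and self._lookup[key] != canonical:
            logger.warning(
                "synonym conflict: %r already maps to %r; keeping first", canonical, self._lookup[key]
            )
            return
        self._lookup.setdefault(key, canonical)
        bucket = self._canonical_to_aliases.setdefault(canonical, set())
        for alias in aliases:
            akey = alias.casefold()
            if akey == key:
                continue
            if akey in self._lookup and self._lookup[akey] != canonical:
                logger.warning(
                    "synonym conflict: alias %r claimed by %r and %r; keeping first",
                    alias, self._lookup[akey], canonical,
                )
                continue
            self._lookup[akey] = canonical
            bucket.add(alias)

    def canonical_of(self, name: str) -> str | None:
        """Canonical form of ``name`` or None when unknown."""
        return self._lookup.get(name.casefold())

    def aliases_of(self, canonical: str) -> frozenset[str]:
        return frozenset(self._canonical_to_aliases.get(canonical, ()))

    @property
    def canonicals(self) -> list[str]:
        return sorted(self._canonical_to_aliases)

    def __len__(self) -> int:
        return len(self._canonical_to_aliases)


# ---------------------------------------------------------------------------
# documents


def _parse_date(raw: object) -> datetime.date | None:
    if raw in (None, ""):
        return None
    try:
        return datetime.date.fromisoformat(str(raw))
    except ValueError:
        return None


def read_documents(path: str | Path) -> list[Document]:
    """Read a JSON Lines corpus, one record per line, in file order.

    Raises :class:`ParseError` naming the line on malformed JSON and
    :class:`IntegrityError` on duplicate doc_id.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            if not isinstance(record, dict) or "doc_id" not in record:
                raise ParseError(f"{path}: line {lineno} is not a document record")
            doc_id = str(record["doc_id"])
            if doc_id in seen:
                raise IntegrityError(f"{path}: duplicate doc_id {doc_id!r} on line {lineno}")
            seen.add(doc_id)
            docs.append(
                Document(
                    doc_id=doc_id,
                    title=record.get("title") or "",
                    abstract=record.get("abstract") or "",
                    date=_parse_date(record.get("date")),
                )
            )
    return docs


def write_documents(docs: Iterable[Document], path: str | Path) -> None:
    """Write documents as JSON Lines, one record per line."""
    with open(path, "w", encoding="utf-8") as handle:
        for doc in docs:
            handle.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "title": doc.title,
                        "abstract": doc.abstract,
                        "date": doc.date.isoformat() if doc.date else None,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_sentence_rows(path: str | Path) -> list[SentenceRow]:
    """Read a sentence-table export (TSV: doc_id, section, sentence_index, text)."""
    rows: list[SentenceRow] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for lineno, record in enumerate(reader, start=2):
            try:
                rows.append(
                    SentenceRow(
                        doc_id=record["doc_id"],
                        section=record["section"],
                        sentence_index=int(record["sentence_index"]),
                        text=record.get("text") or "",
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}: bad sentence row on line {lineno}: {exc}") from exc
    return rows


def aggregate_sentences(rows: Sequence[SentenceRow]) -> list[Document]:
    """Re-assemble whole documents from sentence-level rows.

    Sentences of a section are joined with a single space in
    ``sentence_index`` order; documents are emitted in lexicographic doc_id
    order.  A gap in the index sequence is tolerated (logged) and the join
    proceeds over the rows that are present.
    """
    seen: set[tuple[str, str, int]] = set()
    per_doc: dict[str, dict[str, list[tuple[int, str]]]] = defaultdict(
        lambda: {"TI": [], "AB": []}
    )
    for row in rows:
        key = (row.doc_id, row.section, row.sentence_index)
        if key in seen:
            raise IntegrityError(f"duplicate sentence row {key}")
        seen.add(key)
        per_doc[row.doc_id][row.section].append((row.sentence_index, row.text))

    docs: list[Document] = []
    for doc_id in sorted(per_doc):
        parts = {}
        for section in SECTIONS:
            entries = sorted(per_doc[doc_id][section])
            indices = [i for i, _ in entries]
            if entries and indices != list(range(1, len(entries) + 1)):
                logger.warning("doc %s section %s has sentence-index gaps: %s", doc_id, section, indices)
            parts[section] = " ".join(text for _, text in entries)
        docs.append(Document(doc_id=doc_id, title=parts["TI"], abstract=parts["AB"]))
    return docs


# ---------------------------------------------------------------------------
# reference edges and harmonization


def read_reference_edges(path: str | Path, origin: str) -> list[ReferenceEdge]:
    """Read a TSV of reference edges (header: source, target[, score])."""
    edges: list[ReferenceEdge] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for lineno, record in enumerate(reader, start=2):
            score: float | None = None
            if record.get("score") not in (None, ""):
                score = float(record["score"])
                if not (0.0 <= score <= 1.0):
                    raise ValidationError(f"{path}: line {lineno}: score {score} outside [0,1]")
            edges.append(
                ReferenceEdge(
                    source_name=record["source"],
                    target_name=record["target"],
                    origin=origin,
                    score=score,
                )
            )
    return edges


def write_reference_edges(edges: Iterable[ReferenceEdge], path: str | Path) -> None:
    edges = list(edges)
    with_score = any(e.score is not None for e in edges)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "score"] if with_score else ["source", "target"])
        for e in edges:
            row = [e.source_name, e.target_name]
            if with_score:
                row.append("" if e.score is None else repr(e.score))
            writer.writerow(row)


def harmonize_names(
    records: Sequence[ReferenceEdge], synonyms: SynonymTable
) -> list[ReferenceEdge]:
    """Rewrite edge endpoints onto canonical nomenclature.

    Names are matched case-insensitively against the synonym table; unmapped
    names are kept verbatim (and tallied in the log).  Edges whose endpoints
    collapse onto one canonical entity are dropped, and exact duplicates
    (same canonical pair + origin) are collapsed to one.  Idempotent.
    """
    unmapped = 0
    out: list[ReferenceEdge] = []
    seen: set[tuple[str, str, str]] = set()
    for edge in records:
        names = []
        for name in (edge.source_name, edge.target_name):
            canonical = synonyms.canonical_of(name)
            if canonical is None:
                unmapped += 1
                canonical = name
            names.append(canonical)
        src, dst = names
        if src == dst:
            continue
        key = (min(src, dst), max(src, dst), edge.origin)
        if key in seen:
            continue
        seen.add(key)
        out.append(dataclasses.replace(edge, source_name=src, target_name=dst))
    if unmapped:
        logger.info("harmonize_names: %d names had no canonical mapping", unmapped)
    return out


def read_synonyms(path: str | Path) -> SynonymTable:
    """Read a synonym table (TSV: canonical, alias; one alias per row).

    A row with an empty alias registers a canonical with no aliases.
    """
    table = SynonymTable()
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for record in reader:
            alias = record.get("alias") or ""
            table.add(record["canonical"], [alias] if alias else [])
    return table


# ---------------------------------------------------------------------------
# knowledge-graph tables

NODES_CSV = "nodes.csv"
EDGES_CSV = "edges.csv"
ALIASES_CSV = "Name_Aliases.csv"
GRAPHML = "graph.graphml"
MENTIONS_JSON = "doc_mentions.json"
META_JSON = "meta.json"


def write_graph(graph, directory: str | Path) -> list[Path]:
    """Persist a knowledge graph as csv tables plus a GraphML export.

    Writes nodes.csv, edges.csv and Name_Aliases.csv (RFC-4180), a
    graph.graphml rendering, the doc_id→pages mention map (JSON, needed by
    incremental updates) and a small meta.json.  Re-reading with
    :func:`read_graph` reproduces an isomorphic graph.  Row order and
    float formatting are deterministic so identical graphs serialize to
    identical bytes.
    """
    import networkx as nx

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def fmt(value: float | None) -> str:
        return "" if value is None else repr(value)

    nodes_path = directory / NODES_CSV
    with open(nodes_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["node_id", "name", "type", "wiki_page_id"])
        for nid in sorted(graph.nodes):
            node = graph.nodes[nid]
            writer.writerow([nid, node.name, node.type.value, "" if node.wiki_page_id is None else node.wiki_page_id])
    written.append(nodes_path)

    edges_path = directory / EDGES_CSV
    with open(edges_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(
            ["source_id", "target_id", "edge_type", "biotagme_score", "string_score", "literature_flag", "doc_ids", "origins"]
        )
        for key in sorted(graph.edges, key=lambda k: (k[0], k[1], k[2].value)):
            edge = graph.edges[key]
            writer.writerow(
                [
                    edge.source,
                    edge.target,
                    edge.edge_type.value,
                    fmt(edge.biotagme_score),
                    fmt(edge.string_score),
                    edge.literature_flag,
                    "|".join(sorted(edge.doc_ids)),
                    "|".join(sorted(edge.origins)),
                ]
            )
    written.append(edges_path)

    aliases_path = directory / ALIASES_CSV
    with open(aliases_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["node_id", "alias"])
        for nid in sorted(graph.nodes):
            for alias in sorted(graph.nodes[nid].aliases):
                writer.writerow([nid, alias])
    written.append(aliases_path)

    multigraph = nx.MultiGraph()
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        multigraph.add_node(nid, name=node.name, type=node.type.value)
    for key in sorted(graph.edges, key=lambda k: (k[0], k[1], k[2].value)):
        edge = graph.edges[key]
        attrs = {"edge_type": edge.edge_type.value, "literature_flag": edge.literature_flag}
        if edge.biotagme_score is not None:
            attrs["biotagme_score"] = edge.biotagme_score
        if edge.string_score is not None:
            attrs["string_score"] = edge.string_score
        multigraph.add_edge(edge.source, edge.target, key=edge.edge_type.value, **attrs)
    graphml_path = directory / GRAPHML
    nx.write_graphml(multigraph, graphml_path)
    written.append(graphml_path)

    mentions_path = directory / MENTIONS_JSON
    mentions_path.write_text(
        json.dumps({doc: sorted(pages) for doc, pages in sorted(graph.doc_mentions.items())}, sort_keys=True)
        + "\n",
        encoding="utf-8",
    )
    written.append(mentions_path)

    meta_path = directory / META_JSON
    meta_path.write_text(
        json.dumps({"build_date": graph.build_date.isoformat() if graph.build_date else None}) + "\n",
        encoding="utf-8",
    )
    written.append(meta_path)
    return written


def read_graph(directory: str | Path):
    """Rebuild a knowledge graph from the tables written by write_graph."""
    from .graph import Edge, EdgeType, KnowledgeGraph, Node, NodeType

    directory = Path(directory)
    aliases: dict[int, set[str]] = defaultdict(set)
    alias_path = directory / ALIASES_CSV
    if alias_path.exists():
        with open(alias_path, encoding="utf-8", newline="") as handle:
            for record in csv.DictReader(handle):
                aliases[int(record["node_id"])].add(record["alias"])

    build_date = None
    meta_path = directory / META_JSON
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        build_date = _parse_date(meta.get("build_date"))

    graph = KnowledgeGraph(build_date=build_date)
    with open(directory / NODES_CSV, encoding="utf-8", newline="") as handle:
        for record in csv.DictReader(handle):
            nid = int(record["node_id"])
            graph.add_node(
                Node(
                    node_id=nid,
                    name=record["name"],
                    type=NodeType(record["type"]),
                    wiki_page_id=int(record["wiki_page_id"]) if record["wiki_page_id"] else None,
                    aliases=frozenset(aliases.get(nid, ())),
                )
            )
    with open(directory / EDGES_CSV, encoding="utf-8", newline="") as handle:
        for record in csv.DictReader(handle):
            graph.add_edge(
                Edge(
                    source=int(record["source_id"]),
                    target=int(record["target_id"]),
                    edge_type=EdgeType(record["edge_type"]),
                    biotagme_score=float(record["biotagme_score"]) if record["biotagme_score"] else None,
                    string_score=float(record["string_score"]) if record["string_score"] else None,
                    literature_flag=int(record["literature_flag"]),
                    doc_ids=frozenset(d for d in record["doc_ids"].split("|") if d),
                    origins=frozenset(o for o in record["origins"].split("|") if o),
                )
            )
    mentions_path = directory / MENTIONS_JSON
    if mentions_path.exists():
        raw = json.loads(mentions_path.read_text(encoding="utf-8"))
        graph.doc_mentions = {doc: frozenset(pages) for doc, pages in raw.items()}
    return graph


def write_synonyms(table: SynonymTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["canonical", "alias"])
        for canonical in table.canonicals:
            aliases = sorted(table.aliases_of(canonical))
            if not aliases:
                writer.writerow([canonical, ""])
            for alias in aliases:
                writer.writerow([canonical, alias])
    return None
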