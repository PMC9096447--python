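"""Synthetic mini-Wikipedia, corpus and reference sets with planted truth.

The generator emulates the inputs of the full pipeline at desk scale:

* a Wikipedia-like snapshot whose pages split into a biological subtree
  (descending from a "Biology" category root) and a non-biological rest;
* an anchor dictionary in which a configurable fraction of anchors is
  ambiguous between a biological and a non-biological sense, with the
  commonness prior favouring the *wrong* (non-biological) sense so that
  collective disambiguation has work to do;
* a link graph with planted co-citation: the two pages of each planted
  entity pair share most of their in-neighbours, so link-based relatedness
  is high exactly where a relation was planted;
* a corpus of titles/abstracts in which each planted pair is co-mentioned
  in a controlled number of documents, on top of background documents
  mentioning random entities and occasional non-biological noise anchors.

Everything is deterministic given the config seed; sub-generators draw
from child seeds at fixed offsets from it.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from pathlib import Path

import numpy as np

from .corpus import Document, ReferenceEdge, SynonymTable
from .errors import ValidationError
from .wiki import Page, WikiSnapshot

# category ids of the synthetic category graph
BIO_ROOT = 1
_BIO_SUBCATS = (2, 3, 4)  # direct children of the Biology root
_BIO_DEEP = 5  # child of 2: two hops from the root
_GEO_ROOT = 10
_GEO_SUBCAT = 11

_FILLERS = ("the", "of", "and", "in", "with", "for")


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    Defaults are the benchmark conditions used throughout the test-suite:
    50 entities, 200 documents, 40 planted relations each co-mentioned in
    half the corpus share, 10% noise mentions, 20% ambiguous anchors.
    """

    n_pages: int = 120
    n_bio_pages: int = 70
    n_entities: int = 50
    n_docs: int = 200
    n_planted: int = 40
    cooccur_rate: float = 0.5
    noise_mention_rate: float = 0.1
    ambiguity_rate: float = 0.2
    seed: int = 7

    def __post_init__(self) -> None:
        counts = (self.n_pages, self.n_bio_pages, self.n_entities, self.n_docs, self.n_planted)
        if any(c <= 0 for c in counts):
            raise ValidationError("all counts must be positive")
        if self.n_bio_pages > self.n_pages:
            raise ValidationError("n_bio_pages cannot exceed n_pages")
        if self.n_entities > self.n_bio_pages:
            raise ValidationError("entities are biological pages: n_entities <= n_bio_pages")
        if self.n_pages - self.n_entities < 8:
            raise ValidationError("need at least 8 non-entity pages as link hubs")
        if self.n_planted > self.n_entities * (self.n_entities - 1) // 2:
            raise ValidationError("n_planted exceeds the number of entity pairs")
        if not (0.0 < self.cooccur_rate <= 1.0):
            raise ValidationError("cooccur_rate must lie in (0,1]")
        if not (0.0 <= self.noise_mention_rate < 1.0):
            raise ValidationError("noise_mention_rate must lie in [0,1)")
        if not (0.0 <= self.ambiguity_rate <= 1.0):
            raise ValidationError("ambiguity_rate must lie in [0,1]")
        docs_needed = self.n_planted * math.ceil(self.cooccur_rate * self.n_docs / self.n_planted)
        if docs_needed > self.n_docs:
            raise ValidationError("cooccur_rate requires more co-occurrence documents than n_docs")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: relations and intended mentions."""

    planted_pairs: frozenset[tuple[int, int]]
    mention_map: dict[str, frozenset[int]]


def entity_pages(config: SynthConfig) -> list[int]:
    """Page ids of the entity pages (a prefix of the biological pages)."""
    return list(range(1, config.n_entities + 1))


def _entity_title(page_id: int) -> str:
    # alternate one- and two-token titles so spotting exercises n-grams
    return f"BFG{page_id}" if page_id % 2 == 0 else f"Factor {page_id}"


def entity_anchor(page_id: int) -> str:
    return _entity_title(page_id).lower()


def planted_pairs(config: SynthConfig) -> list[tuple[int, int]]:
    """The planted relations, derived from the config seed alone."""
    rng = np.random.default_rng(config.seed)
    entities = entity_pages(config)
    all_pairs = [
        (entities[i], entities[j])
        for i in range(len(entities))
        for j in range(i + 1, len(entities))
    ]
    idx = rng.choice(len(all_pairs), size=config.n_planted, replace=False)
    return [all_pairs[k] for k in sorted(idx)]


def generate_wiki(config: SynthConfig) -> WikiSnapshot:
    """Snapshot with a biological subtree and planted co-citation."""
    rng = np.random.default_rng(config.seed + 1)
    n_ent = config.n_entities

    pages: dict[int, Page] = {}
    for pid in range(1, config.n_pages + 1):
        if pid <= n_ent:
            title = _entity_title(pid)
            cats = frozenset({int(rng.choice(_BIO_SUBCATS + (_BIO_DEEP,)))})
        elif pid <= config.n_bio_pages:
            title = f"Process {pid}"
            cats = frozenset({int(rng.choice(_BIO_SUBCATS))})
        else:
            title = f"City {pid}"
            cats = frozenset({_GEO_SUBCAT})
        pages[pid] = Page(page_id=pid, title=title, categories=cats)

    category_parents = {
        **{c: {BIO_ROOT} for c in _BIO_SUBCATS},
        _BIO_DEEP: {_BIO_SUBCATS[0]},
        _GEO_SUBCAT: {_GEO_ROOT},
    }
    category_names = {
        BIO_ROOT: "Biology",
        _GEO_ROOT: "Geography",
        **{c: f"Biology subfield {c}" for c in _BIO_SUBCATS},
        _BIO_DEEP: "Biology subsubfield",
        _GEO_SUBCAT: "Cities",
    }

    # Link graph: hubs (non-entity pages) cite entities; the two members of
    # a planted pair share a block of hub in-neighbours (co-citation).
    hubs = list(range(n_ent + 1, config.n_pages + 1))
    links: set[tuple[int, int]] = set()
    for i, j in planted_pairs(config):
        common = rng.choice(hubs, size=6, replace=False)
        for h in common:
            links.add((int(h), i))
            links.add((int(h), j))
    for pid in range(1, n_ent + 1):
        for h in rng.choice(hubs, size=2, replace=False):
            links.add((int(h), pid))
    # background structure among non-entity pages
    for h in hubs:
        for t in rng.choice(hubs, size=2, replace=False):
            if int(t) != h:
                links.add((h, int(t)))

    # Anchor dictionary.  Entity anchors get, at ambiguity_rate, a second
    # (non-biological) sense that dominates the commonness prior.
    non_bio = list(range(config.n_bio_pages + 1, config.n_pages + 1))
    anchors: dict[str, dict[int, int]] = {}
    occurrences: dict[str, int] = {}
    n_ambiguous = int(round(config.ambiguity_rate * n_ent))
    ambiguous = set(rng.choice(range(1, n_ent + 1), size=n_ambiguous, replace=False).tolist())
    for pid in range(1, n_ent + 1):
        text = entity_anchor(pid)
        if pid in ambiguous and non_bio:
            other = int(rng.choice(non_bio))
            anchors[text] = {pid: 2, other: 3}
        else:
            anchors[text] = {pid: 4}
        occurrences[text] = sum(anchors[text].values()) + 1
    for pid in non_bio:
        text = pages[pid].title.lower()
        anchors.setdefault(text, {pid: 3})
        occurrences.setdefault(text, 4)

    return WikiSnapshot(
        pages=pages,
        links=links,
        category_parents=category_parents,
        bio_roots=frozenset({BIO_ROOT}),
        anchors=anchors,
        anchor_occurrences=occurrences,
        category_names=category_names,
    )


def generate_corpus(wiki: WikiSnapshot, config: SynthConfig) -> tuple[list[Document], GroundTruth]:
    """Documents embedding anchor texts of intended pages, plus noise.

    Each planted pair is co-mentioned in exactly
    ceil(cooccur_rate * n_docs / n_planted) documents; the remaining
    documents mention 2–4 random entities.  Noise anchors (non-biological
    city pages) are injected per document with probability
    ``noise_mention_rate``.  Dates are uniform over a two-year window.
    """
    rng = np.random.default_rng(config.seed + 2)
    pairs = planted_pairs(config)
    per_pair = math.ceil(config.cooccur_rate * config.n_docs / config.n_planted)
    n_pair_docs = per_pair * len(pairs)

    order = rng.permutation(config.n_docs)
    pair_doc_slots = {int(order[k]): pairs[k % len(pairs)] for k in range(n_pair_docs)}

    entities = entity_pages(config)
    non_bio = [p for p in wiki.pages if p > config.n_bio_pages]
    base_date = datetime.date(2019, 1, 1)

    docs: list[Document] = []
    mention_map: dict[str, frozenset[int]] = {}
    for idx in range(config.n_docs):
        doc_id = str(1000000 + idx)
        if idx in pair_doc_slots:
            i, j = pair_doc_slots[idx]
            intended = {i, j}
            if rng.random() < 0.5:
                intended.add(int(rng.choice(entities)))
        else:
            size = int(rng.integers(2, 5))
            intended = set(rng.choice(entities, size=size, replace=False).tolist())

        phrases = [entity_anchor(p) for p in sorted(intended)]
        if non_bio and rng.random() < config.noise_mention_rate:
            phrases.append(wiki.pages[int(rng.choice(non_bio))].title.lower())
        rng.shuffle(phrases)

        title = phrases[0]
        body: list[str] = []
        for phrase in phrases:
            body.append(phrase)
            body.append(str(rng.choice(_FILLERS)))
        abstract = " ".join(body[:-1])
        date = base_date + datetime.timedelta(days=int(rng.integers(0, 730)))
        docs.append(Document(doc_id=doc_id, title=title, abstract=abstract, date=date))
        mention_map[doc_id] = frozenset(intended)

    truth = GroundTruth(
        planted_pairs=frozenset((min(i, j), max(i, j)) for i, j in pairs),
        mention_map=mention_map,
    )
    return docs, truth


def generate_references(
    wiki: WikiSnapshot, truth: GroundTruth, config: SynthConfig
) -> tuple[list[ReferenceEdge], list[ReferenceEdge], SynonymTable]:
    """Curated-literature and STRING-like edge sets plus a synonym table.

    Even-indexed planted pairs go to curated literature sources (cycling
    over a few database labels), odd-indexed ones to a scored STRING-like
    set.  Some endpoint names are written as aliases so harmonization has
    real work to do.
    """
    rng = np.random.default_rng(config.seed + 3)
    synonyms = SynonymTable()
    for pid in entity_pages(config):
        title = wiki.title_of(pid)
        synonyms.add(title, [f"{title} homolog"])

    def name_of(pid: int) -> str:
        title = wiki.title_of(pid)
        return f"{title} homolog" if rng.random() < 0.3 else title

    lit_origins = ("DisGeNET", "DrugBank", "miRTarBase")
    literature: list[ReferenceEdge] = []
    string_edges: list[ReferenceEdge] = []
    for k, (i, j) in enumerate(sorted(truth.planted_pairs)):
        if k % 2 == 0:
            literature.append(
                ReferenceEdge(
                    source_name=name_of(i),
                    target_name=name_of(j),
                    origin=lit_origins[(k // 2) % len(lit_origins)],
                )
            )
        else:
            string_edges.append(
                ReferenceEdge(
                    source_name=name_of(i),
                    target_name=name_of(j),
                    origin="STRING",
                    score=float(np.round(0.4 + 0.59 * rng.random(), 3)),
                )
            )
    return literature, string_edges, synonyms


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_pairs": sorted([list(p) for p in truth.planted_pairs]),
        "mention_map": {doc: sorted(pages) for doc, pages in sorted(truth.mention_map.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(
        planted_pairs=frozenset((int(i), int(j)) for i, j in payload["planted_pairs"]),
        mention_map={doc: frozenset(pages) for doc, pages in payload["mention_map"].items()},
    )
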