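"""Relationship scoring: relatedness × bipartite projection.

Two signals are combined per entity pair.  The Milne–Witten measure reads
semantic relatedness off the overlap of the pages' in-link sets in the
snapshot.  The degree-tuned hybrid bipartite projection (the ProbS/HeatS
hybrid with exponent λ) scores how strongly two entities are associated
through the documents they are co-annotated in:

    s_raw(i,j) = k_e(i)^-(1-λ) · k_e(j)^-λ · Σ_l a_il a_jl / k_d(l)

symmetrized as (s_raw(i,j) + s_raw(j,i)) / 2.  The predicted edge weight
is the product BioTG = s · r.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import sparse

from .annotator import Annotation
from .errors import ValidationError
from .wiki import WikiSnapshot


@dataclasses.dataclass
class BipartiteNetwork:
    """Binary entity × document incidence built from annotations."""

    entities: list[int]  # page ids, sorted
    documents: list[str]  # doc ids, sorted
    incidence: sparse.csr_matrix  # shape (n_entities, n_documents), 0/1

    @property
    def entity_degree(self) -> np.ndarray:
        return np.asarray(self.incidence.sum(axis=1)).ravel()

    @property
    def doc_degree(self) -> np.ndarray:
        return np.asarray(self.incidence.sum(axis=0)).ravel()

    @property
    def is_empty(self) -> bool:
        return not self.entities


@dataclasses.dataclass(frozen=True)
class ScoredPair:
    """An unordered entity pair with projection score s, relatedness r and
    their product, the BioTAGME score."""

    entity_i: int
    entity_j: int
    s: float
    r: float
    biotg: float

    def __post_init__(self) -> None:
        if self.entity_i >= self.entity_j:
            raise ValidationError("pair must be ordered entity_i < entity_j")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.entity_i, self.entity_j)


@dataclasses.dataclass(frozen=True)
class ScoringConfig:
    """λ tunes the projection between the two degree normalizations
    (0.5 = balanced hybrid); min_biotg thresholds emitted predictions."""

    lambda_: float = 0.5
    min_biotg: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_ <= 1.0):
            raise ValidationError("lambda must lie in [0,1]")
        if self.min_biotg < 0:
            raise ValidationError("min_biotg must be >= 0")


def build_bipartite(annotations: Sequence[Annotation]) -> BipartiteNetwork:
    """Incidence a[i,l] = 1 iff entity i is annotated in document l.

    Duplicate (doc, page) annotations collapse to one cell; zero-degree
    entities cannot occur by construction.
    """
    cells = {(a.page_id, a.doc_id) for a in annotations}
    entities = sorted({pid for pid, _ in cells})
    documents = sorted({doc for _, doc in cells})
    e_index = {pid: i for i, pid in enumerate(entities)}
    d_index = {doc: l for l, doc in enumerate(documents)}
    rows = [e_index[pid] for pid, doc in cells]
    cols = [d_index[doc] for pid, doc in cells]
    incidence = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(entities), len(documents))
    )
    return BipartiteNetwork(entities=entities, documents=documents, incidence=incidence)


def bipartite_from_mentions(
    mentions: dict[str, frozenset[int]] | dict[str, set[int]],
    doc_ids: Iterable[str] | None = None,
) -> BipartiteNetwork:
    """Incidence built from a doc_id → entity-page-set map.

    ``doc_ids`` restricts to a document subset (used by incremental
    updates, which re-project only the sub-network of supporting docs).
    """
    selected = sorted(mentions) if doc_ids is None else sorted(set(doc_ids) & set(mentions))
    cells = {(pid, doc) for doc in selected for pid in mentions[doc]}
    entities = sorted({pid for pid, _ in cells})
    documents = sorted({doc for _, doc in cells})
    e_index = {pid: i for i, pid in enumerate(entities)}
    d_index = {doc: l for l, doc in enumerate(documents)}
    incidence = sparse.csr_matrix(
        (
            np.ones(len(cells)),
            (
                [e_index[pid] for pid, doc in cells],
                [d_index[doc] for pid, doc in cells],
            ),
        ),
        shape=(len(entities), len(documents)),
    )
    return BipartiteNetwork(entities=entities, documents=documents, incidence=incidence)


def relatedness(page_a: int, page_b: int, wiki: WikiSnapshot) -> float:
    """Milne–Witten in-link relatedness, clamped to [0,1].

    With in(x) the in-link set and W the page count:
    1 − [log max(|in(a)|,|in(b)|) − log |in(a)∩in(b)|] /
        [log W − log min(|in(a)|,|in(b)|)].
    Identical pages with in-links score 1; empty intersections score 0.
    """
    in_a = wiki.in_links(page_a)
    in_b = wiki.in_links(page_b)
    if page_a == page_b:
        return 1.0 if in_a else 0.0
    common = len(in_a & in_b)
    if common == 0 or not in_a or not in_b:
        return 0.0
    big, small = max(len(in_a), len(in_b)), min(len(in_a), len(in_b))
    w = wiki.n_pages
    denom = math.log(w) - math.log(small)
    if denom <= 0:
        return 1.0
    raw = 1.0 - (math.log(big) - math.log(common)) / denom
    return max(0.0, min(1.0, raw))


def make_relatedness(wiki: WikiSnapshot) -> Callable[[int, int], float]:
    """Memoized pairwise relatedness over one snapshot."""
    cache: dict[tuple[int, int], float] = {}

    def fn(a: int, b: int) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = relatedness(key[0], key[1], wiki)
        return cache[key]

    return fn


def dthybrid_scores(
    net: BipartiteNetwork, config: ScoringConfig = ScoringConfig()
) -> dict[tuple[int, int], float]:
    """Symmetrized degree-tuned hybrid projection scores.

    Returns {(page_i, page_j): s} for every pair sharing at least one
    document (s > 0 exactly for those pairs).  Sparse throughout: the
    co-occurrence structure, not the n² pair space, is materialized.
    """
    if net.is_empty:
        return {}
    a = net.incidence.tocsr()
    ke = net.entity_degree
    kd = net.doc_degree
    lam = config.lambda_

    # W = A diag(1/kd) A^T holds the resource mass exchanged through docs;
    # zero-degree documents contribute nothing
    inv_kd = sparse.diags(np.divide(1.0, kd, out=np.zeros_like(kd, dtype=float), where=kd > 0))
    w = (a @ inv_kd @ a.T).tocoo()

    left = ke ** -(1.0 - lam)  # applied to rows (entity i)
    right = ke ** -lam  # applied to columns (entity j)
    data = w.data * left[w.row] * right[w.col]
    s_raw = sparse.coo_matrix((data, (w.row, w.col)), shape=w.shape)
    s_sym = ((s_raw + s_raw.T) * 0.5).tocoo()

    scores: dict[tuple[int, int], float] = {}
    for i, j, value in zip(s_sym.row, s_sym.col, s_sym.data):
        if i < j and value > 0:
            scores[(net.entities[i], net.entities[j])] = float(value)
    return scores


def biotagme_score(s: float, r: float) -> float:
    """Predicted edge weight: projection score × relatedness."""
    if not (0.0 <= r <= 1.0):
        raise ValidationError(f"relatedness {r} outside [0,1]")
    if s < 0:
        raise ValidationError(f"projection score {s} negative")
    return s * r


def predict(
    annotations: Sequence[Annotation],
    wiki: WikiSnapshot,
    config: ScoringConfig = ScoringConfig(),
) -> list[ScoredPair]:
    """Score all co-annotated entity pairs and rank by BioTG descending.

    Pairs below ``config.min_biotg`` are dropped; ties order by pair id.
    """
    net = build_bipartite(annotations)
    scores = dthybrid_scores(net, config)
    rel = make_relatedness(wiki)
    pairs: list[ScoredPair] = []
    for (i, j), s in scores.items():
        r = rel(i, j)
        biotg = biotagme_score(s, r)
        if biotg >= config.min_biotg:
            pairs.append(ScoredPair(entity_i=i, entity_j=j, s=s, r=r, biotg=biotg))
    pairs.sort(key=lambda p: (-p.biotg, p.pair))
    return pairs


def supporting_documents(annotations: Iterable[Annotation]) -> dict[tuple[int, int], set[str]]:
    """Documents in which both members of each pair are annotated."""
    per_doc: dict[str, set[int]] = defaultdict(set)
    for a in annotations:
        per_doc[a.doc_id].add(a.page_id)
    support: dict[tuple[int, int], set[str]] = defaultdict(set)
    for doc_id, pages in per_doc.items():
        ordered = sorted(pages)
        for x in range(len(ordered)):
            for y in range(x + 1, len(ordered)):
                support[(ordered[x], ordered[y])].add(doc_id)
    return dict(support)
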