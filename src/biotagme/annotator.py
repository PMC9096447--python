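"""TAGME-style entity annotation of titles+abstracts.

The stages are the classic wikification pipeline: tokenize and strip
stop-words/punctuation, spot anchor-dictionary phrases (longest match,
left to right), disambiguate each spotted mention collectively — every
other mention votes for a candidate sense in proportion to semantic
relatedness weighted by the voter's commonness prior — score each
annotation with ρ = mean(link probability, coherence), then prune by ρ and
by membership in the biological subtree of the category graph.

The annotator is local and self-contained: it reproduces the TAGME family
of heuristics over the supplied snapshot rather than calling a hosted
service, so the whole pipeline runs offline and deterministically.
"""

from __future__ import annotations

import dataclasses
import string
from typing import Callable, Iterable, Sequence

from .corpus import Document
from .errors import LookupFailure, ValidationError
from .wiki import WikiSnapshot

# Minimal English stop-list: function words only, so that content-bearing
# modifiers ("also", "known", "novel") survive tokenization.
STOPWORDS = frozenset(
    """
    a an and are as at be been but by for from had has have he her his i if
    in into is it its may nor not of on or our she so than that the their
    them then there these they this those to was we were which while will
    with you your
    """.split()
)

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


@dataclasses.dataclass(frozen=True)
class Mention:
    """A spotted anchor span with its candidate senses.

    Token offsets are 0-based, half-open; ``candidates`` holds
    (page_id, commonness) with commonness summing to 1 over senses.
    """

    doc_id: str
    anchor_text: str
    start_token: int
    end_token: int
    candidates: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if self.start_token >= self.end_token:
            raise ValidationError("mention span must be non-empty")


@dataclasses.dataclass(frozen=True)
class Annotation:
    """A mention resolved to a page, with quality scores attached."""

    doc_id: str
    anchor_text: str
    page_id: int
    commonness: float
    coherence: float
    rho: float
    start_token: int = 0
    end_token: int = 1


@dataclasses.dataclass(frozen=True)
class AnnotationParams:
    """Knobs of the annotation stage.

    rho_threshold: annotations with ρ below this are pruned (0 disables).
    max_ngram: longest anchor span considered, in tokens.
    max_depth: hops up the category graph allowed to reach a biology root.
    The ρ pruning and the biological-category filter can be switched off
    independently.
    """

    rho_threshold: float = 0.2
    max_ngram: int = 6
    max_depth: int = 3
    use_rho_pruning: bool = True
    use_bio_filter: bool = True


def preprocess(text: str, stopwords: frozenset[str] = STOPWORDS) -> list[str]:
    """Lower-case, strip punctuation, drop stop-words; order preserved."""
    tokens = text.lower().translate(_PUNCT_TABLE).split()
    return [t for t in tokens if t not in stopwords]


def spot(tokens: Sequence[str], wiki: WikiSnapshot, max_ngram: int = 6, doc_id: str = "") -> list[Mention]:
    """Find non-overlapping anchor-dictionary matches, longest first.

    Scans left to right; at each position the longest n-gram (up to
    ``max_ngram`` tokens) present in the anchor dictionary wins and the
    scan resumes after it.
    """
    if max_ngram < 1:
        raise ValidationError("max_ngram must be >= 1")
    mentions: list[Mention] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for length in range(min(max_ngram, n - i), 0, -1):
            phrase = " ".join(tokens[i : i + length])
            if phrase in wiki.anchors:
                candidates = tuple(
                    sorted((pid, commonness(phrase, pid, wiki)) for pid in wiki.anchors[phrase])
                )
                mentions.append(
                    Mention(
                        doc_id=doc_id,
                        anchor_text=phrase,
                        start_token=i,
                        end_token=i + length,
                        candidates=candidates,
                    )
                )
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def commonness(anchor_text: str, page_id: int, wiki: WikiSnapshot) -> float:
    """Prior P(page | anchor): the anchor's link-count fraction to the page."""
    if anchor_text not in wiki.anchors:
        raise LookupFailure(f"unknown anchor {anchor_text!r}")
    senses = wiki.anchors[anchor_text]
    total = sum(senses.values())
    return senses.get(page_id, 0) / total


def disambiguate(
    mentions: Sequence[Mention],
    relatedness_fn: Callable[[int, int], float],
    wiki: WikiSnapshot,
) -> list[tuple[Mention, int]]:
    """Collectively choose one sense per mention by relatedness voting.

    For mention ``a`` and candidate ``p`` the vote of every other mention
    ``b`` is the commonness-weighted mean relatedness of b's candidates to
    p; the candidate with the highest total wins.  Ties break by higher
    commonness, then lower page id; a lone mention falls back to the
    commonness prior.
    """
    if not mentions:
        return []
    chosen: list[tuple[Mention, int]] = []
    for a in mentions:
        others = [b for b in mentions if b is not a]
        best: tuple[float, float, int] | None = None
        best_page = None
        for page, cmn in a.candidates:
            if others:
                score = 0.0
                for b in others:
                    vote = sum(relatedness_fn(q, page) * q_cmn for q, q_cmn in b.candidates)
                    score += vote / len(b.candidates)
            else:
                score = 0.0
            key = (-score, -cmn, page)
            if best is None or key < best:
                best = key
                best_page = page
        assert best_page is not None
        chosen.append((a, best_page))
    return chosen


def rho_score(
    context_pages: Iterable[int],
    anchor_text: str,
    page_id: int,
    wiki: WikiSnapshot,
    relatedness_fn: Callable[[int, int], float],
) -> tuple[float, float]:
    """Return (coherence, ρ) for one chosen annotation.

    ρ averages the anchor's link probability (keyphraseness) with the
    coherence of the chosen page, i.e. its mean relatedness to the other
    pages chosen in the same document (0 when the annotation is alone).
    """
    others = [p for p in context_pages if p != page_id]
    coherence = sum(relatedness_fn(page_id, p) for p in others) / len(others) if others else 0.0
    rho = (wiki.link_probability(anchor_text) + coherence) / 2.0
    return coherence, rho


def biological_filter(page_ids: Iterable[int], wiki: WikiSnapshot, max_depth: int = 3) -> set[int]:
    """Keep pages whose categories reach a biology root within max_depth hops.

    A page directly in a root category qualifies at depth 0.  Traversal of
    the (possibly cyclic) category graph uses a visited set.
    """
    if max_depth < 1:
        raise ValidationError("max_depth must be >= 1")
    kept: set[int] = set()
    for pid in page_ids:
        frontier = set(wiki.pages[pid].categories)
        visited: set[int] = set()
        reached = bool(frontier & wiki.bio_roots)
        depth = 0
        while frontier and not reached and depth < max_depth:
            visited |= frontier
            frontier = {
                parent
                for cat in frontier
                for parent in wiki.category_parents.get(cat, ())
                if parent not in visited
            }
            reached = bool(frontier & wiki.bio_roots)
            depth += 1
        if reached:
            kept.add(pid)
    return kept


def annotate_document(
    doc: Document,
    wiki: WikiSnapshot,
    params: AnnotationParams = AnnotationParams(),
    relatedness_fn: Callable[[int, int], float] | None = None,
) -> list[Annotation]:
    """Full annotation of one document's title+abstract.

    preprocess → spot → disambiguate → ρ-score, then prune by ρ threshold
    and by the biological-category filter; duplicate (doc, page) hits keep
    the max-ρ instance; output is sorted by token offset.
    """
    if relatedness_fn is None:
        from .scoring import make_relatedness

        relatedness_fn = make_relatedness(wiki)

    tokens = preprocess(doc.ti_ab)
    mentions = spot(tokens, wiki, max_ngram=params.max_ngram, doc_id=doc.doc_id)
    if not mentions:
        return []
    chosen = disambiguate(mentions, relatedness_fn, wiki)
    context = [page for _, page in chosen]

    annotations: list[Annotation] = []
    for mention, page in chosen:
        coherence, rho = rho_score(context, mention.anchor_text, page, wiki, relatedness_fn)
        annotations.append(
            Annotation(
                doc_id=doc.doc_id,
                anchor_text=mention.anchor_text,
                page_id=page,
                commonness=commonness(mention.anchor_text, page, wiki),
                coherence=coherence,
                rho=rho,
                start_token=mention.start_token,
                end_token=mention.end_token,
            )
        )

    if params.use_rho_pruning:
        annotations = [a for a in annotations if a.rho >= params.rho_threshold]
    if params.use_bio_filter:
        keep = biological_filter({a.page_id for a in annotations}, wiki, params.max_depth)
        annotations = [a for a in annotations if a.page_id in keep]

    # dedupe repeated (doc, page) pairs keeping the max-rho instance
    best: dict[int, Annotation] = {}
    for a in annotations:
        cur = best.get(a.page_id)
        if cur is None or (a.rho, -a.start_token) > (cur.rho, -cur.start_token):
            best[a.page_id] = a
    return sorted(best.values(), key=lambda a: (a.start_token, a.page_id))


def annotate_corpus(
    docs: Iterable[Document],
    wiki: WikiSnapshot,
    params: AnnotationParams = AnnotationParams(),
) -> list[Annotation]:
    """Annotate many documents with one shared relatedness cache."""
    from .scoring import make_relatedness

    relatedness_fn = make_relatedness(wiki)
    out: list[Annotation] = []
    for doc in docs:
        out.extend(annotate_document(doc, wiki, params, relatedness_fn))
    return out
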