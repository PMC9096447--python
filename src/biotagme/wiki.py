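"""In-memory Wikipedia-like snapshot: pages, links, categories, anchors.

The snapshot is the annotation universe: the anchor dictionary supplies the
spotting vocabulary, the directed page-link graph feeds in-link based
semantic relatedness, and the category graph (with designated biology
roots) supports pruning to the biological subdomain.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

from .errors import IntegrityError, LookupFailure, ValidationError


@dataclasses.dataclass(frozen=True)
class Page:
    page_id: int
    title: str
    categories: frozenset[int] = frozenset()


@dataclasses.dataclass
class WikiSnapshot:
    """Pages, inter-page links, category graph and anchor dictionary.

    ``anchors`` maps anchor text to ``{page_id: link count}``;
    ``anchor_occurrences`` optionally records how often the anchor text
    occurs in the snapshot's text overall, from which the link probability
    (keyphraseness) of the anchor is estimated.  When occurrence counts are
    absent the link probability defaults to 1.
    """

    pages: dict[int, Page]
    links: set[tuple[int, int]]  # directed source -> target
    category_parents: dict[int, set[int]]  # child category -> parent categories
    bio_roots: frozenset[int]
    anchors: dict[str, dict[int, int]]
    anchor_occurrences: dict[str, int] | None = None
    category_names: dict[int, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, dst in self.links:
            if src not in self.pages or dst not in self.pages:
                raise IntegrityError(f"link ({src},{dst}) references unknown page")
        for anchor, senses in self.anchors.items():
            if not senses:
                raise IntegrityError(f"anchor {anchor!r} has no senses")
            for page_id, count in senses.items():
                if page_id not in self.pages:
                    raise IntegrityError(f"anchor {anchor!r} references unknown page {page_id}")
                if count <= 0:
                    raise ValidationError(f"anchor {anchor!r} has non-positive count")
        self._in_links: dict[int, frozenset[int]] | None = None

    @property
    def n_pages(self) -> int:
        return len(self.pages)

    def title_of(self, page_id: int) -> str:
        try:
            return self.pages[page_id].title
        except KeyError:
            raise LookupFailure(f"unknown page {page_id}") from None

    def in_links(self, page_id: int) -> frozenset[int]:
        """Set of pages linking *to* ``page_id`` (cached)."""
        if page_id not in self.pages:
            raise LookupFailure(f"unknown page {page_id}")
        if self._in_links is None:
            table: dict[int, set[int]] = {pid: set() for pid in self.pages}
            for src, dst in self.links:
                table[dst].add(src)
            self._in_links = {pid: frozenset(srcs) for pid, srcs in table.items()}
        return self._in_links[page_id]

    def link_probability(self, anchor_text: str) -> float:
        """Fraction of the anchor's textual occurrences that are links."""
        if anchor_text not in self.anchors:
            raise LookupFailure(f"unknown anchor {anchor_text!r}")
        if not self.anchor_occurrences:
            return 1.0
        occurrences = self.anchor_occurrences.get(anchor_text)
        if not occurrences:
            return 1.0
        links = sum(self.anchors[anchor_text].values())
        return min(1.0, links / occurrences)


# ---------------------------------------------------------------------------
# on-disk layout: plain TSV tables in one directory

_PAGES = "pages.tsv"
_LINKS = "links.tsv"
_CATEGORIES = "categories.tsv"
_ANCHORS = "anchors.tsv"
_OCCURRENCES = "anchor_occurrences.tsv"


def write_wiki(snapshot: WikiSnapshot, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / _PAGES, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["page_id", "title", "categories"])
        for pid in sorted(snapshot.pages):
            page = snapshot.pages[pid]
            writer.writerow([pid, page.title, "|".join(map(str, sorted(page.categories)))])

    with open(directory / _LINKS, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target"])
        for src, dst in sorted(snapshot.links):
            writer.writerow([src, dst])

    with open(directory / _CATEGORIES, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["child", "parent", "is_bio_root", "name"])
        cats = set(snapshot.category_parents) | set(snapshot.bio_roots) | set(snapshot.category_names)
        for cat in sorted(cats):
            parents = sorted(snapshot.category_parents.get(cat, ()))
            name = snapshot.category_names.get(cat, "")
            flag = int(cat in snapshot.bio_roots)
            if parents:
                for parent in parents:
                    writer.writerow([cat, parent, flag, name])
            else:
                writer.writerow([cat, "", flag, name])

    with open(directory / _ANCHORS, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["anchor_text", "page_id", "count"])
        for anchor in sorted(snapshot.anchors):
            for pid in sorted(snapshot.anchors[anchor]):
                writer.writerow([anchor, pid, snapshot.anchors[anchor][pid]])

    if snapshot.anchor_occurrences is not None:
        with open(directory / _OCCURRENCES, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["anchor_text", "occurrences"])
            for anchor in sorted(snapshot.anchor_occurrences):
                writer.writerow([anchor, snapshot.anchor_occurrences[anchor]])


def read_wiki(directory: str | Path) -> WikiSnapshot:
    directory = Path(directory)

    pages: dict[int, Page] = {}
    with open(directory / _PAGES, encoding="utf-8", newline="") as handle:
        for record in csv.DictReader(handle, delimiter="\t"):
            pid = int(record["page_id"])
            cats = frozenset(int(c) for c in record["categories"].split("|") if c)
            pages[pid] = Page(page_id=pid, title=record["title"], categories=cats)

    links: set[tuple[int, int]] = set()
    with open(directory / _LINKS, encoding="utf-8", newline="") as handle:
        for record in csv.DictReader(handle, delimiter="\t"):
            links.add((int(record["source"]), int(record["target"])))

    category_parents: dict[int, set[int]] = {}
    bio_roots: set[int] = set()
    category_names: dict[int, str] = {}
    with open(directory / _CATEGORIES, encoding="utf-8", newline="") as handle:
        for record in csv.DictReader(handle, delimiter="\t"):
            child = int(record["child"])
            if record["parent"]:
                category_parents.setdefault(child, set()).add(int(record["parent"]))
            if int(record["is_bio_root"]):
                bio_roots.add(child)
            if record.get("name"):
                category_names[child] = record["name"]

    anchors: dict[str, dict[int, int]] = {}
    with open(directory / _ANCHORS, encoding="utf-8", newline="") as handle:
        for record in csv.DictReader(handle, delimiter="\t"):
            anchors.setdefault(record["anchor_text"], {})[int(record["page_id"])] = int(record["count"])

    anchor_occurrences: dict[str, int] | None = None
    occ_path = directory / _OCCURRENCES
    if occ_path.exists():
        anchor_occurrences = {}
        with open(occ_path, encoding="utf-8", newline="") as handle:
            for record in csv.DictReader(handle, delimiter="\t"):
                anchor_occurrences[record["anchor_text"]] = int(record["occurrences"])

    return WikiSnapshot(
        pages=pages,
        links=links,
        category_parents=category_parents,
        bio_roots=frozenset(bio_roots),
        anchors=anchors,
        anchor_occurrences=anchor_occurrences,
        category_names=category_names,
    )
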