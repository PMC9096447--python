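"""Edge-set evaluation against a reference network.

The universe of negatives is all unordered node pairs over an explicitly
supplied node set; confusion counts then give sensitivity tp/(tp+fn) and
specificity tn/(tn+fp), reported as percentages truncated to two decimals
(54/77 prints as 70.12).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Collection, Hashable, Iterable

from .errors import ValidationError

Pair = tuple[Hashable, Hashable]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _normalize(pairs: Iterable[Pair]) -> set[frozenset]:
    out = set()
    for a, b in pairs:
        if a == b:
            raise ValidationError(f"self-pair ({a},{b}) not allowed")
        out.add(frozenset((a, b)))
    return out


def confusion(
    predicted: Iterable[Pair],
    reference: Iterable[Pair],
    universe_nodes: Collection[Hashable],
) -> ConfusionCounts:
    """Confusion counts of a predicted pair set against a reference one.

    Pairs are unordered; the universe is all C(n,2) pairs over
    ``universe_nodes``, and any pair endpoint outside it is an error.
    """
    nodes = set(universe_nodes)
    pred = _normalize(predicted)
    ref = _normalize(reference)
    for pair in pred | ref:
        if not pair <= nodes:
            raise ValidationError(f"pair {sorted(pair)} has endpoint outside the universe")
    n = len(nodes)
    universe = n * (n - 1) // 2
    tp = len(pred & ref)
    fn = len(ref - pred)
    fp = len(pred - ref)
    tn = universe - tp - fn - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _truncate2(value: float) -> float:
    return math.floor(value * 100.0) / 100.0


def sensitivity(c: ConfusionCounts) -> float:
    """100·tp/(tp+fn), truncated to two decimals."""
    if c.tp + c.fn == 0:
        raise ValidationError("sensitivity undefined: no reference positives")
    return _truncate2(100.0 * c.tp / (c.tp + c.fn))


def specificity(c: ConfusionCounts) -> float:
    """100·tn/(tn+fp), truncated to two decimals."""
    if c.tn + c.fp == 0:
        raise ValidationError("specificity undefined: no reference negatives")
    return _truncate2(100.0 * c.tn / (c.tn + c.fp))


def report(c: ConfusionCounts) -> dict:
    """JSON-ready evaluation report."""
    return {
        "tp": c.tp,
        "fp": c.fp,
        "tn": c.tn,
        "fn": c.fn,
        "universe_size": c.universe_size,
        "sensitivity": sensitivity(c) if c.tp + c.fn else None,
        "specificity": specificity(c) if c.tn + c.fp else None,
    }
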