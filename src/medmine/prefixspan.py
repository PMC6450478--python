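"""From-scratch PrefixSpan sequential-pattern mining via projected databases.

A sequence is an ordered list of *elements* (same-day medication sets).  A
sequence contains a pattern iff there is an order-preserving mapping of
pattern elements into sequence elements with element-wise set inclusion.
Patterns are grown by prefix projection: an *I-extension* adds an item to the
pattern's last element (same day), an *S-extension* appends a new element
(later day).  Projections are represented compactly per sequence by the set
of element indices at which the pattern's last element can end; this is
sufficient because any further extension depends only on that ending index.

Items within an element are kept lexicographically sorted, which gives every
pattern a canonical identity and makes output deterministic.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

from .emr_model import ValidationError
from .fpgrowth import min_count
from .preprocess import SequenceDB

__all__ = [
    "SequentialPattern",
    "contains",
    "mean_time_gap",
    "mine_sequential_patterns",
    "render_sequence",
]

log = logging.getLogger(__name__)

Elements = tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class SequentialPattern:
    """An ordered list of medication sets with its exact support."""

    elements: Elements
    support_count: int
    support: float

    @property
    def n_items(self) -> int:
        return sum(len(e) for e in self.elements)

    def render(self) -> str:
        return render_sequence(self.elements)


def render_sequence(elements: Iterable[Iterable[str]]) -> str:
    return "⟨" + ",".join("(" + ",".join(sorted(e)) + ")" for e in elements) + "⟩"


def _as_sequences(db) -> list[Elements]:
    if isinstance(db, SequenceDB):
        return db.sequences()
    return [tuple(tuple(sorted(e)) for e in seq) for seq in db]


def contains(sequence: Iterable[Iterable[str]], pattern: Iterable[Iterable[str]]) -> bool:
    """True iff an order-preserving element-wise-inclusion embedding exists.

    Uses the greedy earliest-match strategy, which is exact for this
    containment relation.
    """
    seq = [frozenset(e) for e in sequence]
    pos = 0
    for pel in pattern:
        pset = frozenset(pel)
        while pos < len(seq) and not pset <= seq[pos]:
            pos += 1
        if pos == len(seq):
            return False
        pos += 1
    return True


def mine_sequential_patterns(
    db: SequenceDB | Iterable[Iterable[Iterable[str]]],
    min_support: float,
    max_length: int = 8,
) -> list[SequentialPattern]:
    """Mine all sequential patterns with support >= ``min_support``.

    Complete and sound up to ``max_length`` total items per pattern.  Support
    is the fraction of sequences containing the pattern.
    """
    seqs = _as_sequences(db)
    n = len(seqs)
    if n == 0:
        log.warning("mine_sequential_patterns: empty sequence database")
        min_count(min_support, 1)
        return []
    if max_length < 1:
        raise ValidationError("max_length must be >= 1")
    minc = min_count(min_support, n)
    seq_sets = [[frozenset(e) for e in s] for s in seqs]

    results: list[SequentialPattern] = []

    def recurse(pattern: list[tuple[str, ...]], proj: dict[int, list[int]], n_items: int) -> None:
        supp = len(proj)
        results.append(
            SequentialPattern(elements=tuple(pattern), support_count=supp, support=supp / n)
        )
        if n_items >= max_length:
            return
        last_item = pattern[-1][-1]
        i_counts: dict[str, int] = {}
        s_counts: dict[str, int] = {}
        for sid, endings in proj.items():
            sseq = seqs[sid]
            iset: set[str] = set()
            for e in endings:
                for it in sseq[e]:
                    if it > last_item:
                        iset.add(it)
            for it in iset:
                i_counts[it] = i_counts.get(it, 0) + 1
            sset: set[str] = set()
            for f in range(endings[0] + 1, len(sseq)):
                sset.update(sseq[f])
            for it in sset:
                s_counts[it] = s_counts.get(it, 0) + 1
        for it in sorted(i_counts):
            if i_counts[it] < minc:
                continue
            new_proj: dict[int, list[int]] = {}
            for sid, endings in proj.items():
                new_end = [e for e in endings if it in seq_sets[sid][e]]
                if new_end:
                    new_proj[sid] = new_end
            recurse(pattern[:-1] + [pattern[-1] + (it,)], new_proj, n_items + 1)
        for it in sorted(s_counts):
            if s_counts[it] < minc:
                continue
            new_proj = {}
            for sid, endings in proj.items():
                start = endings[0] + 1
                new_end = [f for f in range(start, len(seqs[sid])) if it in seq_sets[sid][f]]
                if new_end:
                    new_proj[sid] = new_end
            recurse(pattern + [(it,)], new_proj, n_items + 1)

    item_universe: set[str] = set()
    for s in seqs:
        for e in s:
            item_universe.update(e)
    for it in sorted(item_universe):
        proj = {}
        for sid, sseq in enumerate(seq_sets):
            endings = [e for e, el in enumerate(sseq) if it in el]
            if endings:
                proj[sid] = endings
        if len(proj) >= minc:
            recurse([(it,)], proj, 1)

    results.sort(key=lambda p: (-p.support_count, p.render()))
    return results


def mean_time_gap(db: SequenceDB, pattern: SequentialPattern | Sequence[Iterable[str]]) -> float | None:
    """Mean day gap between the two elements of a two-element pattern.

    For every sequence supporting the pattern, the gap is taken between the
    earliest embedding of the first element and the earliest later embedding
    of the second (the deterministic "followed by" reading).  Returns ``None``
    when no sequence supports the pattern.
    """
    elements = pattern.elements if isinstance(pattern, SequentialPattern) else tuple(pattern)
    if len(elements) != 2:
        raise ValidationError("mean_time_gap requires a pattern with exactly two elements")
    first, second = frozenset(elements[0]), frozenset(elements[1])
    gaps: list[float] = []
    for entry in db.entries:
        sets = [frozenset(e) for e in entry.elements]
        e1 = next((i for i, s in enumerate(sets) if first <= s), None)
        if e1 is None:
            continue
        e2 = next((i for i in range(e1 + 1, len(sets)) if second <= sets[i]), None)
        if e2 is None:
            continue
        gaps.append(float(entry.days[e2] - entry.days[e1]))
    if not gaps:
        return None
    return statistics.fmean(gaps)
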