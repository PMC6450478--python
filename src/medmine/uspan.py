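"""From-scratch USpan high-utility sequential-pattern mining.

Items in a utility sequence database carry utilities ``u = P(i) * q`` (dose
value times quantity).  The utility of a pattern *in one sequence* is the
maximum, over all embeddings (occurrences) of the pattern in the sequence, of
the summed utilities of the embedded items — the standard USpan convention.
The pattern's database utility is the sum of those per-sequence maxima over
the sequences that contain it.  Mining returns every pattern whose database
utility reaches ``min_utility``: utility is not anti-monotone, so the search
is kept sound and complete by two provably safe upper bounds:

* width pruning — an item whose *sequence-weighted utility* (SWU: the summed
  total utility of the sequences containing it) is below the threshold can
  never appear in a qualifying pattern;
* depth pruning — a prefix whose best achievable utility (current occurrence
  utility plus all remaining utility at or after the occurrence's last
  element) is below the threshold cannot be extended into a qualifying
  pattern.

Both bounds only ever *over*-estimate the utility of extensions, so no
qualifying pattern is lost (asserted against a brute-force oracle in the
test suite).

The search grows patterns by I-concatenation (add an item, in lexicographic
order, to the last element) and S-concatenation (start a new, later element),
mirroring PrefixSpan's grammar.  Per sequence, the state of a pattern is the
map ``ending element index -> best occurrence utility ending there``, which
is sufficient for both extension and the max-occurrence utility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .emr_model import ValidationError
from .prefixspan import render_sequence
from .preprocess import UtilitySequenceDB

__all__ = ["UtilityPattern", "mine_high_utility_sequences", "pattern_utility"]

log = logging.getLogger(__name__)

Elements = tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class UtilityPattern:
    """A sequential pattern with its total database utility."""

    elements: Elements
    utility: float
    support_count: int

    @property
    def n_items(self) -> int:
        return sum(len(e) for e in self.elements)

    def render(self) -> str:
        return render_sequence(self.elements)


@dataclass(frozen=True)
class _Seq:
    """Preprocessed utility sequence with suffix-utility accumulators."""

    elements: tuple[dict[str, float], ...]
    elem_total: tuple[float, ...]
    #: total utility of all elements strictly after index e
    suffix_after: tuple[float, ...]
    total: float


def _prep(db) -> list[_Seq]:
    if isinstance(db, UtilitySequenceDB):
        raw = [[dict(el) for el in entry.elements] for entry in db.entries]
    else:
        raw = [[dict(el) for el in seq] for seq in db]
    seqs = []
    for elems in raw:
        for el in elems:
            for item, u in el.items():
                if u < 0:
                    raise ValidationError(f"negative utility for item {item!r}")
        totals = tuple(sum(el.values()) for el in elems)
        suffix = [0.0] * len(elems)
        acc = 0.0
        for e in range(len(elems) - 1, -1, -1):
            suffix[e] = acc
            acc += totals[e]
        seqs.append(
            _Seq(
                elements=tuple(elems),
                elem_total=totals,
                suffix_after=tuple(suffix),
                total=acc,
            )
        )
    return seqs


def pattern_utility(db, pattern: Iterable[Iterable[str]]) -> float:
    """Total database utility of ``pattern``: sum over sequences of the
    maximum occurrence utility; 0 if no sequence contains the pattern."""
    elements = [tuple(sorted(e)) for e in pattern]
    if not elements or any(not e for e in elements):
        raise ValidationError("pattern elements must be non-empty")
    total = 0.0
    for seq in _prep(db):
        best = _max_occurrence(seq, elements)
        if best is not None:
            total += best
    return total


def _max_occurrence(seq: _Seq, elements: list[tuple[str, ...]]) -> float | None:
    """Max occurrence utility of the pattern in one sequence (None if absent),
    by dynamic programming over ending positions."""
    endings: dict[int, float] = {}
    first = elements[0]
    for e, el in enumerate(seq.elements):
        if all(i in el for i in first):
            endings[e] = sum(el[i] for i in first)
    for pel in elements[1:]:
        if not endings:
            return None
        new: dict[int, float] = {}
        order = sorted(endings)
        best_before = -1.0
        k = 0
        for f in range(order[0] + 1, len(seq.elements)):
            while k < len(order) and order[k] < f:
                best_before = max(best_before, endings[order[k]])
                k += 1
            el = seq.elements[f]
            if best_before >= 0 and all(i in el for i in pel):
                new[f] = best_before + sum(el[i] for i in pel)
        endings = new
    if not endings:
        return None
    return max(endings.values())


def mine_high_utility_sequences(
    db: UtilitySequenceDB | Iterable[Iterable[Iterable[tuple[str, float]]]],
    min_utility: float,
    max_length: int = 8,
    relative: bool = False,
) -> list[UtilityPattern]:
    """Mine all sequential patterns with database utility >= ``min_utility``.

    With ``relative=True`` the threshold is a fraction of the database's
    total utility (useful when absolute utility scales differ between
    datasets).  Results are ranked by descending utility, ties broken by
    support count and then by rendered pattern.
    """
    seqs = _prep(db)
    if relative:
        min_utility = min_utility * sum(s.total for s in seqs)
    if min_utility <= 0:
        raise ValidationError("min_utility must be positive")
    if max_length < 1:
        raise ValidationError("max_length must be >= 1")
    if not seqs:
        log.warning("mine_high_utility_sequences: empty database")
        return []

    # width pruning: SWU per item
    swu: dict[str, float] = {}
    for seq in seqs:
        items = set()
        for el in seq.elements:
            items.update(el)
        for it in items:
            swu[it] = swu.get(it, 0.0) + seq.total
    root_items = sorted(it for it, w in swu.items() if w + 1e-9 >= min_utility)

    results: list[UtilityPattern] = []

    def recurse(pattern: list[tuple[str, ...]], proj: dict[int, dict[int, float]], n_items: int) -> None:
        utility = sum(max(ends.values()) for ends in proj.values())
        if utility + 1e-9 >= min_utility:
            results.append(
                UtilityPattern(elements=tuple(pattern), utility=utility, support_count=len(proj))
            )
        if n_items >= max_length:
            return
        last_item = pattern[-1][-1]
        # candidate upper bounds, accumulated per sequence:
        #   I-extension via ending e:  u_e + (elem_total[e] - matched) + suffix_after[e]
        #   S-extension via element f: max_{e<f} u_e + elem_total[f] + suffix_after[f]
        # (the unmatched part of the ending/target element plus everything
        # later can only over-count, never under-count, an extension)
        i_bounds: dict[str, float] = {}
        s_bounds: dict[str, float] = {}
        last_pel = pattern[-1]
        for sid, ends in proj.items():
            seq = seqs[sid]
            i_best: dict[str, float] = {}
            for e, u in ends.items():
                el = seq.elements[e]
                matched = sum(el[i] for i in last_pel)
                room = u + (seq.elem_total[e] - matched) + seq.suffix_after[e]
                for it in el:
                    if it > last_item and (it not in i_best or room > i_best[it]):
                        i_best[it] = room
            for it, b in i_best.items():
                i_bounds[it] = i_bounds.get(it, 0.0) + b
            order = sorted(ends)
            s_best: dict[str, float] = {}
            best_before = 0.0
            k = 0
            for f in range(order[0] + 1, len(seq.elements)):
                while k < len(order) and order[k] < f:
                    best_before = max(best_before, ends[order[k]])
                    k += 1
                room = best_before + seq.elem_total[f] + seq.suffix_after[f]
                for it in seq.elements[f]:
                    if it not in s_best or room > s_best[it]:
                        s_best[it] = room
            for it, b in s_best.items():
                s_bounds[it] = s_bounds.get(it, 0.0) + b
        for it in sorted(i_bounds):
            if i_bounds[it] + 1e-9 < min_utility:
                continue
            new_proj: dict[int, dict[int, float]] = {}
            for sid, ends in proj.items():
                seq = seqs[sid]
                new_ends = {
                    e: u + seq.elements[e][it]
                    for e, u in ends.items()
                    if it in seq.elements[e]
                }
                if new_ends:
                    new_proj[sid] = new_ends
            if new_proj:
                recurse(pattern[:-1] + [pattern[-1] + (it,)], new_proj, n_items + 1)
        for it in sorted(s_bounds):
            if s_bounds[it] + 1e-9 < min_utility:
                continue
            new_proj = {}
            for sid, ends in proj.items():
                seq = seqs[sid]
                order = sorted(ends)
                new_ends: dict[int, float] = {}
                best_before = -1.0
                k = 0
                for f in range(order[0] + 1, len(seq.elements)):
                    while k < len(order) and order[k] < f:
                        best_before = max(best_before, ends[order[k]])
                        k += 1
                    if best_before >= 0 and it in seq.elements[f]:
                        new_ends[f] = best_before + seq.elements[f][it]
                if new_ends:
                    new_proj[sid] = new_ends
            if new_proj:
                recurse(pattern + [(it,)], new_proj, n_items + 1)

    for it in root_items:
        proj: dict[int, dict[int, float]] = {}
        for sid, seq in enumerate(seqs):
            ends = {e: el[it] for e, el in enumerate(seq.elements) if it in el}
            if ends:
                proj[sid] = ends
        if proj:
            recurse([(it,)], proj, 1)

    results.sort(key=lambda p: (-p.utility, -p.support_count, p.render()))
    return results
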