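"""From-scratch FP-Growth frequent-itemset mining.

FP-Growth mines the complete set of frequent itemsets without candidate
generation: transactions are compressed into a prefix tree (FP-tree) whose
items are ordered by descending global frequency, and the tree is mined
recursively through conditional pattern bases.  Output is deterministic:
tree order breaks frequency ties lexicographically, and results are sorted
by descending support then by rendered itemset.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .emr_model import ValidationError
from .preprocess import TransactionDB

__all__ = ["Pattern", "mine_frequent_itemsets", "render_itemset", "min_count"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pattern:
    """A frequent itemset with its exact support."""

    items: frozenset[str]
    support_count: int
    support: float

    def render(self) -> str:
        return render_itemset(self.items)


def render_itemset(items: Iterable[str]) -> str:
    return "(" + ";".join(sorted(items)) + ")"


def min_count(min_support: float, n_transactions: int) -> int:
    """Absolute support threshold: ceil(min_support * n), at least 1."""
    if not (0.0 < min_support <= 1.0):
        raise ValidationError(f"min_support must be in (0, 1], got {min_support}")
    # the epsilon guards against ceil(0.15 * 20) = ceil(3.0000000000000004)
    return max(1, math.ceil(min_support * n_transactions - 1e-9))


class _Node:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item: str | None, parent: "_Node | None"):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, _Node] = {}


def _build_tree(
    itemsets: Sequence[Iterable[str]],
    counts: Sequence[int],
    order: dict[str, int],
) -> dict[str, list[_Node]]:
    """Insert transactions (with multiplicities) and return the header table."""
    root = _Node(None, None)
    header: dict[str, list[_Node]] = {}
    for items, count in zip(itemsets, counts):
        filtered = sorted((i for i in items if i in order), key=order.__getitem__)
        node = root
        for item in filtered:
            child = node.children.get(item)
            if child is None:
                child = _Node(item, node)
                node.children[item] = child
                header.setdefault(item, []).append(child)
            child.count += count
            node = child
    return header


def _mine(
    header: dict[str, list[_Node]],
    order: dict[str, int],
    minc: int,
    suffix: frozenset[str],
    out: list[tuple[frozenset[str], int]],
) -> None:
    # visit items from least to most frequent so conditional trees shrink
    for item in sorted(header, key=order.__getitem__, reverse=True):
        nodes = header[item]
        support = sum(n.count for n in nodes)
        itemset = suffix | {item}
        out.append((itemset, support))
        # conditional pattern base: prefix paths above each node of `item`
        paths: list[list[str]] = []
        path_counts: list[int] = []
        base_counts: Counter[str] = Counter()
        for node in nodes:
            path = []
            p = node.parent
            while p is not None and p.item is not None:
                path.append(p.item)
                p = p.parent
            if path:
                paths.append(path)
                path_counts.append(node.count)
                for i in path:
                    base_counts[i] += node.count
        cond_order_items = sorted(
            (i for i, c in base_counts.items() if c >= minc),
            key=lambda i: (-base_counts[i], i),
        )
        if not cond_order_items:
            continue
        cond_order = {i: r for r, i in enumerate(cond_order_items)}
        cond_header = _build_tree(paths, path_counts, cond_order)
        _mine(cond_header, cond_order, minc, itemset, out)


def mine_frequent_itemsets(
    db: TransactionDB | Iterable[Iterable[str]],
    min_support: float,
) -> list[Pattern]:
    """Mine all itemsets with relative support >= ``min_support``.

    ``db`` may be a :class:`~medmine.preprocess.TransactionDB` or any
    iterable of item collections.  The result is complete and sound: exactly
    the itemsets whose support count reaches ``ceil(min_support * |DB|)``,
    each with its exact support, independent of transaction or item order.
    """
    itemsets = db.itemsets() if isinstance(db, TransactionDB) else [frozenset(t) for t in db]
    n = len(itemsets)
    if n == 0:
        log.warning("mine_frequent_itemsets: empty transaction database")
        # still validate the threshold before returning
        min_count(min_support, 1)
        return []
    minc = min_count(min_support, n)
    global_counts: Counter[str] = Counter()
    for t in itemsets:
        global_counts.update(set(t))
    frequent = sorted(
        (i for i, c in global_counts.items() if c >= minc),
        key=lambda i: (-global_counts[i], i),
    )
    order = {i: r for r, i in enumerate(frequent)}
    header = _build_tree(itemsets, [1] * n, order)
    raw: list[tuple[frozenset[str], int]] = []
    _mine(header, order, minc, frozenset(), raw)
    patterns = [
        Pattern(items=items, support_count=c, support=c / n) for items, c in raw
    ]
    patterns.sort(key=lambda p: (-p.support_count, p.render()))
    return patterns
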