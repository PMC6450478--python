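"""Independent brute-force oracles for the three miners.

These enumerate candidate patterns exhaustively (no pruning) and count or
score them by direct embedding search, so they share no code path with the
miners they check.
"""

from __future__ import annotations

import itertools
from math import inf


# --- frequent itemsets -----------------------------------------------------


def brute_frequent_itemsets(transactions, min_support):
    """All itemsets with support >= min_support, by subset enumeration."""
    import math

    txns = [frozenset(t) for t in transactions]
    n = len(txns)
    minc = max(1, math.ceil(min_support * n - 1e-9))
    universe = sorted(set().union(*txns)) if txns else []
    out = {}
    for size in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            items = frozenset(combo)
            count = sum(1 for t in txns if items <= t)
            if count >= minc:
                out[items] = count
    return out


# --- sequential patterns ---------------------------------------------------


def seq_contains(sequence, pattern):
    """Existence of an order-preserving element-subset embedding, by
    exhaustive recursive search."""
    seq = [frozenset(e) for e in sequence]
    pat = [frozenset(e) for e in pattern]

    def rec(p_idx, start):
        if p_idx == len(pat):
            return True
        for f in range(start, len(seq)):
            if pat[p_idx] <= seq[f] and rec(p_idx + 1, f + 1):
                return True
        return False

    return rec(0, 0)


def enumerate_patterns(universe, max_items, max_elements=None):
    """Every sequence of non-empty sorted item subsets with at most
    ``max_items`` total items (and optionally at most ``max_elements``
    elements), as tuples of tuples."""
    universe = sorted(universe)
    subsets = []
    for size in range(1, max_items + 1):
        subsets.extend(itertools.combinations(universe, size))

    out = []

    def rec(prefix, budget):
        for s in subsets:
            if len(s) > budget:
                continue
            pat = prefix + [s]
            out.append(tuple(pat))
            if max_elements is None or len(pat) < max_elements:
                rec(pat, budget - len(s))

    rec([], max_items)
    return out


def brute_sequential_patterns(sequences, min_support, max_items):
    """All sequential patterns with support >= min_support and at most
    ``max_items`` items, by full enumeration + embedding search."""
    import math

    n = len(sequences)
    minc = max(1, math.ceil(min_support * n - 1e-9))
    universe = set()
    for s in sequences:
        for e in s:
            universe.update(e)
    out = {}
    for pat in enumerate_patterns(universe, max_items):
        count = sum(1 for s in sequences if seq_contains(s, pat))
        if count >= minc:
            out[pat] = count
    return out


# --- high-utility sequential patterns --------------------------------------


def max_occurrence_utility(sequence, pattern):
    """Maximum occurrence utility of ``pattern`` in one utility sequence
    (a list of dicts item -> utility); -inf when the pattern is absent."""
    seq = [dict(e) for e in sequence]
    pat = [tuple(e) for e in pattern]

    def rec(p_idx, start):
        if p_idx == len(pat):
            return 0.0
        best = -inf
        for f in range(start, len(seq)):
            el = seq[f]
            if all(i in el for i in pat[p_idx]):
                rest = rec(p_idx + 1, f + 1)
                if rest > -inf:
                    cand = sum(el[i] for i in pat[p_idx]) + rest
                    best = max(best, cand)
        return best

    return rec(0, 0)


def brute_pattern_utility(sequences, pattern):
    total = 0.0
    for s in sequences:
        u = max_occurrence_utility(s, pattern)
        if u > -inf:
            total += u
    return total


def brute_high_utility(sequences, min_utility, max_items):
    """All patterns with database utility >= min_utility, fully enumerated."""
    universe = set()
    for s in sequences:
        for e in s:
            universe.update(dict(e))
    out = {}
    for pat in enumerate_patterns(universe, max_items):
        u = brute_pattern_utility(sequences, pat)
        if u + 1e-9 >= min_utility:
            out[pat] = u
    return out
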