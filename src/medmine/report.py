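"""Reporting: top-k ranking, cross-algorithm comparison, frequency and
route summaries, and Fleiss kappa for expert ratings.

The comparison table mirrors the study workflow: the top k (default 10)
patterns from each of the three miners in each of the six age groups are
aligned into one union table of distinct medication combinations, where a
combination's identity is its flattened item set (an unordered itemset and a
sequential pattern count as the same combination when their item sets are
equal), and each row carries per-algorithm renderings plus age-group
presence flags.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats import inter_rater

from .emr_model import AGE_GROUPS, AdminRecord, ValidationError
from .fpgrowth import Pattern
from .prefixspan import SequentialPattern
from .uspan import UtilityPattern

__all__ = [
    "ComparisonRow",
    "PatternReport",
    "RouteShare",
    "build_comparison",
    "fleiss_kappa",
    "flattened_items",
    "frequency_table",
    "load_rater_table",
    "pattern_score",
    "render_pattern",
    "route_share",
    "top_k",
]

log = logging.getLogger(__name__)

AnyPattern = Pattern | SequentialPattern | UtilityPattern


def render_pattern(p: AnyPattern) -> str:
    return p.render()


def flattened_items(p: AnyPattern) -> frozenset[str]:
    """The unordered set of medications a pattern involves."""
    if isinstance(p, Pattern):
        return p.items
    return frozenset(i for e in p.elements for i in e)


def pattern_score(p: AnyPattern) -> float:
    """The pattern's ranking score: utility for utility patterns, support
    otherwise."""
    return p.utility if isinstance(p, UtilityPattern) else p.support


def top_k(
    patterns: Iterable[AnyPattern],
    k: int,
    score: Callable[[AnyPattern], float] | None = None,
) -> list[AnyPattern]:
    """The k best patterns: score descending, ties by support count then by
    rendered pattern (lexicographic), deterministically."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    score = score or pattern_score
    ranked = sorted(
        patterns, key=lambda p: (-score(p), -p.support_count, render_pattern(p))
    )
    return ranked[:k]


# ---------------------------------------------------------------------------
# Frequency and route summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RouteShare:
    count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.count / self.total


def route_share(records: Sequence[AdminRecord], route_class: Iterable[str]) -> RouteShare:
    """Fraction of administration records whose (merged) route is in
    ``route_class``, with numerator and denominator."""
    records = list(records)
    if not records:
        raise ValidationError("route_share is undefined on an empty record set")
    routes = frozenset(route_class)
    count = sum(1 for r in records if r.route in routes)
    return RouteShare(count=count, total=len(records))


@dataclass(frozen=True)
class FrequencyTable:
    """Per-stratum medication counts/proportions and global top-n coverage."""

    per_stratum: pd.DataFrame  # columns: stratum, medication, count, proportion
    global_counts: pd.DataFrame  # columns: medication, count, proportion
    top_n: int
    top_n_coverage: float  # summed global proportion of the top_n medications


def frequency_table(
    records: Sequence[AdminRecord],
    by: str = "age_group",
    top_n: int = 40,
) -> FrequencyTable:
    """Medication frequency summaries, stratified by age group or calendar
    year, plus the share of records covered by the globally top-n most
    frequent medications."""
    if by not in ("age_group", "calendar_year"):
        raise ValidationError("by must be 'age_group' or 'calendar_year'")
    rows = [
        {
            "stratum": r.age_group if by == "age_group" else r.admin_date.year,
            "medication": r.medication,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["stratum", "medication"])
    global_counts = (
        df.groupby("medication", sort=True).size().rename("count").reset_index()
    )
    total = int(global_counts["count"].sum()) if len(global_counts) else 0
    if total:
        global_counts["proportion"] = global_counts["count"] / total
    else:
        global_counts["proportion"] = pd.Series(dtype=float)
    global_counts = global_counts.sort_values(
        ["count", "medication"], ascending=[False, True]
    ).reset_index(drop=True)
    coverage = float(global_counts.head(top_n)["proportion"].sum()) if total else 0.0
    per_stratum = (
        df.groupby(["stratum", "medication"], sort=True).size().rename("count").reset_index()
    )
    if len(per_stratum):
        per_stratum["proportion"] = per_stratum["count"] / per_stratum.groupby("stratum")[
            "count"
        ].transform("sum")
    else:
        per_stratum["proportion"] = pd.Series(dtype=float)
    return FrequencyTable(
        per_stratum=per_stratum,
        global_counts=global_counts,
        top_n=top_n,
        top_n_coverage=coverage,
    )


# ---------------------------------------------------------------------------
# Fleiss kappa
# ---------------------------------------------------------------------------


def fleiss_kappa(table) -> float:
    """Chance-corrected agreement among n raters assigning categories.

    ``table`` is subjects x categories, each cell the number of raters who
    assigned that category to that subject; every row must sum to the same
    number of raters n >= 2.  Returns kappa in [-1, 1]; raises
    :class:`ValidationError` when expected agreement is 1 (all ratings in a
    single category), where kappa is undefined.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("rater table must be 2-D with >=2 subjects and >=2 categories")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValidationError("rater table cells must be non-negative integer counts")
    n_raters = arr.sum(axis=1)
    if not np.all(n_raters == n_raters[0]):
        raise ValidationError("every subject must be rated by the same number of raters")
    if n_raters[0] < 2:
        raise ValidationError("at least 2 raters are required")
    marginals = arr.sum(axis=0) / arr.sum()
    p_e = float(np.sum(marginals**2))
    if p_e >= 1.0 - 1e-12:
        raise ValidationError("kappa undefined: all ratings fall in a single category")
    return float(inter_rater.fleiss_kappa(arr, method="fleiss"))


def load_rater_table(path) -> np.ndarray:
    """Read a rating-count CSV (subject_id, then one column per category)."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValidationError("rating CSV needs a subject_id column plus >=2 category columns")
    return df.iloc[:, 1:].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Cross-algorithm comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonRow:
    """One distinct medication combination, aligned across algorithms."""

    items: frozenset[str]
    #: algorithm -> sorted tuple of canonical renderings found for this combination
    renderings: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: algorithm -> set of age groups in which the combination appeared
    age_groups: dict[str, set[str]] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return ";".join(sorted(self.items))


@dataclass
class PatternReport:
    """Top-k patterns per (algorithm, age group) with cross-algorithm
    alignment — the machine form of a select-results table."""

    k: int
    algorithms: tuple[str, ...]
    #: (algorithm, age_group) -> ranked top-k patterns (may be empty)
    cells: dict[tuple[str, str], list[AnyPattern]]
    rows: list[ComparisonRow]

    @property
    def n_distinct_combinations(self) -> int:
        return len(self.rows)

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "algorithms": list(self.algorithms),
            "n_distinct_combinations": self.n_distinct_combinations,
            "rows": [
                {
                    "combination": row.key,
                    "renderings": {a: list(r) for a, r in sorted(row.renderings.items())},
                    "age_groups": {a: sorted(g) for a, g in sorted(row.age_groups.items())},
                }
                for row in self.rows
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            header = ["combination"]
            for a in self.algorithms:
                header.append(a)
            header.extend(AGE_GROUPS)
            writer.writerow(header)
            for row in self.rows:
                out = [row.key]
                for a in self.algorithms:
                    out.append(" | ".join(row.renderings.get(a, ())) or "-")
                present = set().union(*row.age_groups.values()) if row.age_groups else set()
                out.extend("x" if g in present else "" for g in AGE_GROUPS)
                writer.writerow(out)


_EXPECTED_TYPE = {
    "fpgrowth": Pattern,
    "prefixspan": SequentialPattern,
    "uspan": UtilityPattern,
}


def build_comparison(
    reports: Mapping[str, Mapping[str, Sequence[AnyPattern]]],
    k: int = 10,
) -> PatternReport:
    """Align per-algorithm, per-age-group top-k results into one report.

    ``reports`` maps algorithm name -> age group -> ranked patterns (each
    cell is truncated to k here, so callers may pass full result lists).
    All algorithms must report over the same age-group set, and each
    algorithm's patterns must be of its own result type; anything else is a
    mixed-provenance error.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not reports:
        raise ValidationError("no algorithm reports given")
    group_sets = {a: frozenset(cells) for a, cells in reports.items()}
    if len(set(group_sets.values())) != 1:
        raise ValidationError(
            "mixed-provenance reports: algorithms cover different age-group sets"
        )
    algorithms = tuple(sorted(reports))
    cells: dict[tuple[str, str], list[AnyPattern]] = {}
    rows_by_key: dict[frozenset[str], ComparisonRow] = {}
    for algo in algorithms:
        expected = _EXPECTED_TYPE.get(algo)
        for group, patterns in sorted(reports[algo].items()):
            ranked = top_k(patterns, k) if patterns else []
            for p in ranked:
                if expected is not None and not isinstance(p, expected):
                    raise ValidationError(
                        f"mixed-provenance reports: {algo} cell contains {type(p).__name__}"
                    )
            cells[(algo, group)] = ranked
            for p in ranked:
                key = flattened_items(p)
                row = rows_by_key.get(key)
                if row is None:
                    row = rows_by_key[key] = ComparisonRow(items=key)
                rend = render_pattern(p)
                existing = row.renderings.get(algo, ())
                if rend not in existing:
                    row.renderings[algo] = tuple(sorted(existing + (rend,)))
                row.age_groups.setdefault(algo, set()).add(group)
    rows = sorted(rows_by_key.values(), key=lambda r: r.key)
    return PatternReport(k=k, algorithms=algorithms, cells=cells, rows=rows)
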