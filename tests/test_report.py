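"""Top-k ranking, summaries, Fleiss kappa, cross-algorithm comparison."""

import numpy as np
import pytest

from medmine import (
    ValidationError,
    build_comparison,
    fleiss_kappa,
    frequency_table,
    route_share,
    top_k,
)
from medmine.fpgrowth import Pattern
from medmine.prefixspan import SequentialPattern
from medmine.uspan import UtilityPattern

from conftest import make_record


def fp(items, count, n):
    return Pattern(items=frozenset(items), support_count=count, support=count / n)


def sp(elements, count, n):
    return SequentialPattern(elements=tuple(map(tuple, elements)), support_count=count, support=count / n)


def up(elements, utility, count):
    return UtilityPattern(elements=tuple(map(tuple, elements)), utility=utility, support_count=count)


class TestTopK:
    def test_returns_all_when_fewer_than_k(self):
        pats = [fp("A", 3, 10), fp("B", 2, 10), fp("C", 1, 10)]
        assert len(top_k(pats, 10)) == 3

    def test_tie_broken_lexicographically(self):
        pats = [fp("B", 2, 10), fp("A", 2, 10)]
        assert [p.render() for p in top_k(pats, 2)] == ["(A)", "(B)"]

    def test_agrees_with_full_sort(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            pats = [
                fp(chr(65 + i), int(rng.integers(1, 6)), 10) for i in range(8)
            ]
            k = int(rng.integers(1, 9))
            ranked = sorted(
                pats, key=lambda p: (-p.support, -p.support_count, p.render())
            )
            assert top_k(pats, k) == ranked[:k]

    def test_k_must_be_positive(self):
        with pytest.raises(ValidationError):
            top_k([], 0)


class TestRouteShare:
    def test_fraction_with_counts(self):
        records = [make_record(route="IV", day=d) for d in range(4)] + [
            make_record(route="PO", day=d) for d in range(6)
        ]
        share = route_share(records, ["IV"])
        assert (share.count, share.total, share.fraction) == (4, 10, 0.4)

    def test_full_cover_is_one(self):
        records = [make_record(route=r) for r in ("IV", "PO", "INH")]
        assert route_share(records, ["IV", "PO", "INH"]).fraction == 1.0

    def test_partition_sums_to_one(self):
        records = [make_record(route=r, day=d) for d, r in enumerate("ABABCA")]
        total = sum(route_share(records, [r]).fraction for r in "ABC")
        assert total == pytest.approx(1.0)

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            route_share([], ["IV"])


class TestFrequencyTable:
    def test_uniform_proportions(self):
        records = [make_record(medication=m, day=d) for d, m in enumerate("ABCDE")]
        table = frequency_table(records, top_n=5)
        assert all(table.global_counts["proportion"] == 0.2)

    def test_top_n_coverage_hand_count(self):
        # top-2 medications cover 30 of 40 records
        records = (
            [make_record(medication="A", day=d % 9) for d in range(18)]
            + [make_record(medication="B", day=d % 9) for d in range(12)]
            + [make_record(medication=m, day=0) for m in "CDEFGHIJKL"]
        )
        table = frequency_table(records, top_n=2)
        assert table.top_n_coverage == pytest.approx(30 / 40)

    def test_stratified_counts_sum_to_global(self):
        from datetime import date

        records = [
            make_record(episode_id="E1", medication="A", birth=date(2014, 12, 1)),
            make_record(episode_id="E2", medication="A", birth=date(2008, 1, 1)),
            make_record(episode_id="E3", medication="B", birth=date(2013, 1, 1)),
        ]
        table = frequency_table(records)
        per_med = table.per_stratum.groupby("medication")["count"].sum()
        for _, row in table.global_counts.iterrows():
            assert per_med[row["medication"]] == row["count"]


class TestFleissKappa:
    def test_perfect_agreement(self):
        table = [[4, 0], [0, 4], [4, 0]]
        assert fleiss_kappa(table) == pytest.approx(1.0)

    def test_hand_computed_small_table(self):
        # 4 subjects x 3 categories, 4 raters; worked through the definition
        # by hand: mean per-subject agreement 0.5, expected agreement
        # 0.40625, kappa = 0.09375 / 0.59375 = 3/19
        table = [[3, 1, 0], [0, 4, 0], [1, 1, 2], [2, 2, 0]]
        assert fleiss_kappa(table) == pytest.approx(3 / 19, abs=1e-9)

    def test_random_ratings_near_zero(self):
        rng = np.random.default_rng(42)
        n_subjects, n_raters = 4000, 8
        assignments = rng.integers(0, 2, size=(n_subjects, n_raters))
        table = np.stack(
            [(assignments == c).sum(axis=1) for c in range(2)], axis=1
        )
        assert abs(fleiss_kappa(table)) < 0.02

    def test_single_category_undefined(self):
        with pytest.raises(ValidationError):
            fleiss_kappa([[4, 0], [4, 0]])

    def test_unbalanced_raters_rejected(self):
        with pytest.raises(ValidationError):
            fleiss_kappa([[3, 1], [2, 1]])

    def test_subject_order_and_relabeling_invariance(self):
        table = np.array([[3, 1, 0], [0, 4, 0], [1, 1, 2], [2, 2, 0]])
        base = fleiss_kappa(table)
        assert fleiss_kappa(table[::-1]) == pytest.approx(base)
        assert fleiss_kappa(table[:, [2, 0, 1]]) == pytest.approx(base)


class TestBuildComparison:
    def test_same_combination_aligned_across_algorithms(self):
        reports = {
            "fpgrowth": {"0-3m": [fp(["A", "B"], 5, 10)]},
            "prefixspan": {"0-3m": [sp([["A"], ["B"]], 4, 10)]},
            "uspan": {"0-3m": []},
        }
        report = build_comparison(reports, k=10)
        assert report.n_distinct_combinations == 1
        (row,) = report.rows
        assert set(row.renderings) == {"fpgrowth", "prefixspan"}
        assert row.age_groups["fpgrowth"] == {"0-3m"}

    def test_empty_cell_rendered_absent(self, tmp_path):
        reports = {
            "fpgrowth": {"0-3m": [fp(["A", "B"], 5, 10)]},
            "uspan": {"0-3m": []},
        }
        report = build_comparison(reports, k=10)
        path = tmp_path / "cmp.tsv"
        report.to_tsv(path)
        line = path.read_text().splitlines()[1].split("\t")
        assert line[2] == "-"  # the uspan column shows no result

    def test_distinct_count_with_known_overlaps(self):
        reports = {
            "fpgrowth": {
                "0-3m": [fp(["A", "B"], 5, 10), fp(["C"], 5, 10)],
                ">5y": [fp(["A", "B"], 3, 10)],
            },
            "uspan": {
                "0-3m": [up([["A"], ["B"]], 900.0, 4)],
                ">5y": [up([["D", "E"]], 700.0, 2)],
            },
        }
        report = build_comparison(reports, k=10)
        # {A,B} (shared), {C}, {D,E} -> 3 distinct combinations
        assert report.n_distinct_combinations == 3
        assert report.n_distinct_combinations <= 2 * 2 * 10

    def test_mismatched_age_groups_rejected(self):
        with pytest.raises(ValidationError):
            build_comparison(
                {"fpgrowth": {"0-3m": []}, "uspan": {">5y": []}}
            )

    def test_wrong_pattern_type_in_cell_rejected(self):
        with pytest.raises(ValidationError):
            build_comparison({"fpgrowth": {"0-3m": [sp([["A"]], 1, 2)]}})

    def test_cells_truncated_to_k(self):
        reports = {"fpgrowth": {"g": [fp([chr(65 + i)], 10 - i, 10) for i in range(15)]}}
        report = build_comparison(reports, k=10)
        assert len(report.cells[("fpgrowth", "g")]) == 10
        assert report.n_distinct_combinations == 10
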