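"""PrefixSpan: worked example, containment, gaps, oracle equivalence."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medmine import (
    ValidationError,
    build_sequence_db,
    contains,
    mean_time_gap,
    mine_sequential_patterns,
)

from _oracles import brute_sequential_patterns, seq_contains
from conftest import make_record, random_sequence_db


def as_dict(patterns):
    return {p.elements: p.support_count for p in patterns}


class TestContains:
    def test_subset_embedding(self):
        assert contains([("A", "B"), ("C",)], [("A",), ("C",)])

    def test_order_violation(self):
        assert not contains([("C",), ("A", "B")], [("A",), ("C",)])

    def test_reflexive(self):
        seq = [("A", "B"), ("D",), ("A",)]
        assert contains(seq, seq)

    def test_element_subset_weakening(self):
        seq = [("A", "B", "C"), ("D", "E")]
        assert contains(seq, [("A", "C"), ("D",)])

    def test_agrees_with_bruteforce(self):
        rng = random.Random(31)
        checked = 0
        for _ in range(300):
            seqs = random_sequence_db(rng)
            seq = seqs[0]
            pat = random_sequence_db(rng, max_items=4, max_seqs=1, max_elements=3)[0]
            assert contains(seq, pat) == seq_contains(seq, pat)
            checked += 1
        assert checked == 300


class TestMining:
    def test_single_patient_worked_example(self):
        """A on day 1, B on day 1, D on day 5, A on day 8, B on day 9 gives
        the maximal pattern <(A,B),(D),(A),(B)> at full support."""
        db = [[("A", "B"), ("D",), ("A",), ("B",)]]
        patterns = as_dict(mine_sequential_patterns(db, 1.0, max_length=5))
        assert patterns[(("A", "B"), ("D",), ("A",), ("B",))] == 1
        max_items = max(sum(len(e) for e in p) for p in patterns)
        assert max_items == 5  # nothing longer than the sequence itself

    def test_no_frequent_items_gives_empty(self):
        db = [[("A",)], [("B",)], [("C",)]]
        assert mine_sequential_patterns(db, 0.9) == []

    def test_empty_db(self):
        assert mine_sequential_patterns([], 0.5) == []

    def test_max_length_bounds_item_count(self):
        db = [[("A", "B"), ("A", "B"), ("A", "B")]]
        patterns = mine_sequential_patterns(db, 1.0, max_length=3)
        assert all(p.n_items <= 3 for p in patterns)

    def test_oracle_equivalence_on_200_random_dbs(self):
        """Identical pattern sets and supports vs unpruned enumeration with
        brute-force embedding search, on 200 random small databases."""
        rng = random.Random(20240902)
        for trial in range(200):
            seqs = random_sequence_db(rng)
            min_support = rng.choice([0.2, 0.4, 0.6, 1.0])
            expected = brute_sequential_patterns(seqs, min_support, max_items=4)
            got = as_dict(mine_sequential_patterns(seqs, min_support, max_length=4))
            assert got == expected, f"trial {trial}: ms={min_support}, db={seqs}"

    def test_prefix_antimonotonicity(self):
        """Every proper prefix of a returned pattern is returned, with
        support at least the pattern's."""
        rng = random.Random(5)
        for _ in range(30):
            seqs = random_sequence_db(rng)
            patterns = as_dict(mine_sequential_patterns(seqs, 0.4, max_length=4))
            for elements, count in patterns.items():
                if len(elements) > 1:
                    prefix = elements[:-1]
                    assert prefix in patterns and patterns[prefix] >= count
                if len(elements[-1]) > 1:
                    shrunk = elements[:-1] + (elements[-1][:-1],)
                    assert shrunk in patterns and patterns[shrunk] >= count

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_sequence_order_invariance(self, seed):
        rng = random.Random(seed)
        seqs = random_sequence_db(rng)
        base = as_dict(mine_sequential_patterns(seqs, 0.4, max_length=4))
        rng.shuffle(seqs)
        assert as_dict(mine_sequential_patterns(seqs, 0.4, max_length=4)) == base


class TestMeanTimeGap:
    def test_single_gap(self):
        db = build_sequence_db(
            [make_record(medication="A", day=1), make_record(medication="B", day=8)]
        )
        assert mean_time_gap(db, [("A",), ("B",)]) == 7.0

    def test_mean_over_supporting_sequences(self):
        records = [
            make_record(episode_id="EP1", medication="A", day=0),
            make_record(episode_id="EP1", medication="B", day=4),
            make_record(episode_id="EP2", medication="A", day=1),
            make_record(episode_id="EP2", medication="B", day=7),
        ]
        db = build_sequence_db(records)
        assert mean_time_gap(db, [("A",), ("B",)]) == 5.0

    def test_unsupported_pattern_is_absent(self):
        db = build_sequence_db([make_record(medication="A")])
        assert mean_time_gap(db, [("A",), ("B",)]) is None

    def test_requires_two_elements(self):
        db = build_sequence_db([make_record(medication="A")])
        with pytest.raises(ValidationError):
            mean_time_gap(db, [("A",)])

    def test_earliest_embedding_convention(self):
        # A on days 0 and 5, B on day 6: the gap is measured from day 0
        records = [
            make_record(medication="A", day=0),
            make_record(medication="A", day=5),
            make_record(medication="B", day=6),
        ]
        db = build_sequence_db(records)
        assert mean_time_gap(db, [("A",), ("B",)]) == 6.0
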