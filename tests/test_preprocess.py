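"""Cleaning and the three database forms built from records."""

import pytest

from medmine import (
    ValidationError,
    build_sequence_db,
    build_transaction_db,
    build_utility_db,
    clean,
)

from conftest import make_record


class TestClean:
    def test_diluents_removed_with_count(self, catalog):
        records = [make_record(medication="AMOXICILLIN", day=d) for d in range(6)] + [
            make_record(medication="D5W", day=0),
            make_record(medication="Normal Saline", day=1),
            make_record(medication="D5W", day=2),
            make_record(medication="NS", day=3),
        ]
        result = clean(records, catalog)
        assert result.n_output == 6
        assert result.removed_diluents == 4

    def test_conservation(self, catalog):
        records = [make_record(medication=m, day=i) for i, m in enumerate(
            ["AMOXICILLIN", "D5W", "CEFOTAXIME", "NS", "ALBUTEROL"]
        )]
        result = clean(records, catalog)
        assert len(records) == result.n_output + result.removed_diluents

    def test_route_merged(self, catalog):
        result = clean([make_record(route="IV drip")], catalog)
        assert result.records[0].route == "IV"

    def test_empty_input(self, catalog):
        result = clean([], catalog)
        assert result.records == () and result.removed_diluents == 0

    def test_unknown_policy_error(self, catalog):
        with pytest.raises(ValidationError):
            clean([make_record(medication="MYSTERY")], catalog, unknown_policy="error")

    def test_unknown_policy_warn_passes_through(self, catalog):
        result = clean([make_record(medication="MYSTERY")], catalog)
        assert result.records[0].medication == "MYSTERY"
        assert result.unknown_medications == ("MYSTERY",)


class TestTransactionDb:
    def test_order_ignored_across_episodes(self):
        # one episode A then B, another B then A: both transactions are {A,B}
        records = [
            make_record(episode_id="EP1", medication="A", day=0),
            make_record(episode_id="EP1", medication="B", day=1),
            make_record(episode_id="EP2", medication="B", day=9),
            make_record(episode_id="EP2", medication="A", day=20, stay=30),
        ]
        db = build_transaction_db(records)
        assert [t.items for t in db.transactions] == [frozenset("AB"), frozenset("AB")]

    def test_repeats_deduplicate(self):
        records = [make_record(medication="A", day=d) for d in range(5)]
        db = build_transaction_db(records)
        assert len(db) == 1 and db.transactions[0].items == frozenset("A")

    def test_age_group_partitioning(self):
        from datetime import date

        records = [
            make_record(episode_id="EP1", birth=date(2014, 12, 1)),  # 0-3m
            make_record(episode_id="EP2", birth=date(2014, 11, 20)),  # 0-3m
            make_record(episode_id="EP3", birth=date(2008, 1, 1)),  # >5y
        ]
        dbs = build_transaction_db(records, by_age_group=True)
        assert {g: len(db) for g, db in dbs.items()} == {"0-3m": 2, ">5y": 1}


class TestSequenceDb:
    def test_same_day_grouped_and_day_ordered(self):
        records = [
            make_record(medication="A", day=0),
            make_record(medication="B", day=0),
            make_record(medication="D", day=4),
            make_record(medication="A", day=7),
            make_record(medication="B", day=8),
        ]
        entry = build_sequence_db(records).entries[0]
        assert entry.elements == (("A", "B"), ("D",), ("A",), ("B",))
        assert entry.days == (0, 4, 7, 8)

    def test_single_administration(self):
        entry = build_sequence_db([make_record(medication="A")]).entries[0]
        assert entry.elements == (("A",),)

    def test_flatten_matches_transaction_db(self, catalog):
        records = [
            make_record(medication=m, day=d)
            for d, m in enumerate(["AMOXICILLIN", "CEFOTAXIME", "AMOXICILLIN", "ALBUTEROL"])
        ]
        seq = build_sequence_db(records).entries[0]
        txn = build_transaction_db(records).transactions[0]
        assert frozenset(i for e in seq.elements for i in e) == txn.items


class TestUtilityDb:
    def test_single_dose(self, catalog):
        # P(AMOXICILLIN) = 10, dose 5 -> utility 50
        db = build_utility_db([make_record(dose=5.0)], catalog)
        assert db.entries[0].elements == ((("AMOXICILLIN", 50.0),),)

    def test_same_day_doses_aggregate(self, catalog):
        db = build_utility_db(
            [make_record(dose=2.0), make_record(dose=3.0)], catalog
        )
        (elem,) = db.entries[0].elements
        assert elem == (("AMOXICILLIN", 50.0),)

    def test_zero_utility_value(self, catalog):
        db = build_utility_db([make_record(medication="D5W", dose=100.0)], catalog)
        assert db.entries[0].elements == ((("D5W", 0.0),),)

    def test_utilities_rederivable_by_groupby(self, catalog):
        """Independent pandas re-aggregation reproduces every item utility."""
        import pandas as pd

        records = [
            make_record(medication=m, day=d, dose=q)
            for m, d, q in [
                ("AMOXICILLIN", 0, 1.0),
                ("AMOXICILLIN", 0, 2.0),
                ("CEFOTAXIME", 0, 4.0),
                ("AMOXICILLIN", 1, 3.0),
                ("ALBUTEROL", 2, 2.0),
            ]
        ]
        db = build_utility_db(records, catalog)
        df = pd.DataFrame(
            {
                "day": [r.day_offset for r in records],
                "med": [r.medication for r in records],
                "dose": [r.dose_qty for r in records],
            }
        )
        expected = df.groupby(["day", "med"])["dose"].sum()
        for day, elem in zip(db.entries[0].days, db.entries[0].elements):
            for med, utility in elem:
                assert utility == pytest.approx(
                    expected.loc[(day, med)] * catalog.utility_value(med)
                )

    def test_jsonl_round_trippable_shapes(self, tmp_path, catalog):
        records = [make_record(medication="AMOXICILLIN"), make_record(medication="ALBUTEROL", day=2)]
        for db in (
            build_transaction_db(records),
            build_sequence_db(records),
            build_utility_db(records, catalog),
        ):
            path = tmp_path / "db.jsonl"
            db.to_jsonl(path)
            assert len(path.read_text().splitlines()) == 1
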