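"""Shared fixtures: a small medication catalog, hand-built records, and
random small-database generators used by the oracle-equivalence suites."""

from __future__ import annotations

import random
from datetime import date, timedelta

import pytest

from medmine import AdminRecord, CatalogEntry, MedicationCatalog


@pytest.fixture
def catalog() -> MedicationCatalog:
    return MedicationCatalog(
        entries={
            "AMOXICILLIN": CatalogEntry(utility_value=10.0, drug_class="antibiotic"),
            "CEFOTAXIME": CatalogEntry(utility_value=8.0, drug_class="antibiotic"),
            "ALBUTEROL": CatalogEntry(utility_value=5.0, drug_class="antiasthmatic"),
            "D5W": CatalogEntry(
                utility_value=0.0,
                is_diluent=True,
                drug_class="diluent",
                synonyms=("Dextrose 5% in Water",),
            ),
            "NS": CatalogEntry(
                utility_value=0.0,
                is_diluent=True,
                drug_class="diluent",
                synonyms=("Normal Saline",),
            ),
        },
        route_merge={"IV drip": "IV", "intravenous": "IV", "nebulization": "INH"},
    )


def make_record(
    episode_id="EP1",
    medication="AMOXICILLIN",
    day=0,
    route="IV",
    dose=1.0,
    stay=10,
    birth=date(2014, 6, 1),
    admission=date(2015, 1, 1),
    sex="male",
    unit="u",
) -> AdminRecord:
    return AdminRecord(
        episode_id=episode_id,
        patient_sex=sex,
        birth_date=birth,
        admission_date=admission,
        discharge_date=admission + timedelta(days=stay - 1),
        medication=medication,
        route=route,
        dose_qty=dose,
        dose_unit=unit,
        admin_date=admission + timedelta(days=day),
    )


def random_transaction_db(rng: random.Random, max_items=8, max_txns=10):
    items = [chr(ord("a") + i) for i in range(rng.randint(2, max_items))]
    n = rng.randint(1, max_txns)
    return [
        frozenset(rng.sample(items, rng.randint(1, len(items)))) for _ in range(n)
    ]


def random_sequence_db(rng: random.Random, max_items=5, max_seqs=6, max_elements=4):
    items = [chr(ord("a") + i) for i in range(rng.randint(2, max_items))]
    seqs = []
    for _ in range(rng.randint(1, max_seqs)):
        seq = []
        for _ in range(rng.randint(1, max_elements)):
            seq.append(tuple(sorted(rng.sample(items, rng.randint(1, min(3, len(items)))))))
        seqs.append(tuple(seq))
    return seqs


def random_utility_db(rng: random.Random, max_items=4, max_seqs=5, max_elements=4):
    items = [chr(ord("a") + i) for i in range(rng.randint(2, max_items))]
    seqs = []
    for _ in range(rng.randint(1, max_seqs)):
        seq = []
        for _ in range(rng.randint(1, max_elements)):
            chosen = rng.sample(items, rng.randint(1, min(3, len(items))))
            seq.append(tuple((i, float(rng.randint(1, 20))) for i in sorted(chosen)))
        seqs.append(tuple(seq))
    return seqs
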