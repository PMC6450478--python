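"""Cleaning and construction of the three mining database forms.

Cleaning merges similar routes of administration and removes diluents
(carriers such as 5% dextrose or normal saline, which deliver IV medications
but have no therapeutic intent of their own).  From the cleaned records three
databases are built, one entry per hospitalization episode:

* :class:`TransactionDB` — the unordered set of distinct medications per
  episode (input to FP-Growth);
* :class:`SequenceDB` — the day-ordered list of same-day medication sets
  (input to PrefixSpan);
* :class:`UtilitySequenceDB` — the same shape, with each (medication, day)
  item carrying a utility ``u = P(i) * q`` where ``q`` is the total dose
  quantity of that medication on that day.

Repeated same-day doses of one medication are aggregated into a single item
whose quantity is the day's total.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable

from .emr_model import AdminRecord, MedicationCatalog, ValidationError

__all__ = [
    "CleanResult",
    "SequenceDB",
    "SequenceEntry",
    "Transaction",
    "TransactionDB",
    "UtilitySequenceDB",
    "UtilitySequenceEntry",
    "clean",
    "build_transaction_db",
    "build_sequence_db",
    "build_utility_db",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleanResult:
    """Outcome of the cleaning pass, with counts for reconciliation."""

    records: tuple[AdminRecord, ...]
    removed_diluents: int
    unknown_medications: tuple[str, ...]

    @property
    def n_output(self) -> int:
        return len(self.records)


def clean(
    records: Iterable[AdminRecord],
    catalog: MedicationCatalog,
    unknown_policy: str = "warn",
) -> CleanResult:
    """Merge routes, canonicalize names, and drop diluent records.

    ``unknown_policy`` controls medications absent from the catalog:
    ``"warn"`` passes them through (their utility falls back to the catalog
    default) and logs once per name; ``"error"`` rejects the run.
    """
    if unknown_policy not in ("warn", "error"):
        raise ValidationError(f"unknown_policy must be 'warn' or 'error', got {unknown_policy!r}")
    out: list[AdminRecord] = []
    removed = 0
    unknown: set[str] = set()
    for r in records:
        name = catalog.canonical(r.medication)
        if name not in catalog.entries:
            unknown.add(name)
            if unknown_policy == "error":
                raise ValidationError(f"medication {name!r} absent from catalog")
        if catalog.is_diluent(name):
            removed += 1
            continue
        route = catalog.merge_route(r.route)
        if name != r.medication or route != r.route:
            r = AdminRecord(
                episode_id=r.episode_id,
                patient_sex=r.patient_sex,
                birth_date=r.birth_date,
                admission_date=r.admission_date,
                discharge_date=r.discharge_date,
                medication=name,
                route=route,
                dose_qty=r.dose_qty,
                dose_unit=r.dose_unit,
                admin_date=r.admin_date,
            )
        out.append(r)
    for name in sorted(unknown):
        log.warning("medication %r not in catalog; passed through with default utility", name)
    log.info("clean: %d records in, %d out, %d diluent records removed", len(out) + removed, len(out), removed)
    return CleanResult(records=tuple(out), removed_diluents=removed, unknown_medications=tuple(sorted(unknown)))


# ---------------------------------------------------------------------------
# Database forms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transaction:
    episode_id: str
    age_group: str
    items: frozenset[str]


@dataclass(frozen=True)
class TransactionDB:
    """One unordered medication set per hospitalization episode."""

    transactions: tuple[Transaction, ...]

    def __len__(self) -> int:
        return len(self.transactions)

    def itemsets(self) -> list[frozenset[str]]:
        return [t.items for t in self.transactions]

    def by_age_group(self) -> dict[str, "TransactionDB"]:
        groups: dict[str, list[Transaction]] = {}
        for t in self.transactions:
            groups.setdefault(t.age_group, []).append(t)
        return {g: TransactionDB(tuple(ts)) for g, ts in sorted(groups.items())}

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.transactions:
                fh.write(
                    json.dumps(
                        {"episode_id": t.episode_id, "age_group": t.age_group, "items": sorted(t.items)}
                    )
                    + "\n"
                )


@dataclass(frozen=True)
class SequenceEntry:
    episode_id: str
    age_group: str
    #: 0-based day offsets from admission, strictly increasing, one per element
    days: tuple[int, ...]
    #: per day, the lexicographically sorted tuple of distinct medications
    elements: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class SequenceDB:
    """One day-ordered sequence of same-day medication sets per episode."""

    entries: tuple[SequenceEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def sequences(self) -> list[tuple[tuple[str, ...], ...]]:
        return [e.elements for e in self.entries]

    def by_age_group(self) -> dict[str, "SequenceDB"]:
        groups: dict[str, list[SequenceEntry]] = {}
        for e in self.entries:
            groups.setdefault(e.age_group, []).append(e)
        return {g: SequenceDB(tuple(es)) for g, es in sorted(groups.items())}

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(
                    json.dumps(
                        {
                            "episode_id": e.episode_id,
                            "age_group": e.age_group,
                            "days": list(e.days),
                            "elements": [list(el) for el in e.elements],
                        }
                    )
                    + "\n"
                )


@dataclass(frozen=True)
class UtilitySequenceEntry:
    episode_id: str
    age_group: str
    days: tuple[int, ...]
    #: per day, ((medication, utility), ...) sorted by medication
    elements: tuple[tuple[tuple[str, float], ...], ...]


@dataclass(frozen=True)
class UtilitySequenceDB:
    """A sequence database whose items carry utilities u = P(i) * q."""

    entries: tuple[UtilitySequenceEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def by_age_group(self) -> dict[str, "UtilitySequenceDB"]:
        groups: dict[str, list[UtilitySequenceEntry]] = {}
        for e in self.entries:
            groups.setdefault(e.age_group, []).append(e)
        return {g: UtilitySequenceDB(tuple(es)) for g, es in sorted(groups.items())}

    def total_utility(self) -> float:
        return sum(u for e in self.entries for el in e.elements for _, u in el)

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(
                    json.dumps(
                        {
                            "episode_id": e.episode_id,
                            "age_group": e.age_group,
                            "days": list(e.days),
                            "elements": [[[m, u] for m, u in el] for el in e.elements],
                        }
                    )
                    + "\n"
                )


def _episodes(records: Iterable[AdminRecord]):
    """Group records by episode, keyed deterministically by episode_id."""
    by_ep: dict[str, list[AdminRecord]] = {}
    for r in records:
        by_ep.setdefault(r.episode_id, []).append(r)
    return sorted(by_ep.items())


def build_transaction_db(records: Iterable[AdminRecord], by_age_group: bool = False):
    """One transaction (the set of distinct medications) per episode."""
    txns = []
    for ep_id, recs in _episodes(records):
        txns.append(
            Transaction(
                episode_id=ep_id,
                age_group=recs[0].age_group,
                items=frozenset(r.medication for r in recs),
            )
        )
    db = TransactionDB(tuple(txns))
    return db.by_age_group() if by_age_group else db


def build_sequence_db(records: Iterable[AdminRecord], by_age_group: bool = False):
    """Per episode, same-day medications grouped into one element, day-ordered."""
    entries = []
    for ep_id, recs in _episodes(records):
        by_day: dict[int, set[str]] = {}
        for r in recs:
            by_day.setdefault(r.day_offset, set()).add(r.medication)
        days = tuple(sorted(by_day))
        entries.append(
            SequenceEntry(
                episode_id=ep_id,
                age_group=recs[0].age_group,
                days=days,
                elements=tuple(tuple(sorted(by_day[d])) for d in days),
            )
        )
    db = SequenceDB(tuple(entries))
    return db.by_age_group() if by_age_group else db


def build_utility_db(
    records: Iterable[AdminRecord],
    catalog: MedicationCatalog,
    by_age_group: bool = False,
):
    """Like :func:`build_sequence_db`, with per-item utilities P(i) * q.

    ``q`` is the summed same-day dose quantity of the medication within the
    episode; medications without a configured utility value use the catalog's
    default (1.0 unless overridden), so utility degrades to dose mass.
    """
    entries = []
    for ep_id, recs in _episodes(records):
        by_day: dict[int, dict[str, float]] = {}
        for r in recs:
            if r.dose_qty < 0:
                raise ValidationError(f"negative dose in episode {ep_id}")
            day = by_day.setdefault(r.day_offset, {})
            day[r.medication] = day.get(r.medication, 0.0) + r.dose_qty
        days = tuple(sorted(by_day))
        entries.append(
            UtilitySequenceEntry(
                episode_id=ep_id,
                age_group=recs[0].age_group,
                days=days,
                elements=tuple(
                    tuple(
                        (m, catalog.utility_value(m) * q)
                        for m, q in sorted(by_day[d].items())
                    )
                    for d in days
                ),
            )
        )
    db = UtilitySequenceDB(tuple(entries))
    return db.by_age_group() if by_age_group else db
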