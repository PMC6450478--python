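"""Domain types and file I/O for deidentified inpatient medication administration data.

The unit of analysis throughout the package is the *hospitalization episode*
(one admission-to-discharge stay); a rehospitalized patient contributes one
episode per stay.  An :class:`AdminRecord` is a single administration event:
which episode, which medication, by which route, how much, on which calendar
day.  Time is modeled at calendar-day granularity; intra-day ordering is not
represented.

A :class:`MedicationCatalog` carries the reference configuration the cleaning
and utility steps need: canonical medication names with synonym maps, diluent
(carrier) flags, per-medication utility values ``P(i)`` (utility per dose
unit), drug-class annotations, and a raw-to-merged route map.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping

__all__ = [
    "AGE_GROUPS",
    "AdminRecord",
    "CatalogEntry",
    "MedicationCatalog",
    "RowError",
    "SchemaError",
    "ValidationError",
    "age_in_months",
    "assign_age_group",
    "read_admin_records",
    "write_admin_records",
]


class SchemaError(ValueError):
    """The input file does not have the documented column schema."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


#: The six pediatric age groups, labeled by age at admission.  Together they
#: partition [0 years, 18 years); boundaries are half-open in calendar months:
#: [0,3m), [3m,6m), [6m,12m), [1y,2y), [2y,5y), [5y,18y).
AGE_GROUPS: tuple[str, ...] = ("0-3m", "3-6m", "6-12m", "1-2y", "2-5y", ">5y")

_GROUP_UPPER_MONTHS: tuple[int, ...] = (3, 6, 12, 24, 60, 216)

#: Columns of the flat CSV interchange format, in order.
CSV_COLUMNS: tuple[str, ...] = (
    "episode_id",
    "patient_sex",
    "birth_date",
    "admission_date",
    "discharge_date",
    "medication",
    "route",
    "dose_qty",
    "dose_unit",
    "admin_date",
)


def age_in_months(birth_date: date, admission_date: date) -> int:
    """Age at admission in whole calendar months (floor).

    A month boundary falls on the same day-of-month as the birth date, so a
    child born on Jan 1 turns 3 months old on Apr 1.
    """
    if admission_date < birth_date:
        raise ValidationError(
            f"admission date {admission_date} precedes birth date {birth_date}"
        )
    months = (admission_date.year - birth_date.year) * 12 + (
        admission_date.month - birth_date.month
    )
    if admission_date.day < birth_date.day:
        months -= 1
    return months


def assign_age_group(birth_date: date, admission_date: date) -> str:
    """Return the unique age-group label containing the age at admission.

    Age is the difference between admission date and birth date, in calendar
    months, and the six groups are half-open so that every age in
    [0, 18 years) belongs to exactly one group.

    Raises :class:`ValidationError` for a negative age or an age of 18 years
    or more.
    """
    months = age_in_months(birth_date, admission_date)
    for label, upper in zip(AGE_GROUPS, _GROUP_UPPER_MONTHS):
        if months < upper:
            return label
    raise ValidationError(
        f"age at admission ({months} months) is outside the pediatric range [0, 18y)"
    )


@dataclass(frozen=True)
class AdminRecord:
    """One medication administration event within a hospitalization episode."""

    episode_id: str
    patient_sex: str
    birth_date: date
    admission_date: date
    discharge_date: date
    medication: str
    route: str
    dose_qty: float
    dose_unit: str
    admin_date: date

    def validate(self) -> "AdminRecord":
        if self.patient_sex not in ("male", "female"):
            raise ValidationError(f"patient_sex must be male/female, got {self.patient_sex!r}")
        if self.birth_date > self.admission_date:
            raise ValidationError("birth_date must not be after admission_date")
        if not (self.admission_date <= self.admin_date <= self.discharge_date):
            raise ValidationError(
                "admin_date must lie within [admission_date, discharge_date]"
            )
        if self.dose_qty < 0:
            raise ValidationError("dose_qty must be non-negative")
        return self

    @property
    def age_group(self) -> str:
        return assign_age_group(self.birth_date, self.admission_date)

    @property
    def day_offset(self) -> int:
        """Administration day as a 0-based offset from admission."""
        return (self.admin_date - self.admission_date).days


@dataclass(frozen=True)
class CatalogEntry:
    """Reference data for one canonical medication."""

    utility_value: float = 1.0
    is_diluent: bool = False
    drug_class: str = ""
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.utility_value < 0:
            raise ValidationError("utility_value P(i) must be non-negative")


@dataclass
class MedicationCatalog:
    """The universal medication set I with utility values, flags and maps.

    ``entries`` is keyed by canonical medication name.  Raw names are resolved
    through each entry's synonym list; raw route labels are resolved through
    ``route_merge``.  Medications absent from the catalog resolve to
    themselves with ``default_utility`` and no diluent flag.
    """

    entries: dict[str, CatalogEntry] = field(default_factory=dict)
    route_merge: dict[str, str] = field(default_factory=dict)
    default_utility: float = 1.0

    def __post_init__(self) -> None:
        self._synonym_index: dict[str, str] = {}
        for name, entry in self.entries.items():
            for raw in entry.synonyms:
                if raw in self._synonym_index and self._synonym_index[raw] != name:
                    raise ValidationError(
                        f"synonym {raw!r} maps to both {self._synonym_index[raw]!r} and {name!r}"
                    )
                self._synonym_index[raw] = name

    def canonical(self, name: str) -> str:
        if name in self.entries:
            return name
        return self._synonym_index.get(name, name)

    def utility_value(self, name: str) -> float:
        entry = self.entries.get(self.canonical(name))
        return entry.utility_value if entry is not None else self.default_utility

    def is_diluent(self, name: str) -> bool:
        entry = self.entries.get(self.canonical(name))
        return entry.is_diluent if entry is not None else False

    def drug_class(self, name: str) -> str:
        entry = self.entries.get(self.canonical(name))
        return entry.drug_class if entry is not None else ""

    def merge_route(self, route: str) -> str:
        return self.route_merge.get(route, route)

    def __contains__(self, name: str) -> bool:
        return self.canonical(name) in self.entries

    # --- JSON round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "medications": {
                name: {
                    "P": entry.utility_value,
                    "is_diluent": entry.is_diluent,
                    "class": entry.drug_class,
                    "synonyms": list(entry.synonyms),
                }
                for name, entry in sorted(self.entries.items())
            },
            "route_merge": dict(sorted(self.route_merge.items())),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "MedicationCatalog":
        entries = {
            name: CatalogEntry(
                utility_value=float(spec.get("P", 1.0)),
                is_diluent=bool(spec.get("is_diluent", False)),
                drug_class=str(spec.get("class", "")),
                synonyms=tuple(spec.get("synonyms", ())),
            )
            for name, spec in payload.get("medications", {}).items()
        }
        return cls(entries=entries, route_merge=dict(payload.get("route_merge", {})))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "MedicationCatalog":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class RowError:
    """A malformed input row, reported with its 1-based line number."""

    line: int
    message: str


def _parse_row(row: Mapping[str, str]) -> AdminRecord:
    return AdminRecord(
        episode_id=row["episode_id"],
        patient_sex=row["patient_sex"],
        birth_date=date.fromisoformat(row["birth_date"]),
        admission_date=date.fromisoformat(row["admission_date"]),
        discharge_date=date.fromisoformat(row["discharge_date"]),
        medication=row["medication"],
        route=row["route"],
        dose_qty=float(row["dose_qty"]),
        dose_unit=row["dose_unit"],
        admin_date=date.fromisoformat(row["admin_date"]),
    ).validate()


def read_admin_records(
    path, catalog: MedicationCatalog | None = None
) -> tuple[list[AdminRecord], list[RowError]]:
    """Read administration records from the flat CSV interchange format.

    When a catalog is given, medication names are canonicalized through its
    synonym map and raw route labels are merged through its route map.
    Malformed rows (bad dates, negative doses, inverted date ranges) are
    collected as :class:`RowError` with their line numbers rather than
    silently dropped; a missing required column raises :class:`SchemaError`.
    """
    records: list[AdminRecord] = []
    errors: list[RowError] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError("input file is empty (no header row)")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        for row in reader:
            line = reader.line_num
            try:
                record = _parse_row(row)
            except (ValueError, KeyError, TypeError) as exc:
                errors.append(RowError(line=line, message=str(exc)))
                continue
            if catalog is not None:
                record = AdminRecord(
                    episode_id=record.episode_id,
                    patient_sex=record.patient_sex,
                    birth_date=record.birth_date,
                    admission_date=record.admission_date,
                    discharge_date=record.discharge_date,
                    medication=catalog.canonical(record.medication),
                    route=catalog.merge_route(record.route),
                    dose_qty=record.dose_qty,
                    dose_unit=record.dose_unit,
                    admin_date=record.admin_date,
                )
            records.append(record)
    return records, errors


def write_admin_records(path, records: Iterable[AdminRecord]) -> None:
    """Write records to the flat CSV interchange format (ISO-8601 dates)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.episode_id,
                    r.patient_sex,
                    r.birth_date.isoformat(),
                    r.admission_date.isoformat(),
                    r.discharge_date.isoformat(),
                    r.medication,
                    r.route,
                    repr(float(r.dose_qty)),
                    r.dose_unit,
                    r.admin_date.isoformat(),
                ]
            )
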