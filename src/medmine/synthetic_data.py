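"""Synthetic inpatient medication-administration data with planted patterns.

Real medication-administration extracts of the kind this package analyzes are
not publicly distributable, so the generator produces datasets with the same
statistical structure — six pediatric age groups with realistic proportions,
a stay-length distribution placing about 60% of episodes at 9-15 days, a
long-tailed medication catalog (~650 items whose top 40 cover ~74% of
records), IV-heavy route use with diluents co-administered alongside IV
medications — plus *planted* patterns with known ground truth:

* co-occurrence itemsets (for frequent-itemset mining),
* ordered two-element sequences with day-scale gaps (for sequential mining),
* low-frequency / high-dose combinations (for high-utility mining).

Background medication draws are independent per day given episode length, and
background items are disjoint from planted items, so a planted pattern's
mined support count equals the generator's ledger count exactly.  Everything
is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np

from .emr_model import (
    AGE_GROUPS,
    AdminRecord,
    CatalogEntry,
    MedicationCatalog,
    ValidationError,
    write_admin_records,
)

__all__ = [
    "GeneratorConfig",
    "PlantedHighUtility",
    "PlantedItemset",
    "PlantedSequence",
    "SyntheticDataset",
    "default_realistic_config",
    "generate",
    "write_dataset",
    "zipf_exponent_for_coverage",
]

#: raw route labels emitted in the CSV, per merged route class
ROUTE_VARIANTS: dict[str, tuple[str, ...]] = {
    "IV": ("IV", "IV drip", "intravenous"),
    "PO": ("PO", "oral"),
    "INH": ("inhalation", "nebulization"),
    "TOP": ("topical", "external use"),
}

#: half-open age ranges per group, in days since birth, kept a few days away
#: from the calendar-month boundaries so day-based sampling always lands in
#: the intended calendar-month group
_GROUP_DAY_RANGES: tuple[tuple[int, int], ...] = (
    (0, 84),
    (96, 176),
    (188, 360),
    (370, 725),
    (735, 1820),
    (1831, 6550),
)

_DILUENTS: dict[str, tuple[str, ...]] = {
    "D5W": ("Dextrose 5% in Water", "GS 5%"),
    "NS": ("Normal Saline", "0.9% Sodium Chloride"),
}


@dataclass(frozen=True)
class PlantedItemset:
    """A co-occurrence pattern: all items on one day of an episode."""

    items: tuple[str, ...]
    prevalence: float
    age_groups: tuple[str, ...] | None = None  # None = all groups
    route: str = "IV"
    drug_class: str = "planted"


@dataclass(frozen=True)
class PlantedSequence:
    """A two-element ordered pattern with a day-scale gap distribution."""

    elements: tuple[tuple[str, ...], ...]
    prevalence: float
    gap_mean_days: float
    age_groups: tuple[str, ...] | None = None
    route: str = "IV"
    drug_class: str = "planted"


@dataclass(frozen=True)
class PlantedHighUtility:
    """A low-prevalence, high-dose co-occurrence with a high utility value."""

    items: tuple[str, ...]
    prevalence: float
    dose_multiplier: float
    utility_value: float
    age_groups: tuple[str, ...] | None = None
    route: str = "IV"
    drug_class: str = "planted-high-utility"


@dataclass(frozen=True)
class GeneratorConfig:
    n_episodes: int
    seed: int = 0
    age_group_weights: tuple[float, ...] = (
        11453 / 30512,
        2439 / 30512,
        3096 / 30512,
        3317 / 30512,
        6103 / 30512,
        4104 / 30512,
    )
    male_share: float = 18419 / 30512
    #: probability mass over stay lengths 1..30 days; defaults place ~0.601
    #: of episodes at 9-15 days
    stay_pmf: tuple[float, ...] = ()
    catalog_size: int = 650
    #: Zipf exponent for background medication frequencies; None solves the
    #: exponent so the top 40 of ``catalog_size`` items carry
    #: ``top40_coverage_target`` of the background draws
    zipf_exponent: float | None = None
    top40_coverage_target: float = 0.7366
    background_meds_per_day: float = 1.8
    #: merged-route weights for background administrations
    route_weights: tuple[tuple[str, float], ...] = (
        ("IV", 0.34),
        ("PO", 0.415),
        ("INH", 0.10),
        ("TOP", 0.145),
    )
    diluent_attach_prob: float = 0.5
    synonym_emit_prob: float = 0.3
    dose_range: tuple[int, int] = (1, 4)
    utility_value_range: tuple[int, int] = (1, 10)
    admission_window: tuple[date, date] = (date(2010, 1, 1), date(2015, 12, 31))
    planted_itemsets: tuple[PlantedItemset, ...] = ()
    planted_sequences: tuple[PlantedSequence, ...] = ()
    planted_high_utility: tuple[PlantedHighUtility, ...] = ()

    def validate(self) -> None:
        if self.n_episodes < 0:
            raise ValidationError("n_episodes must be >= 0")
        if len(self.age_group_weights) != len(AGE_GROUPS):
            raise ValidationError("need one age-group weight per group")
        if abs(sum(self.age_group_weights) - 1.0) > 1e-6:
            raise ValidationError("age_group_weights must sum to 1")
        pmf = self.effective_stay_pmf()
        if len(pmf) != 30 or abs(sum(pmf) - 1.0) > 1e-6 or min(pmf) < 0:
            raise ValidationError("stay_pmf must be a distribution over 1..30 days")
        max_stay = max(d + 1 for d, p in enumerate(pmf) if p > 0)
        for p in self.planted_itemsets + self.planted_high_utility:
            if not (0.0 <= p.prevalence <= 1.0):
                raise ValidationError("planted prevalence must be in [0, 1]")
        for s in self.planted_sequences:
            if not (0.0 <= s.prevalence <= 1.0):
                raise ValidationError("planted prevalence must be in [0, 1]")
            if len(s.elements) != 2:
                raise ValidationError("planted sequences must have exactly 2 elements")
            if len(s.elements) > max_stay:
                raise ValidationError("planted sequence longer than the longest stay")
        groups = set(AGE_GROUPS)
        for p in self.planted_itemsets + self.planted_sequences + self.planted_high_utility:
            if p.age_groups is not None and not set(p.age_groups) <= groups:
                raise ValidationError(f"unknown age group in planted pattern {p!r}")
        if not (0.0 <= self.diluent_attach_prob <= 1.0):
            raise ValidationError("diluent_attach_prob must be in [0, 1]")
        if abs(sum(w for _, w in self.route_weights) - 1.0) > 1e-6:
            raise ValidationError("route_weights must sum to 1")

    def effective_stay_pmf(self) -> tuple[float, ...]:
        return self.stay_pmf if self.stay_pmf else _default_stay_pmf()

    def planted_medications(self) -> list[tuple[str, str, float]]:
        """(name, drug_class, utility_value) for every planted medication."""
        meds: dict[str, tuple[str, float]] = {}
        for p in self.planted_itemsets:
            for m in p.items:
                meds.setdefault(m, (p.drug_class, float(np.mean(self.utility_value_range))))
        for s in self.planted_sequences:
            for el in s.elements:
                for m in el:
                    meds.setdefault(m, (s.drug_class, float(np.mean(self.utility_value_range))))
        for h in self.planted_high_utility:
            for m in h.items:
                meds[m] = (h.drug_class, h.utility_value)
        return [(m, c, u) for m, (c, u) in sorted(meds.items())]


def _default_stay_pmf() -> tuple[float, ...]:
    """Stay-length distribution over 1..30 days with ~60.1% mass on 9-15."""
    short = np.array([0.5, 1.0, 1.8, 3.0, 4.5, 6.0, 7.0, 7.5])  # days 1-8
    core = np.array([1.0, 2.0, 3.0, 3.5, 3.0, 2.0, 1.0])  # days 9-15
    tail = 0.78 ** np.arange(15)  # days 16-30
    pmf = np.concatenate(
        [
            0.282 * short / short.sum(),
            0.601 * core / core.sum(),
            0.117 * tail / tail.sum(),
        ]
    )
    return tuple(pmf / pmf.sum())


def zipf_exponent_for_coverage(
    n_items: int, top: int, target: float, lo: float = 0.2, hi: float = 4.0
) -> float:
    """Solve (by bisection) for the Zipf exponent at which the ``top`` most
    frequent of ``n_items`` items carry ``target`` of the probability mass."""
    ranks = np.arange(1, n_items + 1, dtype=float)

    def coverage(a: float) -> float:
        w = ranks**-a
        return float(w[:top].sum() / w.sum())

    if not (coverage(lo) <= target <= coverage(hi)):
        raise ValidationError(f"coverage target {target} unreachable for n={n_items}, top={top}")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if coverage(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def default_realistic_config(n_episodes: int = 2000, seed: int = 0) -> GeneratorConfig:
    """A configuration whose marginals target the study-like structure:
    age proportions, the 9-15-day stay mass, IV dominance with attached
    diluents, a long-tailed catalog, and planted patterns of all three kinds
    (an inhaled-therapy triple, two antibiotic sequences with mean gaps of 7
    and 5 days in specific age strata, and a rare high-dose combination)."""
    return GeneratorConfig(
        n_episodes=n_episodes,
        seed=seed,
        planted_itemsets=(
            PlantedItemset(
                items=("ALBUTEROL", "BUDESONIDE", "IPRATROPIUM BROMIDE"),
                prevalence=0.30,
                age_groups=None,
                route="INH",
                drug_class="inhaled therapy",
            ),
        ),
        planted_sequences=(
            PlantedSequence(
                elements=(("CEFOTAXIME",), ("CEFIXIME",)),
                prevalence=0.30,
                gap_mean_days=7.0,
                age_groups=("0-3m",),
                route="IV",
                drug_class="third-generation cephalosporin",
            ),
            PlantedSequence(
                elements=(("CEFTRIAXONE",), ("AZITHROMYCIN",)),
                prevalence=0.30,
                gap_mean_days=5.0,
                age_groups=(">5y",),
                route="IV",
                drug_class="antibiotic",
            ),
        ),
        planted_high_utility=(
            PlantedHighUtility(
                items=("ALBUMIN", "IVIG"),
                prevalence=0.05,
                dose_multiplier=25.0,
                utility_value=300.0,
                age_groups=None,
                route="IV",
                drug_class="plasma product",
            ),
        ),
    )


def build_catalog(config: GeneratorConfig, rng: np.random.Generator) -> MedicationCatalog:
    """The medication catalog implied by a generator config: background
    items with seeded utility values, planted items with their configured
    values, diluents with synonyms, and the raw-to-merged route map."""
    entries: dict[str, CatalogEntry] = {}
    lo, hi = config.utility_value_range
    for i in range(config.catalog_size):
        entries[f"MED_{i + 1:03d}"] = CatalogEntry(
            utility_value=float(rng.integers(lo, hi + 1)),
            drug_class="background",
        )
    for name, drug_class, utility in config.planted_medications():
        entries[name] = CatalogEntry(utility_value=utility, drug_class=drug_class)
    for name, synonyms in _DILUENTS.items():
        entries[name] = CatalogEntry(
            utility_value=0.0, is_diluent=True, drug_class="diluent", synonyms=synonyms
        )
    route_merge = {
        raw: merged for merged, raws in ROUTE_VARIANTS.items() for raw in raws
    }
    return MedicationCatalog(entries=entries, route_merge=route_merge)


@dataclass(frozen=True)
class SyntheticDataset:
    records: tuple[AdminRecord, ...]
    catalog: MedicationCatalog
    truth: dict


def _draw_gap(rng: np.random.Generator, mean: float, stay: int) -> int:
    """A day gap with the configured mean (>=1), truncated to the stay."""
    gap = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
    return min(gap, stay - 1)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate records plus a machine-readable ledger of planted ground
    truth.  Fully deterministic given ``config.seed``."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    cat_rng = np.random.default_rng(seeds[0])
    rng = np.random.default_rng(seeds[1])
    catalog = build_catalog(config, cat_rng)

    bg_names = [f"MED_{i + 1:03d}" for i in range(config.catalog_size)]
    exponent = config.zipf_exponent
    if exponent is None:
        exponent = zipf_exponent_for_coverage(
            config.catalog_size, 40, config.top40_coverage_target
        )
    weights = np.arange(1, config.catalog_size + 1, dtype=float) ** -exponent
    bg_cum = np.cumsum(weights / weights.sum())

    stay_pmf = np.asarray(config.effective_stay_pmf())
    age_w = np.asarray(config.age_group_weights)
    route_names = [r for r, _ in config.route_weights]
    route_cum = np.cumsum([w for _, w in config.route_weights])
    window_start, window_end = config.admission_window
    window_days = (window_end - window_start).days
    dose_lo, dose_hi = config.dose_range
    diluent_names = sorted(_DILUENTS)

    records: list[AdminRecord] = []
    route_counts: dict[str, int] = {}
    stay_counts: dict[int, int] = {}
    group_counts: dict[str, int] = {g: 0 for g in AGE_GROUPS}
    sex_counts = {"male": 0, "female": 0}
    n_diluent_records = 0

    planted_ledger: list[dict] = []
    for p in config.planted_itemsets:
        planted_ledger.append(
            {
                "kind": "cooccurrence",
                "items": sorted(p.items),
                "age_groups": sorted(p.age_groups) if p.age_groups else None,
                "configured_prevalence": p.prevalence,
                "eligible": 0,
                "count": 0,
                "count_by_group": {g: 0 for g in AGE_GROUPS},
            }
        )
    for s in config.planted_sequences:
        planted_ledger.append(
            {
                "kind": "sequence",
                "elements": [sorted(el) for el in s.elements],
                "age_groups": sorted(s.age_groups) if s.age_groups else None,
                "configured_prevalence": s.prevalence,
                "configured_gap_mean_days": s.gap_mean_days,
                "eligible": 0,
                "count": 0,
                "collapsed": 0,
                "count_by_group": {g: 0 for g in AGE_GROUPS},
                "gaps": [],
            }
        )
    for h in config.planted_high_utility:
        planted_ledger.append(
            {
                "kind": "high_utility",
                "items": sorted(h.items),
                "age_groups": sorted(h.age_groups) if h.age_groups else None,
                "configured_prevalence": h.prevalence,
                "eligible": 0,
                "count": 0,
                "count_by_group": {g: 0 for g in AGE_GROUPS},
                "occurrence_utility": 0.0,
            }
        )

    def draw_route() -> str:
        return route_names[int(np.searchsorted(route_cum, rng.random(), side="right"))]

    def raw_route(merged: str) -> str:
        variants = ROUTE_VARIANTS[merged]
        return variants[int(rng.integers(0, len(variants)))]

    def draw_dose() -> float:
        return float(rng.integers(dose_lo, dose_hi + 1))

    for ep in range(config.n_episodes):
        episode_id = f"EP{ep + 1:06d}"
        g_idx = int(np.searchsorted(np.cumsum(age_w), rng.random(), side="right"))
        g_idx = min(g_idx, len(AGE_GROUPS) - 1)
        group = AGE_GROUPS[g_idx]
        group_counts[group] += 1
        sex = "male" if rng.random() < config.male_share else "female"
        sex_counts[sex] += 1
        stay = 1 + int(np.searchsorted(np.cumsum(stay_pmf), rng.random(), side="right"))
        stay = min(stay, 30)
        stay_counts[stay] = stay_counts.get(stay, 0) + 1
        admission = window_start + timedelta(days=int(rng.integers(0, max(window_days - stay, 1))))
        discharge = admission + timedelta(days=stay - 1)
        lo_d, hi_d = _GROUP_DAY_RANGES[g_idx]
        birth = admission - timedelta(days=int(rng.integers(lo_d, hi_d + 1)))

        ep_records: list[AdminRecord] = []

        def add(med: str, day: int, merged_route: str, dose: float, unit: str = "u") -> None:
            ep_records.append(
                AdminRecord(
                    episode_id=episode_id,
                    patient_sex=sex,
                    birth_date=birth,
                    admission_date=admission,
                    discharge_date=discharge,
                    medication=med,
                    route=raw_route(merged_route),
                    dose_qty=dose,
                    dose_unit=unit,
                    admin_date=admission + timedelta(days=day),
                )
            )
            route_counts[merged_route] = route_counts.get(merged_route, 0) + 1

        for day in range(stay):
            k = int(rng.poisson(config.background_meds_per_day))
            if day == stay - 1 and not ep_records and k == 0:
                k = 1  # every episode appears in the administration extract
            if k:
                draws = np.searchsorted(bg_cum, rng.random(k), side="right")
                for d in draws:
                    add(bg_names[int(d)], day, draw_route(), draw_dose())

        ledger_idx = 0
        for p in config.planted_itemsets:
            entry = planted_ledger[ledger_idx]
            ledger_idx += 1
            if p.age_groups is not None and group not in p.age_groups:
                continue
            entry["eligible"] += 1
            if rng.random() >= p.prevalence:
                continue
            entry["count"] += 1
            entry["count_by_group"][group] += 1
            day = int(rng.integers(0, stay))
            for m in sorted(p.items):
                add(m, day, p.route, draw_dose())
        for s in config.planted_sequences:
            entry = planted_ledger[ledger_idx]
            ledger_idx += 1
            if s.age_groups is not None and group not in s.age_groups:
                continue
            entry["eligible"] += 1
            if rng.random() >= s.prevalence:
                continue
            gap = _draw_gap(rng, s.gap_mean_days, stay)
            if gap < 1:
                # single-day stay: both elements collapse onto one day and no
                # longer form a two-element sequence; tracked separately
                entry["collapsed"] += 1
                day1 = day2 = 0
            else:
                entry["count"] += 1
                entry["count_by_group"][group] += 1
                entry["gaps"].append(gap)
                day1 = int(rng.integers(0, stay - gap))
                day2 = day1 + gap
            for m in sorted(s.elements[0]):
                add(m, day1, s.route, draw_dose())
            for m in sorted(s.elements[1]):
                add(m, day2, s.route, draw_dose())
        for h in config.planted_high_utility:
            entry = planted_ledger[ledger_idx]
            ledger_idx += 1
            if h.age_groups is not None and group not in h.age_groups:
                continue
            entry["eligible"] += 1
            if rng.random() >= h.prevalence:
                continue
            entry["count"] += 1
            entry["count_by_group"][group] += 1
            day = int(rng.integers(0, stay))
            occ_utility = 0.0
            for m in sorted(h.items):
                dose = draw_dose() * h.dose_multiplier
                occ_utility += dose * h.utility_value
                add(m, day, h.route, dose)
            entry["occurrence_utility"] += occ_utility

        # diluents ride along with IV administrations
        for r in list(ep_records):
            if catalog.merge_route(r.route) != "IV":
                continue
            if rng.random() < config.diluent_attach_prob:
                name = diluent_names[int(rng.integers(0, len(diluent_names)))]
                emitted = name
                if rng.random() < config.synonym_emit_prob:
                    syns = catalog.entries[name].synonyms
                    emitted = syns[int(rng.integers(0, len(syns)))]
                ep_records.append(
                    AdminRecord(
                        episode_id=episode_id,
                        patient_sex=sex,
                        birth_date=birth,
                        admission_date=admission,
                        discharge_date=discharge,
                        medication=emitted,
                        route=raw_route("IV"),
                        dose_qty=100.0,
                        dose_unit="mL",
                        admin_date=r.admin_date,
                    )
                )
                route_counts["IV"] = route_counts.get("IV", 0) + 1
                n_diluent_records += 1

        records.extend(ep_records)

    for entry in planted_ledger:
        eligible = entry["eligible"]
        entry["realized_prevalence"] = entry["count"] / eligible if eligible else None
        if "gaps" in entry:
            entry["mean_gap_days"] = (
                float(np.mean(entry["gaps"])) if entry["gaps"] else None
            )

    truth = {
        "seed": config.seed,
        "n_episodes": config.n_episodes,
        "n_records": len(records),
        "n_diluent_records": n_diluent_records,
        "age_group_counts": group_counts,
        "sex_counts": sex_counts,
        "stay_counts": {str(k): v for k, v in sorted(stay_counts.items())},
        "route_record_counts": dict(sorted(route_counts.items())),
        "zipf_exponent": exponent,
        "planted": planted_ledger,
    }
    return SyntheticDataset(records=tuple(records), catalog=catalog, truth=truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write records.csv, catalog.json and truth.json under ``outdir``."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_admin_records(outdir / "records.csv", dataset.records)
    dataset.catalog.to_json(outdir / "catalog.json")
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
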