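# Methods

## Problem and data model

`medmine` analyzes deidentified inpatient medication-administration extracts:
one row per administration event (episode, medication, route, dose, day).
The unit of analysis is the *hospitalization episode* — a rehospitalized
patient contributes one unit per stay — and time is modeled at calendar-day
granularity; intra-day ordering is not represented because administration
timestamps in such extracts are rarely reliable below the day.

Episodes are stratified into six pediatric age groups by age at admission
(admission date minus birth date, in calendar months), with half-open
boundaries [0,3m), [3m,6m), [6m,12m), [1y,2y), [2y,5y), [5y,18y).  The
half-open convention makes the six groups a true partition of [0, 18y) and
is testable; whether a child admitted exactly at 3 months belongs to the
lower or upper group is otherwise arbitrary.

Cleaning merges raw route labels into route classes (IV, oral, inhalation,
topical) via a configurable map, resolves medication synonyms to canonical
names, and removes diluents/carriers (e.g. 5% dextrose in water, normal
saline): these are the most frequently administered "medications" in
IV-heavy pediatric data but have no therapeutic intent.  Cleaning reports a
removal count so record totals always reconcile:
`input = output + diluents removed (+ malformed rows caught at parse time)`.

## The three database forms and miners

From cleaned records three databases are built, one entry per episode:

1. **Transaction database** — the set of distinct medications in the episode.
   Mined by **FP-Growth** for frequent itemsets: a prefix tree ordered by
   descending global frequency (ties lexicographic) is mined recursively via
   conditional pattern bases.  `min_support` is relative; the absolute
   threshold is `ceil(min_support × |DB|)` so it is meaningful across age
   groups of very different size.
2. **Sequence database** — the day-ordered list of same-day medication sets.
   Mined by **PrefixSpan** for sequential patterns via prefix projection
   (I-extension adds an item to the last element, S-extension starts a later
   element).  The projection is represented per sequence as the set of
   element indices where the pattern's last element can end; this is
   sufficient state for both counting and extension, because feasibility of
   any extension depends only on the ending index.
3. **Utility sequence database** — same shape, each (medication, day) item
   carrying `u = P(i) × q`, where `P(i)` is the medication's configured
   utility value per dose unit and `q` the summed same-day dose.  Repeated
   same-day doses are aggregated into one item (the sequence examples the
   design follows carry one item per day).  What `P(i)` should encode
   (price, potency, expert weight) is a modeling choice of the user; it is
   pure configuration here and defaults to 1, degrading utility to dose
   mass.  Mined by **USpan** for high-utility sequential patterns.

USpan's scoring follows the published definition: a pattern's utility in one
sequence is the *maximum* occurrence utility over all embeddings, and its
database utility is the sum of those maxima over supporting sequences.
Utility is not anti-monotone, so completeness rests on two safe upper
bounds: sequence-weighted utility (SWU) for width pruning at the root, and a
remaining-utility bound (best current occurrence utility plus all utility at
or after its ending element) for depth pruning.  Candidate extensions
accumulate their bound during candidate collection, so hopeless branches
are discarded before the projection is built.  Both prunings only
over-estimate, and the test suite certifies on hundreds of random databases
that the miner's output equals an unpruned brute-force enumerator's.

Numerical notes: support thresholds use `ceil(ms·n − 1e-9)` to avoid float
spillover at exact multiples (e.g. `0.15 × 20`); utility comparisons carry a
1e-9 slack; all outputs are deterministically ordered (score descending,
then support count, then the canonical rendering with elements' items
sorted lexicographically).  Empty databases return empty results with a
warning rather than raising.

## Reporting

The report layer ranks each (algorithm × age group) cell's results
(score descending, ties by support count then rendering), keeps the top
k = 10, and aligns cells into a union table of distinct medication
combinations.  Combination identity is the flattened item set: an unordered
itemset and a sequential pattern over the same medications are the same
combination, which is how cross-algorithm rows of this kind of comparison
table are conventionally aligned.  Each row keeps per-algorithm canonical
renderings and age-group presence flags; an algorithm that found nothing for
a combination renders as absent.  With 3 algorithms, 6 groups and k = 10 the
distinct-combination count is bounded by 180.

Mean day gaps for two-element sequential patterns are computed post hoc
(mining is unconstrained by time windows): per supporting sequence, the gap
between the earliest embedding of the first element and the earliest later
embedding of the second, averaged over supporting sequences.

Fleiss kappa for expert-panel ratings is computed with the standard
definition, κ = (P̄ − P̄ₑ)/(1 − P̄ₑ), via `statsmodels`; the wrapper
validates the table (constant rater count, ≥2 subjects/categories) and
raises on the degenerate all-one-category case where κ is undefined.  The
panel review itself is out of scope — ratings arrive as a subject × category
count table.

## The synthetic generator

Real administration extracts of this kind are not distributable, so the
generator emulates their statistical structure with planted, ledgered ground
truth.  Defaults (the study conditions, fixed up front):

| parameter | default | rationale |
|---|---|---|
| age-group weights | .3753/.0799/.1015/.1087/.2000/.1345 | pediatric-pneumonia inpatient age mix (0-3m dominant, 86.5% under 5) |
| male share | .6037 | same source mix |
| stay pmf | support 1–30 d, mass .601 on 9–15 d | typical stay distribution |
| background catalog | 650 items, Zipf-weighted | long-tailed formulary; exponent solved so top 40 items carry .7366 of draws |
| background rate | Poisson(1.8) meds/day | ≈22 administration records per episode before diluents |
| route weights (background records) | IV .34, PO .415, INH .10, TOP .145 | with diluents attached to IV records at p=.5 and planted IV/INH patterns, the overall record-level IV share lands near .43 and inhalation near .115 |
| dose, utility value | doses 1–4 units; P(i) ∈ 1–10 | unit-scale background utilities |
| planted co-occurrence | inhaled triple (albuterol, budesonide, ipratropium bromide), prevalence .30, all groups, INH route | a same-day nebulized combination |
| planted sequences | cefotaxime→cefixime, gap mean 7 d, 0-3m only; ceftriaxone→azithromycin, gap mean 5 d, >5y only, prevalence .30 each | antibiotic switch patterns with day-scale gaps in specific strata |
| planted high-utility | (albumin, IVIG), prevalence .05, dose ×25, P=300, IV | low-frequency/high-dose pattern invisible to support-based miners |

Background draws are independent per day given stay length — the simplest
null under which planted structure is identifiable — and background item
names are disjoint from planted names, so a planted pattern's mined support
count equals the ledger's realized count *exactly*.  Planted gaps are drawn
as 1 + Poisson(mean − 1) truncated to stay − 1; truncation pulls realized
mean gaps slightly (≈0.5 d) below the configured means under the default
stay distribution, and the ledger records the realized values.  A sequence
planted into a single-day stay collapses onto one day and is ledgered
separately as "collapsed", not as sequence support.  Episodes that would
otherwise produce no records receive one background record, since an episode
without administrations would not appear in an administration extract.
Diluents (D5W/NS, sometimes emitted under synonyms) attach to IV records
with probability .5 and are removed again by cleaning, exercising that path.

Age is sampled in day ranges kept a few days clear of calendar-month
boundaries, so the sampled group always equals the group later assigned from
the dates.  All sampling flows from one `numpy` SeedSequence; identical
seeds give byte-identical CSV/JSON outputs.

What the generator does **not** emulate: diagnosis-dependent co-prescription
structure, dose-unit heterogeneity, seasonal/calendar drift, correlated
background medications, clinical response or outcomes.  Passing recovery
tests therefore show that the miners and the pipeline are correct and
complete under controlled conditions — not that any specific clinical
pattern generalizes to real data.

## Problem sizes and thresholds in the shipped runs

The acceptance run (`scripts/acceptance.py`) generates 2,000 episodes
(≈50,000 records), cleans them, mines each age group with the pipeline
thresholds — minimum support 0.15 (FP-Growth, PrefixSpan), minimum utility
30,000 (USpan) — and builds the top-10 comparison.  PrefixSpan and USpan run
with `max_length = 3` total items there: planted patterns have at most
three items, and the combination report is about small combinations;
unbounded-depth behavior is exercised separately by the oracle suites on
small databases, where results are checked exactly against brute force.
The miners accept any `max_length` (library default 8).

## Known limitations

- USpan's `max_length` bounds total items, not elements; extremely dense
  utility sequences with near-uniform utilities defeat the bounds' pruning
  power and revert to near-exhaustive search (inherent to utility mining).
- The combination-identity rule (flattened item set) merges sequential
  patterns that differ only in ordering/element split into one report row;
  the per-algorithm renderings preserve the distinction inside the row.
- `mean_time_gap` is defined for two-element patterns only, per the
  "A followed by B" reading; longer chains need repeated calls.
- Utility values `P(i)` are configuration; no pharmacological normalization
  (e.g. defined daily doses) is attempted.
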