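# Methods

## Problem and approach

Administrative Medicaid-style claims record a delivery in the mother's
claims and (often) the newborn's care in the infant's own claims, but no
shared family identifier connects them. `dyadlink` links the two sides
deterministically, using only variables available in claims and enrollment
files: state, dates, residential ZIP, facility ZIP (via the provider NPI
registry), race/ethnicity, and the household case ID where states assign
one. No names, addresses, or vital-records linkage are used, and no
probabilistic (Fellegi–Sunter) scoring is involved: every link is the
unique survivor of an explicit criterion, which makes the output auditable
and lets users discard matches from the weaker phases.

## Delivery identification

Delivery-coded claims (user-supplied ICD-9/ICD-10/CPT lists; the package
ships a small illustrative default) are kept when the beneficiary was aged
12–50 — in completed years at the service date, birthday-based — and
grouped per beneficiary into distinct deliveries.

**Clustering.** Each claim day starts as a singleton cluster. The pair of
clusters with the smallest midpoint distance merges while that distance is
strictly below 270 days, midpoints being recomputed after every merge; a
cluster midpoint is the day halfway between its earliest and latest claim,
rounded down. Ties on distance break toward the pair with the earliest
midpoint, so the result is independent of input row order. Emitted
clusters therefore always satisfy pairwise midpoint gaps ≥ 270 days — no
beneficiary is credited with two live births within nine months. The
merge criterion is the iterative midpoint rule rather than single- or
complete-linkage agglomeration: the midpoint-gap constraint is the
property the output must satisfy, and merging on current midpoints is the
direct way to enforce it. An exhaustive partition oracle in the tests
confirms both that the implementation matches an independent naive greedy
merger and that its output is always a constraint-satisfying partition.

**Window.** A delivery's window runs from its earliest to latest claim
date. Windows wider than 7 days (measured as end − start; an
inclusive-day-count mode exists behind `window_span_inclusive_count`) are
excluded as unlocalisable; deliveries with multiple-gestation codes are
excluded after clustering, at event level. When both apply, the
wide-window reason is recorded, mirroring the order of the exclusion flow.

## Newborn identification

A beneficiary's birth date is taken from enrollment records and accepted
only when all non-missing values agree across records ("confident" DOB);
conflicts exclude the candidate explicitly. The code route keeps
beneficiaries with a newborn-care-coded claim in [DOB, DOB + 7 days].
Because several states bill newborn care under the mother — making the
infant invisible to the code route — each state-year's code-based count is
compared with the NVSS count of Medicaid-payer births: when the ratio is
strictly below 0.95 (or the NVSS denominator is zero or absent), the
enrollment fallback admits every beneficiary enrolled on or before
DOB + 1 day whose birth year is that state-year. The age-0 restriction
keeps older enrollees out. A beneficiary found by both routes counts as
code-based. Coverage is computed before the singleton exclusion, since
multiple gestations cannot be separated in NVSS counts.

## Matching variables

Residential ZIP, race/ethnicity and case ID come from the enrollment
record of the event year (delivery-midpoint year or birth year), falling
back to the nearest available year with earlier years preferred on ties —
the year alignment is a package choice, as enrollment snapshots drift.
Facility ZIP is resolved per event from the NPIs on its claims (the
delivery's clustered claims; the newborn's claims within the 7-day
lookahead), each looked up for the claim's filing year; the modal resolved
ZIP wins, ties broken by earliest claim date then lexicographically.

Cleaning: case IDs held by more than 10 distinct beneficiaries in a
state-year cannot be household identifiers and are cleared, as are
sentinel values (empty, all-zero, configurable); multiracial identity is
cleared for matching only (mother-infant congruence on it is poor) while
remaining available to the reporting tables. Cleaning is idempotent.

## Matching

Six phases, eight steps each. Hard criteria in every cell: same state,
and newborn DOB within [window_start − t, window_end + t] with t = 0/1/2
days in phases 1–3 and again 4–6; phases 1–3 additionally require a case
ID present on both sides and equal, phases 4–6 impose no case-ID condition
(missing and conflicting both pass). Steps require agreement on all
three of {residential ZIP, facility ZIP, race/ethnicity}, each two-subset,
each singleton, then none, in that enumeration order (configurable — the
order among equal-cardinality subsets is a convention).

A required variable agrees only when present on both sides and equal;
missing values never wildcard. This is deliberate: the step ladder already
handles missing data by dropping requirements, so letting missingness
satisfy a requirement would only manufacture ambiguous candidates.

Acceptance is simultaneous mutual-degree-one: within a step, a pair links
iff neither side participates in any other candidate pair. One pass is
made per step (a fixed-point mode that re-checks uniqueness after removals
is available via `iterate_within_step`; it is off by default to keep the
single-sweep semantics). Simultaneity makes the algorithm invariant to
input row order, which the tests verify byte-for-byte.

A brute-force oracle re-implements the whole procedure by exhaustive
pairwise predicate evaluation with no merging or indexing; engine and
oracle must agree exactly, link set and phase/step attribution included.

## Synthetic study conditions

The generator produces claims, enrollment, an NPI→ZIP table, NVSS counts
and a ground-truth dyad table. Defaults define three archetypal states of
400 mothers each: `ZA` (household case IDs, 5% newborn billing under the
mother, 98% code coverage), `ZB` (case IDs, 80% under-mother billing — the
enrollment-fallback regime), `ZC` (no case IDs — links can only appear
from phase 4). Other defaults: 15% of mothers have a second delivery,
inter-birth gaps uniform in 300–500 days (≥ 280 by construction, above the
270-day threshold so truth deliveries are separable); twin rate 1.3%,
near the share of multiple-gestation deliveries such claims data exhibit;
claim-date jitter uniform on {0,1,2} days after the true delivery date
(so some true dyads are only recoverable in the tolerance phases);
per-variable missingness 5–15%; infant race agrees with the mother's 70%
of the time, else Unknown/Other, emulating weak race capture in newborn
enrollment; 10% extra newborns whose mothers did not use Medicaid for the
delivery (they must go unmatched, and get unique non-household case IDs so
household case IDs remain a sound signal); NVSS payer misreporting 8%,
which makes identified deliveries exceed the benchmark by roughly that
relative amount. The last two reproduce, mechanically, the two documented
drivers of positive delivery and newborn over-coverage versus NVSS.

All draws come from one seeded `numpy` generator in a fixed order, so
outputs are byte-reproducible. IDs are sequential state-prefixed strings;
nothing resembling PII is generated.

**What the synthetic conditions do not show.** Realism is structural, not
demographic: no attempt is made to match real MAX/TAF marginals, claim
volumes, enrollment churn, cross-state moves, or data-entry error beyond
the modelled missingness. Passing tests demonstrate the algorithm's
correctness properties (exact recovery under perfect information, exact
case-ID-phase precision, oracle equivalence, boundary behaviour), not the
match rates to expect on real claims.

## Scoring

Precision = correct links / links. Recall divides by *eligible* truth
dyads: singleton, with a Medicaid delivery, and identifiable under the
run's conditions (infant billed under its own ID, or born in a state-year
where the fallback activated). Infants invisible to both routes cannot be
recovered by any linkage and are excluded from the denominator.

## Problem sizes and numerical choices

The acceptance checks use 20 random pools of 120×130 records for
engine/oracle equivalence (well under the 500×500 the exhaustive oracle
can handle), a 10,000-birth perfect-information run, and the default
three-state conditions for end-to-end scoring; each completes in seconds
to tens of seconds on one CPU. Dates are calendar dates with arithmetic
in whole days; ZIPs are validated as five digits (nine-digit forms
truncated) with an optional user-supplied valid-ZIP list as the hook for
stricter validation; ages are completed years at service; all tie-breaks
(cluster merges, facility-ZIP modes, step order) are fixed and documented
above so identical inputs always produce identical output.

## Known limitations

* The clustering merge criterion is one faithful reading of the stated
  midpoint-gap constraint; other agglomerative criteria could partition
  pathological claim sequences differently.
* The delivery window uses all claims in a cluster, without privileging
  inpatient claims.
* "Confident DOB" is operationalised as cross-record agreement; a single
  erroneous enrollment year discards an otherwise good candidate.
* Facility ZIP inherits NPPES-style registry quality: group practices
  registered at administrative addresses blur the facility signal.
* In states without case IDs, phases 4–6 rest on ZIP/race/date uniqueness
  alone; in dense state-years the uniqueness requirement suppresses most
  candidates, and the residual links carry the highest error rate — users
  can drop late-phase links via the recorded phase/step annotations.
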