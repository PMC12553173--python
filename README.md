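# dyadlink

Deterministic mother–infant dyad linkage for Medicaid-style administrative
claims.

Research on maternal and child health often needs to connect a delivery in a
mother's insurance claims to the newborn's own beneficiary record — but
Medicaid claims carry no names, addresses, or shared family identifiers, and
billing conventions vary sharply across states (some bill newborn care under
the mother's coverage; some never assign household case IDs). `dyadlink`
implements a complete, reusable pipeline for this problem:

1. **Delivery identification** — select claims bearing live-birth delivery
   codes (ICD-9/ICD-10/CPT) for beneficiaries aged 12–50, then cluster each
   beneficiary's delivery claims into distinct deliveries by agglomerative
   midpoint merging, requiring cluster midpoints at least 270 days apart.
   Deliveries whose claim dates span more than 7 days, or that carry
   multiple-gestation codes, are excluded from matching.
2. **Newborn identification** — beneficiaries with newborn-care-coded
   claims billed within 7 days of their (enrollment-derived) date of birth;
   in state-years where that code-based count falls below 95% of the
   NVSS count of Medicaid-payer births, an *enrollment fallback* admits all
   beneficiaries enrolled before or up to one day after their birth date.
3. **Matching** — a greedy deterministic algorithm over six phases of
   progressively weaker criteria. Every phase requires the same state and a
   birth date inside the delivery window (± 0/1/2-day tolerance); phases
   1–3 also require a shared household case ID, phases 4–6 do not. Within
   each phase, eight steps relax agreement on residential ZIP, facility ZIP
   (via an NPI→ZIP lookup) and race/ethnicity: all three, any two, any one,
   none. A pair is linked only when it is *unique* — mutual degree one
   among the current candidates — and linked records leave the pool.

Because real Medicaid data are restricted, the package ships a first-class
synthetic claims generator (`dyadlink.synth`) that emulates the structural
heterogeneity above with ground-truth dyads, so the full pipeline is
testable and benchmarkable end to end.

## Worked example

```python
from dyadlink import SynthConfig, generate, run_pipeline, score_against_truth
from dyadlink.pipeline import fallback_state_years

data = generate(SynthConfig(seed=1))          # 3 states, 400 mothers each
result = run_pipeline(data.claims, data.enrollment, data.npi_table,
                      data.nvss_counts, data.code_lists)

m = result.manifest
print(m["unique_deliveries"])                 # 1379
print(m["newborns_code_based"],
      m["newborns_enrollment_based"])         # 1006 421
print(m["dyads_linked"])                      # 1262
print(round(m["pct_deliveries_linked"], 2),
      round(m["pct_newborns_linked"], 2))     # 92.86 90.34

score = score_against_truth(result.links, data.truth_dyads,
                            fallback_state_years(result.coverage))
print(round(score["precision"], 4),
      round(score["recall"], 4))              # 0.9319 0.9202
```

The run identifies 1,379 distinct deliveries and 1,427 newborn candidates
(1,006 from codes, 421 recovered by the enrollment fallback in the
bill-under-mother state), links 1,262 dyads (92.9% of matchable deliveries,
90.3% of matchable newborns), and — checked against the generator's ground
truth — achieves precision 0.93 and recall 0.92 overall, with the
case-ID-required phases (1–3) exactly correct. `result.links` carries the
phase and step of every dyad, so downstream analyses can keep only the
matches made under the stringency they trust.

The same pipeline runs from the shell:

```sh
dyadlink synth --out data/ --seed 1
dyadlink run --data-dir data/ --out results/
```

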