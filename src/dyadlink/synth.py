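"""Seeded synthetic claims generator with ground-truth mother-infant dyads.

The generator emulates the structural heterogeneity that makes nationwide
mother-infant linkage hard in real Medicaid data, without attempting
demographic realism:

* states that do or do not assign household-level case IDs;
* states where newborn care is billed under the mother's coverage, so the
  newborn never appears in claims and is only recoverable through the
  enrollment fallback;
* incomplete diagnosis/procedure code coverage;
* per-variable missingness in the matching keys;
* newborns enrolled in Medicaid whose mothers did not use Medicaid for the
  delivery (a driver of newborn over-coverage versus NVSS);
* payer misreporting in the NVSS benchmark (a driver of delivery
  over-coverage);
* twin births, which the pipeline must flag and exclude.

All randomness flows from one :class:`numpy.random.Generator` seeded from
the config, with draws made in a fixed order, so output is reproducible.
Inter-birth gaps are at least 280 days, strictly above the 270-day
clustering threshold, so true deliveries are always separable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .claims_io import CodeLists

#: Illustrative default code lists (users substitute their own full lists).
DEFAULT_CODE_LISTS: CodeLists = {
    "delivery": {
        ("O80", "ICD10-DX"),
        ("Z37.0", "ICD10-DX"),
        ("10E0XZZ", "ICD10-PR"),
        ("650", "ICD9-DX"),
        ("72.1", "ICD9-PR"),
        ("59400", "CPT"),
        ("59409", "CPT"),
        ("59510", "CPT"),
    },
    "newborn_care": {
        ("Z38.00", "ICD10-DX"),
        ("Z38.01", "ICD10-DX"),
        ("V30.00", "ICD9-DX"),
        ("99460", "CPT"),
        ("99461", "CPT"),
        ("99462", "CPT"),
    },
    "multiple_gestation": {
        ("Z37.2", "ICD10-DX"),
        ("Z38.30", "ICD10-DX"),
        ("O30.003", "ICD10-DX"),
        ("651.01", "ICD9-DX"),
        ("V31.00", "ICD9-DX"),
    },
}


class StateProfile(BaseModel):
    """Per-state billing conventions the generator emulates."""

    has_case_ids: bool = True
    newborn_billed_under_mother_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    code_coverage: float = Field(default=1.0, ge=0.0, le=1.0)


def default_state_profiles() -> dict[str, StateProfile]:
    """Three archetypes: a case-ID state with near-complete newborn coding,
    a state billing newborns under mothers (fallback territory), and a
    state without household case IDs."""
    return {
        "ZA": StateProfile(has_case_ids=True, newborn_billed_under_mother_prob=0.05, code_coverage=0.98),
        "ZB": StateProfile(has_case_ids=True, newborn_billed_under_mother_prob=0.80, code_coverage=0.95),
        "ZC": StateProfile(has_case_ids=False, newborn_billed_under_mother_prob=0.10, code_coverage=0.97),
    }


RACE_DISTRIBUTION = {
    "White": 0.385,
    "Hispanic": 0.255,
    "Black": 0.210,
    "Unknown/Other": 0.070,
    "Asian": 0.030,
    "Multiracial": 0.030,
    "AIAN": 0.015,
    "Hawaiian/PI": 0.005,
}


class SynthConfig(BaseModel):
    """Study conditions for a synthetic run."""

    states: dict[str, StateProfile] = Field(default_factory=default_state_profiles)
    n_mothers_per_state: int = Field(default=400, ge=1)
    second_delivery_prob: float = Field(default=0.15, ge=0.0, le=1.0)
    min_interbirth_gap: int = Field(default=300, ge=280)
    max_interbirth_gap: int = Field(default=500, ge=280)
    twin_rate: float = Field(default=0.013, ge=0.0, le=1.0)
    #: Per matching variable, probability that a beneficiary's value is missing.
    missingness: dict[str, float] = Field(
        default_factory=lambda: {
            "residential_zip": 0.05,
            "facility_zip": 0.10,
            "race_ethnicity": 0.15,
            "case_id": 0.05,
        }
    )
    #: Race/ethnicity sampling weights (defaults to RACE_DISTRIBUTION);
    #: weights are renormalised to sum to one.
    race_distribution: dict[str, float] | None = None
    #: Probability an infant's recorded race/ethnicity agrees with the
    #: mother's (disagreements are recorded as Unknown/Other, emulating the
    #: weaker race capture in newborn enrollment records).
    infant_race_agreement: float = Field(default=0.70, ge=0.0, le=1.0)
    claim_date_jitter: int = Field(default=2, ge=0)
    claims_per_delivery_max: int = Field(default=3, ge=1)
    newborn_without_medicaid_delivery_rate: float = Field(default=0.10, ge=0.0, le=1.0)
    nvss_payer_misreport_rate: float = Field(default=0.08, ge=0.0, le=0.5)
    start_year: int = 2014
    n_delivery_years: int = Field(default=2, ge=1)
    n_zips_per_state: int = Field(default=20, ge=1)
    n_facilities_per_state: int = Field(default=12, ge=1)
    seed: int = 0

    @field_validator("min_interbirth_gap")
    @classmethod
    def _gap_separable(cls, v):
        # 280 > 270: truth deliveries must stay separable under clustering.
        if v < 280:
            raise ValueError("min_interbirth_gap must be >= 280 days")
        return v

    @field_validator("max_interbirth_gap")
    @classmethod
    def _gap_order(cls, v, info):
        if "min_interbirth_gap" in info.data and v < info.data["min_interbirth_gap"]:
            raise ValueError("max_interbirth_gap must be >= min_interbirth_gap")
        return v

    @field_validator("missingness")
    @classmethod
    def _missing_fractions(cls, v):
        for key, frac in v.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"missingness[{key!r}] must be in [0, 1]")
        return v


def perfect_information_config(
    n_mothers_per_state: int = 5000, n_states: int = 2, seed: int = 0
) -> SynthConfig:
    """The noise-free regime: unique household case IDs everywhere, complete
    code coverage, zero missingness, zero jitter, full race congruence, no
    twins, no extra newborns, exact NVSS.  Every eligible dyad is then
    uniquely determined by its case ID and delivery date alone."""
    states = {
        f"Z{chr(65 + s)}": StateProfile(
            has_case_ids=True, newborn_billed_under_mother_prob=0.0, code_coverage=1.0
        )
        for s in range(n_states)
    }
    return SynthConfig(
        states=states,
        n_mothers_per_state=n_mothers_per_state,
        second_delivery_prob=0.15,
        twin_rate=0.0,
        missingness={k: 0.0 for k in ("residential_zip", "facility_zip", "race_ethnicity", "case_id")},
        infant_race_agreement=1.0,
        claim_date_jitter=0,
        newborn_without_medicaid_delivery_rate=0.0,
        nvss_payer_misreport_rate=0.0,
        # Multiracial is deterministically cleared by the matching-variable
        # cleaning rule, so a noise-free regime must not sample it.
        race_distribution={
            k: v for k, v in RACE_DISTRIBUTION.items() if k != "Multiracial"
        },
        seed=seed,
    )


@dataclass
class SynthData:
    """Everything a pipeline run needs, plus the evaluation ground truth."""

    claims: pd.DataFrame
    enrollment: pd.DataFrame
    npi_table: pd.DataFrame
    nvss_counts: pd.DataFrame
    truth_dyads: pd.DataFrame
    code_lists: CodeLists


TRUTH_COLUMNS = [
    "mother_id",
    "infant_id",
    "state",
    "true_delivery_date",
    "household_case_id",
    "multiple_gestation",
    "has_medicaid_delivery",
    "infant_code_billed",
]


def _choice(rng: np.random.Generator, options: list[str], n: int, probs=None) -> np.ndarray:
    return rng.choice(np.array(options, dtype=object), size=n, p=probs)


def generate(config: SynthConfig) -> SynthData:
    """Generate claims, enrollment, NPI, NVSS and truth tables.

    Deterministic given ``config.seed``: all draws come from a single
    generator in a fixed order (states sorted, mothers in index order).
    """
    rng = np.random.default_rng(config.seed)
    epoch = pd.Timestamp("1970-01-01")

    delivery_codes = sorted(DEFAULT_CODE_LISTS["delivery"])
    newborn_codes = sorted(DEFAULT_CODE_LISTS["newborn_care"])
    twin_code = ("Z37.2", "ICD10-DX")
    twin_newborn_code = ("Z38.30", "ICD10-DX")

    span_start = pd.Timestamp(f"{config.start_year}-01-01")
    span_days = 365 * config.n_delivery_years

    claims_rows: list[dict] = []
    enroll_rows: list[dict] = []
    npi_rows: list[dict] = []
    truth_rows: list[dict] = []
    true_delivery_counts: dict[tuple[str, int], int] = {}

    claim_seq = 0

    def emit_claim(bene, state, date, codes, npi, source):
        nonlocal claim_seq
        claim_seq += 1
        claims_rows.append(
            {
                "claim_id": f"C{claim_seq:08d}",
                "beneficiary_id": bene,
                "state": state,
                "service_date": date,
                "codes": ";".join(f"{s}:{c}" for c, s in codes),
                "provider_npi": npi,
                "source_file": source,
                "claim_year": int(date.year),
            }
        )

    for state in sorted(config.states):
        profile = config.states[state]
        state_idx = sorted(config.states).index(state)
        zips = [f"{600 + state_idx}{z:02d}" for z in range(config.n_zips_per_state)]
        facilities = []
        for f in range(config.n_facilities_per_state):
            npi = f"{1000000000 + state_idx * 1000 + f}"
            fzip = zips[f % len(zips)]
            facilities.append((npi, fzip))

        n_mothers = config.n_mothers_per_state
        mother_zip_idx = rng.integers(0, len(zips), size=n_mothers)
        mother_fac_idx = rng.integers(0, len(facilities), size=n_mothers)
        race_dist = config.race_distribution or RACE_DISTRIBUTION
        race_probs = np.array(list(race_dist.values()), dtype=float)
        race_probs = race_probs / race_probs.sum()
        mother_race = _choice(rng, list(race_dist), n_mothers, probs=race_probs)
        first_delivery_offset = rng.integers(0, span_days, size=n_mothers)
        has_second = rng.random(n_mothers) < config.second_delivery_prob
        second_gap = rng.integers(
            config.min_interbirth_gap, config.max_interbirth_gap + 1, size=n_mothers
        )
        mother_age_at_first = rng.integers(18, 41, size=n_mothers)

        # Per-beneficiary missingness draws for the matching variables.
        miss = {
            var: rng.random(n_mothers) < config.missingness.get(var, 0.0)
            for var in ("residential_zip", "race_ethnicity", "case_id")
        }

        years = range(config.start_year, config.start_year + config.n_delivery_years + 2)
        for y in years:
            for npi, fzip in facilities:
                npi_rows.append({"npi": npi, "year": y, "zip": fzip})

        infant_seq = 0
        for m in range(n_mothers):
            mother_id = f"{state}M{m:06d}"
            case_id = f"{state}H{m:06d}" if profile.has_case_ids else None
            if case_id is not None and miss["case_id"][m]:
                case_id = None
            rzip = None if miss["residential_zip"][m] else zips[mother_zip_idx[m]]
            race = None if miss["race_ethnicity"][m] else mother_race[m]
            fac_npi, fac_zip = facilities[mother_fac_idx[m]]

            first_date = span_start + pd.Timedelta(days=int(first_delivery_offset[m]))
            delivery_dates = [first_date]
            if has_second[m]:
                delivery_dates.append(first_date + pd.Timedelta(days=int(second_gap[m])))
            mother_dob = first_date - pd.Timedelta(days=int(mother_age_at_first[m]) * 365 + 100)

            for y in years:
                enroll_rows.append(
                    {
                        "beneficiary_id": mother_id,
                        "state": state,
                        "year": y,
                        "date_of_birth": mother_dob,
                        "enrollment_start": span_start - pd.Timedelta(days=400),
                        "residential_zip": rzip,
                        "race_ethnicity": race,
                        "case_id": case_id,
                        "sex": "F",
                    }
                )

            for delivery_date in delivery_dates:
                is_twin = bool(rng.random() < config.twin_rate)
                n_claims = int(rng.integers(1, config.claims_per_delivery_max + 1))
                offsets = rng.integers(0, config.claim_date_jitter + 1, size=n_claims)
                code_idx = rng.integers(0, len(delivery_codes), size=n_claims)
                npi_missing = rng.random() < config.missingness.get("facility_zip", 0.0)
                for k in range(n_claims):
                    codes = [delivery_codes[code_idx[k]]]
                    if is_twin:
                        codes.append(twin_code)
                    emit_claim(
                        mother_id,
                        state,
                        delivery_date + pd.Timedelta(days=int(offsets[k])),
                        codes,
                        None if npi_missing else fac_npi,
                        "inpatient",
                    )

                n_infants = 2 if is_twin else 1
                for t in range(n_infants):
                    infant_seq += 1
                    infant_id = f"{state}I{m:06d}x{infant_seq:03d}"
                    _emit_infant(
                        rng,
                        config,
                        profile,
                        emit_claim,
                        enroll_rows,
                        truth_rows,
                        infant_id=infant_id,
                        mother_id=mother_id,
                        state=state,
                        dob=delivery_date,
                        case_id=case_id,
                        rzip=rzip,
                        mother_race=mother_race[m],
                        fac=(fac_npi, fac_zip),
                        newborn_codes=newborn_codes,
                        twin=is_twin,
                        twin_code=twin_newborn_code,
                        has_delivery=True,
                        years=years,
                    )
                key = (state, int(delivery_date.year))
                true_delivery_counts[key] = true_delivery_counts.get(key, 0) + 1

        # Newborns enrolled in Medicaid whose mothers did not use Medicaid
        # for the delivery: enrolled and possibly code-billed, but no
        # delivery claims exist, so they must remain unmatched.
        n_extra = int(round(config.newborn_without_medicaid_delivery_rate * n_mothers))
        extra_offsets = rng.integers(0, span_days, size=n_extra)
        extra_zip_idx = rng.integers(0, len(zips), size=n_extra)
        extra_fac_idx = rng.integers(0, len(facilities), size=n_extra)
        for x in range(n_extra):
            infant_id = f"{state}X{x:06d}"
            dob = span_start + pd.Timedelta(days=int(extra_offsets[x]))
            _emit_infant(
                rng,
                config,
                profile,
                emit_claim,
                enroll_rows,
                truth_rows,
                infant_id=infant_id,
                mother_id=None,
                state=state,
                dob=dob,
                case_id=f"{state}XH{x:06d}" if profile.has_case_ids else None,
                rzip=zips[extra_zip_idx[x]],
                mother_race=str(_choice(rng, list(race_dist), 1, race_probs)[0]),
                fac=facilities[extra_fac_idx[x]],
                newborn_codes=newborn_codes,
                twin=False,
                twin_code=twin_newborn_code,
                has_delivery=False,
                years=years,
            )

    claims = pd.DataFrame(claims_rows)
    enrollment = pd.DataFrame(enroll_rows)
    npi_table = pd.DataFrame(npi_rows)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    nvss_rows = []
    for (state, year), n_true in sorted(true_delivery_counts.items()):
        reported = int(round(n_true * (1.0 - config.nvss_payer_misreport_rate)))
        nvss_rows.append({"state": state, "year": year, "medicaid_births": reported})
    nvss = pd.DataFrame(nvss_rows, columns=["state", "year", "medicaid_births"])

    # Conservation check: every claim's beneficiary exists in enrollment.
    assert set(claims["beneficiary_id"]) <= set(enrollment["beneficiary_id"])
    return SynthData(claims, enrollment, npi_table, nvss, truth, DEFAULT_CODE_LISTS)


def _emit_infant(
    rng,
    config,
    profile,
    emit_claim,
    enroll_rows,
    truth_rows,
    *,
    infant_id,
    mother_id,
    state,
    dob,
    case_id,
    rzip,
    mother_race,
    fac,
    newborn_codes,
    twin,
    twin_code,
    has_delivery,
    years,
):
    """Emit one infant's enrollment rows, newborn claim (under own or
    mother's ID, or uncoded) and truth row.  Shares the run's RNG."""
    fac_npi, fac_zip = fac
    # Infant matching-variable missingness (independent of the mother's).
    i_rzip = None if rng.random() < config.missingness.get("residential_zip", 0.0) else rzip
    i_case = None if rng.random() < config.missingness.get("case_id", 0.0) else case_id
    race_roll = rng.random()
    if rng.random() < config.missingness.get("race_ethnicity", 0.0):
        i_race = None
    elif race_roll < config.infant_race_agreement:
        i_race = mother_race
    else:
        i_race = "Unknown/Other"

    for y in years:
        if y < dob.year:
            continue
        enroll_rows.append(
            {
                "beneficiary_id": infant_id,
                "state": state,
                "year": y,
                "date_of_birth": dob,
                "enrollment_start": dob,
                "residential_zip": i_rzip,
                "race_ethnicity": i_race,
                "case_id": i_case,
                "sex": "F" if rng.random() < 0.49 else "M",
            }
        )

    billed_under_mother = rng.random() < profile.newborn_billed_under_mother_prob
    coded = rng.random() < profile.code_coverage
    code_billed = False
    claim_date = dob + pd.Timedelta(days=int(rng.integers(0, 3)))
    npi_missing = rng.random() < config.missingness.get("facility_zip", 0.0)
    code = newborn_codes[int(rng.integers(0, len(newborn_codes)))]
    codes = [code] + ([twin_code] if twin else [])
    if billed_under_mother:
        if mother_id is not None:
            emit_claim(mother_id, state, claim_date, codes,
                       None if npi_missing else fac_npi, "other_services")
    elif coded:
        code_billed = True
        emit_claim(infant_id, state, claim_date, codes,
                   None if npi_missing else fac_npi, "other_services")
    else:
        # Claim exists but carries no recognizable newborn-care code.
        emit_claim(infant_id, state, claim_date, [("99999", "CPT")],
                   None if npi_missing else fac_npi, "other_services")

    truth_rows.append(
        {
            "mother_id": mother_id,
            "infant_id": infant_id,
            "state": state,
            "true_delivery_date": dob,
            "household_case_id": case_id,
            "multiple_gestation": twin,
            "has_medicaid_delivery": has_delivery,
            "infant_code_billed": code_billed,
        }
    )


def score_against_truth(
    links: pd.DataFrame,
    truth: pd.DataFrame,
    fallback: set[str] | set[tuple[str, int]] | None = None,
) -> dict:
    """Precision/recall of a link set against the generated ground truth.

    Precision = correct links / all links (``None`` when no links).
    Recall = correct links / eligible truth dyads, where a truth dyad is
    eligible when it is a singleton with a Medicaid delivery whose infant
    is identifiable under the run's conditions: billed under its own ID, or
    born in a state(-year) where the enrollment fallback was active.
    ``fallback`` may hold state codes or (state, year) pairs.
    Also returns per-phase correct/incorrect attribution.
    """
    truth_pairs = set(
        zip(truth["mother_id"].astype(str), truth["infant_id"].astype(str))
    )
    fallback = fallback or set()
    if fallback and isinstance(next(iter(fallback)), tuple):
        in_fallback = pd.Series(
            [
                (s, int(d.year)) in fallback
                for s, d in zip(truth["state"], truth["true_delivery_date"])
            ],
            index=truth.index,
        )
    else:
        in_fallback = truth["state"].isin(fallback)
    eligible = truth[
        ~truth["multiple_gestation"]
        & truth["has_medicaid_delivery"]
        & (truth["infant_code_billed"] | in_fallback)
    ]
    n_links = len(links)
    correct_mask = (
        [
            (str(m), str(i)) in truth_pairs
            for m, i in zip(links["mother_id"], links["infant_id"])
        ]
        if n_links
        else []
    )
    n_correct = int(sum(correct_mask))
    per_phase = {}
    if n_links:
        tagged = links.assign(_correct=correct_mask)
        for phase, grp in tagged.groupby("phase"):
            per_phase[int(phase)] = {
                "links": int(len(grp)),
                "correct": int(grp["_correct"].sum()),
            }
    return {
        "n_links": n_links,
        "n_correct": n_correct,
        "n_eligible": int(len(eligible)),
        "precision": (n_correct / n_links) if n_links else None,
        "recall": (n_correct / len(eligible)) if len(eligible) else None,
        "per_phase": per_phase,
    }


def random_match_pools(
    seed: int,
    n_deliveries: int,
    n_newborns: int,
    n_states: int = 2,
    missing_rate: float = 0.25,
    window_days: int = 60,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Small random pools for oracle-equivalence testing.

    Dense date windows, shared key vocabularies, per-field missingness and
    one state without case IDs push links into every phase and manufacture
    plenty of ambiguity, which is what the uniqueness rule must survive.
    """
    rng = np.random.default_rng(seed)
    states = [f"T{chr(65 + s)}" for s in range(n_states)]
    zips = [f"90{z:03d}" for z in range(6)]
    races = ["White", "Hispanic", "Black", "Asian"]
    cases = [f"HH{c:03d}" for c in range(max(4, n_deliveries // 4))]
    base = pd.Timestamp("2015-06-01")

    def maybe(values):
        values = np.asarray(values, dtype=object)
        mask = rng.random(len(values)) < missing_rate
        values[mask] = None
        return values

    d_state = rng.choice(states, size=n_deliveries)
    starts = rng.integers(0, window_days, size=n_deliveries)
    spans = rng.integers(0, 4, size=n_deliveries)
    d_case = maybe(rng.choice(cases, size=n_deliveries))
    d_case[d_state == states[-1]] = None  # one state never assigns case IDs
    deliveries = pd.DataFrame(
        {
            "delivery_id": [f"D{i:04d}" for i in range(n_deliveries)],
            "mother_id": [f"M{i:04d}" for i in range(n_deliveries)],
            "state": d_state,
            "window_start": [base + pd.Timedelta(days=int(s)) for s in starts],
            "window_end": [
                base + pd.Timedelta(days=int(s + w)) for s, w in zip(starts, spans)
            ],
            "residential_zip": maybe(rng.choice(zips, size=n_deliveries)),
            "facility_zip": maybe(rng.choice(zips, size=n_deliveries)),
            "race_ethnicity": maybe(rng.choice(races, size=n_deliveries)),
            "case_id": d_case,
        }
    )
    n_state = rng.choice(states, size=n_newborns)
    dobs = rng.integers(-2, window_days + 5, size=n_newborns)
    n_case = maybe(rng.choice(cases, size=n_newborns))
    n_case[n_state == states[-1]] = None
    newborns = pd.DataFrame(
        {
            "infant_id": [f"N{i:04d}" for i in range(n_newborns)],
            "state": n_state,
            "date_of_birth": [base + pd.Timedelta(days=int(d)) for d in dobs],
            "residential_zip": maybe(rng.choice(zips, size=n_newborns)),
            "facility_zip": maybe(rng.choice(zips, size=n_newborns)),
            "race_ethnicity": maybe(rng.choice(races, size=n_newborns)),
            "case_id": n_case,
        }
    )
    return deliveries, newborns
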