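"""Identification of newborn Medicaid beneficiaries.

Two routes, mirroring how states bill newborn care:

1. *Code-based*: beneficiaries with a newborn-care-coded claim billed from
   their date of birth up to 7 days post-birth.
2. *Enrollment fallback*: in state-years where the code-based count falls
   below 95% of the NVSS count of Medicaid-payer births (some states bill
   newborn care under the mother's coverage, making the newborn invisible
   in claims), every beneficiary enrolled before or up to one day after
   their date of birth is admitted as a candidate.

Birth dates come from enrollment records and are accepted only when all
non-missing values across a beneficiary's records agree; conflicting or
absent dates exclude the candidate.  Multiple-gestation newborns are
flagged (and excluded from matching) from codes on their day 0–7 claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .claims_io import CodeLists, claims_with_any_code
from .config import PipelineConfig

logger = logging.getLogger(__name__)

NEWBORN_COLUMNS = [
    "infant_id",
    "state",
    "date_of_birth",
    "source",
    "multiple_gestation",
    "excluded_reason",
]
COVERAGE_COLUMNS = [
    "state",
    "year",
    "code_based_count",
    "nvss_count",
    "coverage_ratio",
    "fallback_active",
]


def determine_dob(enrollment: pd.DataFrame) -> pd.Series:
    """Confident date of birth per beneficiary.

    Returns the DOB when every non-missing value across the beneficiary's
    enrollment records agrees; NaT when the values conflict or are all
    missing.  Indexed by beneficiary_id.
    """
    grouped = enrollment.groupby("beneficiary_id")["date_of_birth"]
    n_distinct = grouped.nunique(dropna=True)
    first = grouped.first()  # first non-NaN within group
    out = first.where(n_distinct == 1, pd.NaT)
    return out


def select_newborn_claims(
    claims: pd.DataFrame,
    code_lists: CodeLists,
    dob: pd.Series,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Newborn-care-coded claims billed in [dob, dob + lookahead] under the
    beneficiary's own ID.  Returns the qualifying claim rows."""
    mask = claims_with_any_code(claims, code_lists.get("newborn_care", set()))
    coded = claims[mask].copy()
    if coded.empty:
        return coded
    coded["_dob"] = coded["beneficiary_id"].map(dob)
    delta = (coded["service_date"] - coded["_dob"]).dt.days
    keep = coded["_dob"].notna() & (delta >= 0) & (delta <= config.newborn_claim_lookahead)
    return coded[keep].drop(columns="_dob").reset_index(drop=True)


def compute_coverage(
    code_based_counts: pd.DataFrame,
    nvss: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per state-year congruence of code-based newborn counts with NVSS.

    ``code_based_counts``: columns (state, year, code_based_count).  The
    report covers the union of state-years seen in either input; the
    fallback activates when coverage_ratio < threshold (strict), and always
    when the NVSS count is zero or absent (ratio undefined, logged).
    """
    grid = pd.merge(
        code_based_counts,
        nvss.rename(columns={"medicaid_births": "nvss_count"}),
        on=["state", "year"],
        how="outer",
    )
    grid["code_based_count"] = (
        pd.to_numeric(grid["code_based_count"], errors="coerce").fillna(0).astype(int)
    )
    missing_nvss = grid["nvss_count"].isna()
    zero_nvss = missing_nvss | (grid["nvss_count"] == 0)
    for _, row in grid[zero_nvss].iterrows():
        logger.warning(
            "no NVSS denominator for %s %s: fallback forced active", row["state"], row["year"]
        )
    grid["nvss_count"] = grid["nvss_count"].fillna(0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = grid["code_based_count"] / grid["nvss_count"].replace(0, np.nan)
    grid["coverage_ratio"] = ratio
    grid["fallback_active"] = zero_nvss | (
        ratio < config.enrollment_fallback_coverage_threshold
    )
    return grid[COVERAGE_COLUMNS].sort_values(["state", "year"]).reset_index(drop=True)


def enrollment_fallback(
    enrollment: pd.DataFrame,
    dob: pd.Series,
    fallback_state_years: set[tuple[str, int]],
    config: PipelineConfig,
) -> pd.Series:
    """Beneficiary IDs admitted by the enrollment route.

    A beneficiary qualifies when their (state, birth year) is a fallback
    state-year, their earliest enrollment start is on or before
    dob + ``enrollment_dob_slack`` days, and the birth year equals the
    state-year (age-0 at enrollment — keeps older enrollees out)."""
    if not fallback_state_years:
        return pd.Series(dtype=object)
    per_bene = enrollment.groupby("beneficiary_id").agg(
        state=("state", "first"), enrollment_start=("enrollment_start", "min")
    )
    per_bene["dob"] = dob.reindex(per_bene.index)
    per_bene = per_bene.dropna(subset=["dob", "enrollment_start"])
    slack = pd.Timedelta(days=config.enrollment_dob_slack)
    enrolled_at_birth = per_bene["enrollment_start"] <= per_bene["dob"] + slack
    in_fallback = [
        (state, int(d.year)) in fallback_state_years
        for state, d in zip(per_bene["state"], per_bene["dob"])
    ]
    chosen = per_bene[enrolled_at_birth & pd.Series(in_fallback, index=per_bene.index)]
    return pd.Series(chosen.index)


def flag_multiple_gestation_newborn(
    claims: pd.DataFrame,
    code_lists: CodeLists,
    dob: pd.Series,
    config: PipelineConfig,
) -> set[str]:
    """Beneficiaries with a multiple-gestation code on any claim in
    [dob, dob + lookahead]; enrollment-only candidates are vacuously false."""
    mult = code_lists.get("multiple_gestation", set())
    if not mult or claims.empty:
        return set()
    mask = claims_with_any_code(claims, mult)
    coded = claims[mask].copy()
    coded["_dob"] = coded["beneficiary_id"].map(dob)
    delta = (coded["service_date"] - coded["_dob"]).dt.days
    keep = coded["_dob"].notna() & (delta >= 0) & (delta <= config.newborn_claim_lookahead)
    return set(coded.loc[keep, "beneficiary_id"])


@dataclass
class NewbornStats:
    """Flow accounting for the newborn identification stage."""

    code_based: int = 0
    enrollment_based: int = 0
    no_confident_dob: int = 0
    multiple_gestation_excluded: int = 0
    extra: dict = field(default_factory=dict)


def identify_newborns(
    claims: pd.DataFrame,
    enrollment: pd.DataFrame,
    code_lists: CodeLists,
    nvss: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, NewbornStats]:
    """Full newborn identification: code route, NVSS coverage, enrollment
    fallback, multiple-gestation flagging.

    Returns (newborns, coverage_report, stats).  A beneficiary found by both
    routes is attributed to the code route; coverage is computed before the
    singleton exclusion, matching how the NVSS comparison is defined.
    """
    dob = determine_dob(enrollment)
    bene_state = enrollment.groupby("beneficiary_id")["state"].first()

    qualifying = select_newborn_claims(claims, code_lists, dob, config)
    code_based_ids = sorted(set(qualifying["beneficiary_id"]))

    # Newborn-coded claims whose beneficiary has no confident DOB: these are
    # candidates we must exclude explicitly rather than silently skip.
    coded_mask = claims_with_any_code(claims, code_lists.get("newborn_care", set()))
    coded_benes = set(claims.loc[coded_mask, "beneficiary_id"])
    no_dob_ids = sorted(b for b in coded_benes if pd.isna(dob.get(b, pd.NaT)))

    cb = pd.DataFrame({"infant_id": code_based_ids})
    cb["state"] = cb["infant_id"].map(bene_state)
    cb["date_of_birth"] = cb["infant_id"].map(dob)
    counts = (
        cb.assign(year=lambda d: d["date_of_birth"].dt.year)
        .groupby(["state", "year"], as_index=False)
        .size()
        .rename(columns={"size": "code_based_count"})
    )
    if counts.empty:
        counts = pd.DataFrame(columns=["state", "year", "code_based_count"])
    coverage = compute_coverage(counts, nvss, config)
    fallback_sy = {
        (r.state, int(r.year)) for r in coverage.itertuples() if r.fallback_active
    }

    fb_ids = enrollment_fallback(enrollment, dob, fallback_sy, config)
    fb_only = sorted(set(fb_ids) - set(code_based_ids))

    mult_ids = flag_multiple_gestation_newborn(claims, code_lists, dob, config)

    rows = []
    for infant, source in (
        [(b, "code_based") for b in code_based_ids]
        + [(b, "enrollment_based") for b in fb_only]
    ):
        multiple = infant in mult_ids
        rows.append(
            {
                "infant_id": infant,
                "state": bene_state.get(infant),
                "date_of_birth": dob.get(infant),
                "source": source,
                "multiple_gestation": multiple,
                "excluded_reason": "multiple_gestation" if multiple else "none",
            }
        )
    for infant in no_dob_ids:
        rows.append(
            {
                "infant_id": infant,
                "state": bene_state.get(infant),
                "date_of_birth": pd.NaT,
                "source": "code_based",
                "multiple_gestation": False,
                "excluded_reason": "no_confident_dob",
            }
        )
    newborns = pd.DataFrame(rows, columns=NEWBORN_COLUMNS)
    if not newborns.empty:
        newborns["date_of_birth"] = pd.to_datetime(newborns["date_of_birth"])

    stats = NewbornStats(
        code_based=len(code_based_ids),
        enrollment_based=len(fb_only),
        no_confident_dob=len(no_dob_ids),
        multiple_gestation_excluded=int((newborns["excluded_reason"] == "multiple_gestation").sum())
        if not newborns.empty
        else 0,
    )
    return newborns, coverage, stats
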