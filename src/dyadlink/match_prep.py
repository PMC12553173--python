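"""Derivation and cleaning of the four matching variables.

For every delivery and newborn candidate we derive: the residential ZIP,
the facility ZIP (via the NPI-to-ZIP lookup for the claim's filing year),
the race/ethnicity, and the case ID.  Cleaning rules: case IDs assigned to
more than the configured household size (default 10) distinct beneficiaries
within a state-year are invalidated, as are sentinel values; multiracial
identity is removed for matching (kept for reporting) because mother-infant
congruence on it is poor.  All cleaning is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig

MATCH_KEY_COLUMNS = ["residential_zip", "facility_zip", "race_ethnicity", "case_id"]


def clean_case_ids(enrollment: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Invalidate case IDs that cannot identify a household.

    A case ID is cleared (set missing) when it is a configured sentinel
    value, all-zero, or held by more than ``max_case_id_household_size``
    distinct beneficiaries within one state-year.
    """
    out = enrollment.copy()
    case = out["case_id"]
    is_sentinel = case.isin(config.case_id_sentinels) | case.fillna("").astype(str).str.fullmatch("0+")
    out.loc[is_sentinel, "case_id"] = None

    holders = (
        out.dropna(subset=["case_id"])
        .groupby(["state", "year", "case_id"])["beneficiary_id"]
        .nunique()
    )
    too_big = holders[holders > config.max_case_id_household_size]
    if len(too_big):
        big_keys = set(too_big.index)
        mask = [
            (s, y, c) in big_keys
            for s, y, c in zip(out["state"], out["year"], out["case_id"].fillna(""))
        ]
        out.loc[mask, "case_id"] = None
    return out


def clean_race(enrollment: pd.DataFrame) -> pd.DataFrame:
    """Add ``race_for_matching``: race/ethnicity with Multiracial removed.

    The original ``race_ethnicity`` column is untouched so reporting can
    still describe the full population.
    """
    out = enrollment.copy()
    race = out["race_ethnicity"]
    out["race_for_matching"] = race.where(race != "Multiracial", None)
    return out


def resolve_facility_zip(
    entity_claims: pd.DataFrame,
    npi_table: pd.DataFrame,
    entity_col: str = "entity_id",
) -> pd.Series:
    """Modal facility ZIP per entity from its claims' NPIs.

    ``entity_claims`` columns: ``entity_col``, claim_id, service_date,
    provider_npi, claim_year.  Each claim's NPI is looked up for its filing
    year; per entity the most frequent resolved ZIP wins, ties broken by
    the earliest claim date among the tied ZIPs, then lexicographically.
    Entities with no resolving claim are absent from the result.
    """
    if entity_claims.empty:
        return pd.Series(dtype=object)
    merged = entity_claims.merge(
        npi_table,
        left_on=["provider_npi", "claim_year"],
        right_on=["npi", "year"],
        how="inner",
    )
    if merged.empty:
        return pd.Series(dtype=object)
    stats = (
        merged.groupby([entity_col, "zip"])
        .agg(n=("claim_id", "size"), first_date=("service_date", "min"))
        .reset_index()
    )
    stats = stats.sort_values(
        ["n", "first_date", "zip"], ascending=[False, True, True], kind="mergesort"
    )
    best = stats.drop_duplicates(subset=[entity_col], keep="first")
    return best.set_index(entity_col)["zip"]


def _nearest_year_record(enrollment: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """For each (beneficiary_id, target_year) pick the enrollment row of
    that year, else the nearest year (earlier preferred on ties)."""
    merged = targets.merge(enrollment, on="beneficiary_id", how="left")
    merged["_dist"] = (merged["year"] - merged["target_year"]).abs()
    merged = merged.sort_values(
        ["beneficiary_id", "target_year", "_dist", "year"], kind="mergesort"
    )
    return merged.drop_duplicates(subset=["beneficiary_id", "target_year"], keep="first")


@dataclass
class MissingnessSummary:
    """Per-variable missingness tallies for the run manifest."""

    deliveries: dict = field(default_factory=dict)
    newborns: dict = field(default_factory=dict)


def attach_match_keys(
    deliveries: pd.DataFrame,
    newborns: pd.DataFrame,
    enrollment: pd.DataFrame,
    npi_table: pd.DataFrame,
    claims: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, MissingnessSummary]:
    """Attach the four matching keys to every delivery and newborn.

    Enrollment-sourced keys (residential ZIP, race, case ID) come from the
    record of the event year — the delivery midpoint year or the birth year
    — falling back to the nearest available year.  Facility ZIP is resolved
    from the delivery's clustered claims, or the newborn's claims within
    the post-birth lookahead window.  Records absent from enrollment keep
    missing keys but are retained.
    """
    cleaned = clean_race(clean_case_ids(enrollment, config))

    def _enrollment_keys(ids: pd.Series, years: pd.Series) -> pd.DataFrame:
        years = years.astype(int)
        targets = pd.DataFrame(
            {"beneficiary_id": ids.values, "target_year": years.values}
        ).drop_duplicates()
        picked = _nearest_year_record(cleaned, targets)
        picked = picked.set_index(["beneficiary_id", "target_year"])
        key = pd.MultiIndex.from_arrays([ids.values, years.values])
        out = picked.reindex(key)[["residential_zip", "race_for_matching", "case_id"]]
        out.columns = ["residential_zip", "race_ethnicity", "case_id"]
        return out.reset_index(drop=True)

    d_out = deliveries.copy()
    if not d_out.empty:
        keys = _enrollment_keys(d_out["mother_id"], d_out["midpoint"].dt.year)
        for col in keys.columns:
            d_out[col] = keys[col].values

        claim_map = d_out[["delivery_id", "claim_ids"]].copy()
        claim_map["claim_id"] = claim_map["claim_ids"].str.split(";")
        long = claim_map.explode("claim_id")[["delivery_id", "claim_id"]]
        d_claims = long.merge(
            claims[["claim_id", "service_date", "provider_npi", "claim_year"]],
            on="claim_id",
            how="left",
        ).rename(columns={"delivery_id": "entity_id"})
        fz = resolve_facility_zip(d_claims.dropna(subset=["provider_npi"]), npi_table)
        d_out["facility_zip"] = d_out["delivery_id"].map(fz)
    else:
        for col in MATCH_KEY_COLUMNS:
            d_out[col] = pd.Series(dtype=object)

    n_out = newborns.copy()
    if not n_out.empty:
        keys = _enrollment_keys(n_out["infant_id"], n_out["date_of_birth"].dt.year.fillna(-1).astype(int))
        for col in keys.columns:
            n_out[col] = keys[col].values

        inf_claims = claims.merge(
            n_out[["infant_id", "date_of_birth"]],
            left_on="beneficiary_id",
            right_on="infant_id",
            how="inner",
        )
        delta = (inf_claims["service_date"] - inf_claims["date_of_birth"]).dt.days
        inf_claims = inf_claims[
            (delta >= 0) & (delta <= config.newborn_claim_lookahead)
        ].rename(columns={"infant_id": "entity_id"})
        fz = resolve_facility_zip(
            inf_claims.dropna(subset=["provider_npi"])[
                ["entity_id", "claim_id", "service_date", "provider_npi", "claim_year"]
            ],
            npi_table,
        )
        n_out["facility_zip"] = n_out["infant_id"].map(fz)
    else:
        for col in MATCH_KEY_COLUMNS:
            n_out[col] = pd.Series(dtype=object)

    summary = MissingnessSummary(
        deliveries={c: int(d_out[c].isna().sum()) for c in MATCH_KEY_COLUMNS},
        newborns={c: int(n_out[c].isna().sum()) for c in MATCH_KEY_COLUMNS},
    )
    return d_out, n_out, summary
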