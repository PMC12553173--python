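"""End-to-end orchestration: claims in, linked dyads and reports out.

Chains the stages in their canonical order — delivery identification,
newborn identification (with the NVSS-coverage fallback), matching-key
preparation, the six-phase matcher — and accumulates a run manifest with
the row counts behind each stage transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import delivery_id, match_engine, match_prep, newborn_id, reporting
from .claims_io import CodeLists
from .config import PipelineConfig


@dataclass
class PipelineResult:
    deliveries: pd.DataFrame
    newborns: pd.DataFrame
    coverage: pd.DataFrame
    delivery_pool: pd.DataFrame
    newborn_pool: pd.DataFrame
    links: pd.DataFrame
    tallies: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def build_pools(
    deliveries: pd.DataFrame, newborns: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matchable pools: singleton, non-excluded records with match keys."""
    d = deliveries[deliveries["excluded_reason"] == "none"].reset_index(drop=True)
    n = newborns[newborns["excluded_reason"] == "none"].reset_index(drop=True)
    return (
        d[match_engine.DELIVERY_POOL_COLUMNS],
        n[match_engine.NEWBORN_POOL_COLUMNS],
    )


def run_pipeline(
    claims: pd.DataFrame,
    enrollment: pd.DataFrame,
    npi_table: pd.DataFrame,
    nvss: pd.DataFrame,
    code_lists: CodeLists,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run identification, preparation and matching over one claim universe."""
    config = config or PipelineConfig()
    manifest: dict = {"claims_in": len(claims), "enrollment_in": len(enrollment)}

    selected, sel_stats = delivery_id.select_delivery_claims(
        claims, code_lists, enrollment, config
    )
    manifest["delivery_claims_selected"] = sel_stats.selected
    manifest["delivery_claims_age_excluded"] = sel_stats.age_excluded_claims
    manifest["delivery_claims_missing_dob"] = sel_stats.missing_dob_claims

    deliveries = delivery_id.identify_deliveries(selected, code_lists, config)
    manifest["unique_deliveries"] = len(deliveries)
    manifest["deliveries_wide_window"] = int(
        (deliveries["excluded_reason"] == "wide_window").sum()
    ) if not deliveries.empty else 0
    manifest["deliveries_multiple_gestation"] = int(
        (deliveries["excluded_reason"] == "multiple_gestation").sum()
    ) if not deliveries.empty else 0

    newborns, coverage, nb_stats = newborn_id.identify_newborns(
        claims, enrollment, code_lists, nvss, config
    )
    manifest["newborns_code_based"] = nb_stats.code_based
    manifest["newborns_enrollment_based"] = nb_stats.enrollment_based
    manifest["newborns_no_confident_dob"] = nb_stats.no_confident_dob
    manifest["newborns_multiple_gestation"] = nb_stats.multiple_gestation_excluded

    deliveries, newborns, missingness = match_prep.attach_match_keys(
        deliveries, newborns, enrollment, npi_table, claims, config
    )
    manifest["missingness"] = {
        "deliveries": missingness.deliveries,
        "newborns": missingness.newborns,
    }

    d_pool, n_pool = build_pools(deliveries, newborns)
    manifest["delivery_pool"] = len(d_pool)
    manifest["newborn_pool"] = len(n_pool)

    links, tallies = match_engine.run_matching(
        d_pool, n_pool, config.phase_schedule, config.iterate_within_step
    )
    manifest["dyads_linked"] = len(links)
    manifest["pct_deliveries_linked"] = (
        100.0 * len(links) / len(d_pool) if len(d_pool) else 0.0
    )
    manifest["pct_newborns_linked"] = (
        100.0 * len(links) / len(n_pool) if len(n_pool) else 0.0
    )

    return PipelineResult(
        deliveries=deliveries,
        newborns=newborns,
        coverage=coverage,
        delivery_pool=d_pool,
        newborn_pool=n_pool,
        links=links,
        tallies=tallies,
        manifest=manifest,
    )


def identified_state_year_counts(result: PipelineResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """State-year delivery and newborn counts pre-singleton-exclusion, the
    inputs to :func:`dyadlink.reporting.nvss_comparison`."""
    d = result.deliveries
    d = d[d["excluded_reason"] != "wide_window"]
    d_counts = (
        d.assign(year=d["midpoint"].dt.year)
        .groupby(["state", "year"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        if not d.empty
        else pd.DataFrame(columns=["state", "year", "count"])
    )
    n = result.newborns
    n = n[n["excluded_reason"] != "no_confident_dob"]
    n_counts = (
        n.assign(year=n["date_of_birth"].dt.year)
        .groupby(["state", "year"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        if not n.empty
        else pd.DataFrame(columns=["state", "year", "count"])
    )
    return d_counts, n_counts


def fallback_states(coverage: pd.DataFrame) -> set[str]:
    """States with at least one fallback-active state-year."""
    return set(coverage.loc[coverage["fallback_active"], "state"])


def fallback_state_years(coverage: pd.DataFrame) -> set[tuple[str, int]]:
    """The (state, year) cells where the enrollment fallback was active."""
    active = coverage[coverage["fallback_active"]]
    return {(r.state, int(r.year)) for r in active.itertuples()}


__all__ = [
    "PipelineResult",
    "run_pipeline",
    "build_pools",
    "identified_state_year_counts",
    "fallback_states",
    "fallback_state_years",
    "reporting",
]
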