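"""Validation surfaces: NVSS congruence, cumulative match curves, and
matched-versus-unmatched demographic tables.

These reproduce the standard diagnostics for an administrative-claims
linkage: how identified delivery/newborn counts compare with the external
vital-statistics benchmark per state-year, how the cumulative match rate
grows over the 48 (phase, step) cells, and whether the linked cohort is
demographically representative of the pre-match population.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .config import PhaseSpec

#: Census region of each U.S. state (plus DC), the default region mapping.
CENSUS_REGIONS: dict[str, str] = {
    **dict.fromkeys(
        ["CT", "ME", "MA", "NH", "NJ", "NY", "PA", "RI", "VT"], "Northeast"
    ),
    **dict.fromkeys(
        ["IL", "IN", "IA", "KS", "MI", "MN", "MO", "NE", "ND", "OH", "SD", "WI"],
        "Midwest",
    ),
    **dict.fromkeys(
        ["AL", "AR", "DE", "DC", "FL", "GA", "KY", "LA", "MD", "MS", "NC", "OK",
         "SC", "TN", "TX", "VA", "WV"],
        "South",
    ),
    **dict.fromkeys(
        ["AK", "AZ", "CA", "CO", "HI", "ID", "MT", "NV", "NM", "OR", "UT", "WA", "WY"],
        "West",
    ),
}

AGE_BANDS = ["<20", "20-24", "25-29", "30-34", "35+"]


def nvss_comparison(
    delivery_counts: pd.DataFrame,
    newborn_counts: pd.DataFrame,
    nvss: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """State-year congruence of identified counts with the NVSS benchmark.

    Inputs are state-year counts *before* the singleton exclusion (multiple
    gestations cannot be separated in NVSS).  ``delivery_counts`` /
    ``newborn_counts`` columns: state, year, count.  Returns the per
    state-year table plus national over-coverage aggregates computed as
    (total identified - total NVSS) / total NVSS, in percent.
    """
    table = (
        nvss.rename(columns={"medicaid_births": "nvss_count"})
        .merge(
            delivery_counts.rename(columns={"count": "medicaid_deliveries"}),
            on=["state", "year"],
            how="outer",
        )
        .merge(
            newborn_counts.rename(columns={"count": "medicaid_newborns"}),
            on=["state", "year"],
            how="outer",
        )
    )
    for col in ("nvss_count", "medicaid_deliveries", "medicaid_newborns"):
        table[col] = table[col].fillna(0).astype(int)
    nz = table["nvss_count"].where(table["nvss_count"] > 0)
    table["delivery_ratio"] = table["medicaid_deliveries"] / nz
    table["newborn_ratio"] = table["medicaid_newborns"] / nz
    table = table[
        ["state", "year", "medicaid_newborns", "medicaid_deliveries", "nvss_count",
         "delivery_ratio", "newborn_ratio"]
    ].sort_values(["state", "year"]).reset_index(drop=True)

    total_nvss = int(table["nvss_count"].sum())
    aggregates = {
        "total_nvss": total_nvss,
        "total_deliveries": int(table["medicaid_deliveries"].sum()),
        "total_newborns": int(table["medicaid_newborns"].sum()),
        "delivery_overcoverage_pct": (
            100.0 * (table["medicaid_deliveries"].sum() - total_nvss) / total_nvss
            if total_nvss
            else float("nan")
        ),
        "newborn_overcoverage_pct": (
            100.0 * (table["medicaid_newborns"].sum() - total_nvss) / total_nvss
            if total_nvss
            else float("nan")
        ),
    }
    return table, aggregates


def cumulative_match_curve(
    links: pd.DataFrame,
    n_deliveries: int,
    n_newborns: int,
    schedule: Iterable[PhaseSpec],
) -> pd.DataFrame:
    """Cumulative percentage of deliveries and newborns linked per cell.

    One row per (phase, step) in schedule order with cumulative link counts
    and the corresponding percentages of each pool; the curves are monotone
    non-decreasing and end at the overall match rates.
    """
    cells = [
        (spec.phase_number, step)
        for spec in schedule
        for step in range(1, len(spec.step_schedule) + 1)
    ]
    per_cell = (
        links.groupby(["phase", "step"]).size() if not links.empty else pd.Series(dtype=int)
    )
    rows = []
    cum = 0
    for phase, step in cells:
        cum += int(per_cell.get((phase, step), 0))
        rows.append(
            {
                "phase": phase,
                "step": step,
                "cumulative_links": cum,
                "pct_deliveries_linked": 100.0 * cum / n_deliveries if n_deliveries else 0.0,
                "pct_newborns_linked": 100.0 * cum / n_newborns if n_newborns else 0.0,
            }
        )
    return pd.DataFrame(rows)


def cumulative_match_curve_by_state(
    links: pd.DataFrame,
    delivery_states: pd.Series,
    newborn_states: pd.Series,
    schedule: Iterable[PhaseSpec],
) -> pd.DataFrame:
    """Per-state cumulative curves; pool sizes from the state value counts."""
    d_sizes = delivery_states.value_counts()
    n_sizes = newborn_states.value_counts()
    link_state = links.merge(
        delivery_states.rename("state"), left_on="delivery_id", right_index=True, how="left"
    ) if not links.empty else links
    frames = []
    for state in sorted(set(d_sizes.index) | set(n_sizes.index)):
        sub = (
            link_state[link_state["state"] == state]
            if not links.empty
            else links
        )
        curve = cumulative_match_curve(
            sub, int(d_sizes.get(state, 0)), int(n_sizes.get(state, 0)), schedule
        )
        curve.insert(0, "state", state)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _block_percentages(values: pd.Series, denominator: int) -> pd.Series:
    counts = values.dropna().value_counts()
    if denominator == 0:
        return counts * 0.0
    return 100.0 * counts / denominator


def demographics_table(
    identified: pd.DataFrame,
    prematch: pd.DataFrame,
    matched_ids: set,
    id_col: str,
    blocks: Mapping[str, str],
) -> pd.DataFrame:
    """Representativeness table: percent of identified / pre-match /
    matched / unmatched records per demographic category.

    ``blocks`` maps a block label (e.g. ``"Race/Ethnicity"``) to the column
    of ``identified``/``prematch`` holding the category.  Percentages use
    the respective population totals as denominators, so matched plus
    unmatched counts reconstruct the pre-match counts exactly per category.
    """
    is_matched = prematch[id_col].isin(matched_ids)
    matched = prematch[is_matched]
    unmatched = prematch[~is_matched]
    rows = []
    for block, col in blocks.items():
        if col not in identified.columns:
            continue
        categories = sorted(
            set(identified[col].dropna()) | set(prematch[col].dropna()), key=str
        )
        pct_i = _block_percentages(identified[col], len(identified))
        pct_p = _block_percentages(prematch[col], len(prematch))
        pct_m = _block_percentages(matched[col], len(matched))
        pct_u = _block_percentages(unmatched[col], len(unmatched))
        for cat in categories:
            rows.append(
                {
                    "block": block,
                    "category": cat,
                    "pct_identified": float(pct_i.get(cat, 0.0)),
                    "pct_prematch": float(pct_p.get(cat, 0.0)),
                    "pct_matched": float(pct_m.get(cat, 0.0)),
                    "pct_unmatched": float(pct_u.get(cat, 0.0)),
                    "n_prematch": int((prematch[col] == cat).sum()),
                    "n_matched": int((matched[col] == cat).sum()),
                    "n_unmatched": int((unmatched[col] == cat).sum()),
                }
            )
    return pd.DataFrame(rows)


def age_band(age: pd.Series) -> pd.Series:
    """Maternal age bands used in the demographic tables."""
    bins = [-1, 19, 24, 29, 34, 200]
    return pd.cut(age, bins=bins, labels=AGE_BANDS)
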