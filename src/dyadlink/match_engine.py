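"""Greedy deterministic six-phase mother-infant matching.

Every phase requires the delivery and newborn to share a state and the
newborn's date of birth to fall inside the delivery date window expanded by
the phase's tolerance (0, 1 or 2 days).  Phases 1-3 additionally require a
shared, present case ID; phases 4-6 impose no case-ID condition.  Within a
phase, eight steps progressively relax agreement on residential ZIP,
facility ZIP and race/ethnicity: all three, any two, any one, none.  A
required variable counts as agreeing only when present on both sides and
equal — missingness never wildcards.

A candidate pair is accepted only when it is *unique*: the delivery
participates in exactly one candidate pair and so does the newborn (mutual
degree one).  Acceptances within a step are simultaneous; linked records
leave both pools before the next step.  The procedure is deterministic and
invariant to input row order.

:func:`brute_force_oracle` re-implements the same semantics by exhaustive
pairwise evaluation with no indexing, as an independent cross-check for
tests.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .config import PhaseSpec

LINK_COLUMNS = ["delivery_id", "infant_id", "mother_id", "phase", "step", "matched_on"]

DELIVERY_POOL_COLUMNS = [
    "delivery_id",
    "mother_id",
    "state",
    "window_start",
    "window_end",
    "residential_zip",
    "facility_zip",
    "race_ethnicity",
    "case_id",
]
NEWBORN_POOL_COLUMNS = [
    "infant_id",
    "state",
    "date_of_birth",
    "residential_zip",
    "facility_zip",
    "race_ethnicity",
    "case_id",
]


def candidate_pairs(
    deliveries: pd.DataFrame,
    newborns: pd.DataFrame,
    spec: PhaseSpec,
    step_vars: Sequence[str],
) -> pd.DataFrame:
    """All (delivery_id, infant_id) pairs satisfying the phase's hard
    criteria and the step's required-variable agreements.

    Hard criteria: equal state; newborn DOB within
    [window_start - tolerance, window_end + tolerance]; if the phase
    requires case IDs, both present and equal.  Each variable in
    ``step_vars`` must be present on both sides and equal.
    """
    required = list(step_vars)
    block = ["state"] + (["case_id"] if spec.case_id_required else []) + required
    d = deliveries.dropna(subset=[c for c in block if c != "state"])
    n = newborns.dropna(subset=[c for c in block if c != "state"])
    if d.empty or n.empty:
        return pd.DataFrame(columns=["delivery_id", "infant_id"])
    merged = d.merge(n, on=block, how="inner", suffixes=("_d", "_n"))
    if merged.empty:
        return pd.DataFrame(columns=["delivery_id", "infant_id"])
    tol = pd.Timedelta(days=spec.date_tolerance)
    in_window = (merged["date_of_birth"] >= merged["window_start"] - tol) & (
        merged["date_of_birth"] <= merged["window_end"] + tol
    )
    out = merged.loc[in_window, ["delivery_id", "infant_id"]]
    return out.sort_values(["delivery_id", "infant_id"]).reset_index(drop=True)


def accept_unique(pairs: pd.DataFrame) -> pd.DataFrame:
    """Mutual-degree-one acceptance, simultaneous across the whole step.

    A pair is linked iff its delivery appears in exactly one candidate pair
    and its newborn appears in exactly one candidate pair.
    """
    if pairs.empty:
        return pairs
    d_degree = pairs["delivery_id"].map(pairs["delivery_id"].value_counts())
    n_degree = pairs["infant_id"].map(pairs["infant_id"].value_counts())
    return pairs[(d_degree == 1) & (n_degree == 1)].reset_index(drop=True)


def run_matching(
    deliveries: pd.DataFrame,
    newborns: pd.DataFrame,
    schedule: Iterable[PhaseSpec],
    iterate_within_step: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full phase/step schedule over the two pools.

    Returns ``(links, tallies)``: one link row per accepted dyad annotated
    with phase, step and the step's required variables, and one tally row
    per (phase, step) cell with incremental and cumulative counts (the data
    behind a cumulative match-rate curve).

    Pools must contain only matchable records (singleton, non-excluded);
    both input frames are left unmodified.
    """
    d_pool = deliveries[DELIVERY_POOL_COLUMNS].copy()
    n_pool = newborns[NEWBORN_POOL_COLUMNS].copy()
    mother_of = dict(zip(d_pool["delivery_id"], d_pool["mother_id"]))

    links: list[dict] = []
    tallies: list[dict] = []
    cumulative = 0
    for spec in schedule:
        for step_number, step_vars in enumerate(spec.step_schedule, start=1):
            step_links = 0
            while True:
                pairs = candidate_pairs(d_pool, n_pool, spec, step_vars)
                accepted = accept_unique(pairs)
                if not accepted.empty:
                    matched_on = "+".join(step_vars)
                    for d_id, n_id in accepted.itertuples(index=False, name=None):
                        links.append(
                            {
                                "delivery_id": d_id,
                                "infant_id": n_id,
                                "mother_id": mother_of[d_id],
                                "phase": spec.phase_number,
                                "step": step_number,
                                "matched_on": matched_on,
                            }
                        )
                    step_links += len(accepted)
                    d_pool = d_pool[~d_pool["delivery_id"].isin(set(accepted["delivery_id"]))]
                    n_pool = n_pool[~n_pool["infant_id"].isin(set(accepted["infant_id"]))]
                if not iterate_within_step or accepted.empty:
                    break
            cumulative += step_links
            tallies.append(
                {
                    "phase": spec.phase_number,
                    "step": step_number,
                    "n_links": step_links,
                    "cumulative_links": cumulative,
                }
            )

    link_df = pd.DataFrame(links, columns=LINK_COLUMNS)
    if not link_df.empty:
        link_df = link_df.sort_values(["phase", "step", "delivery_id"]).reset_index(drop=True)
        if link_df["delivery_id"].duplicated().any() or link_df["infant_id"].duplicated().any():
            raise AssertionError("one-to-one linking invariant violated")
    tally_df = pd.DataFrame(tallies, columns=["phase", "step", "n_links", "cumulative_links"])
    return link_df, tally_df


# ---------------------------------------------------------------------------
# Independent oracle: same semantics, exhaustive pairwise evaluation.
# ---------------------------------------------------------------------------


def _record_list(df: pd.DataFrame, id_col: str) -> list[dict]:
    records = []
    for row in df.to_dict("records"):
        rec = dict(row)
        for key, value in list(rec.items()):
            if pd.isna(value):
                rec[key] = None
        records.append(rec)
    return sorted(records, key=lambda r: str(r[id_col]))


def brute_force_oracle(
    deliveries: pd.DataFrame,
    newborns: pd.DataFrame,
    schedule: Iterable[PhaseSpec],
    iterate_within_step: bool = False,
) -> pd.DataFrame:
    """Exhaustive re-implementation of :func:`run_matching` for testing.

    Evaluates every delivery-newborn pair against the phase/step predicate
    with plain Python comparisons (no merges or indexes) and applies the
    same greedy mutual-degree-one acceptance.  Must agree with
    :func:`run_matching` exactly, phase/step attribution included.
    """
    d_pool = _record_list(deliveries[DELIVERY_POOL_COLUMNS], "delivery_id")
    n_pool = _record_list(newborns[NEWBORN_POOL_COLUMNS], "infant_id")

    def compatible(d: dict, n: dict, spec: PhaseSpec, step_vars: tuple[str, ...]) -> bool:
        if d["state"] != n["state"]:
            return False
        dob = n["date_of_birth"]
        tol = pd.Timedelta(days=spec.date_tolerance)
        if dob is None or not (d["window_start"] - tol <= dob <= d["window_end"] + tol):
            return False
        if spec.case_id_required:
            if d["case_id"] is None or n["case_id"] is None or d["case_id"] != n["case_id"]:
                return False
        for var in step_vars:
            if d[var] is None or n[var] is None or d[var] != n[var]:
                return False
        return True

    links = []
    for spec in schedule:
        for step_number, step_vars in enumerate(spec.step_schedule, start=1):
            while True:
                pairs = [
                    (d, n)
                    for d in d_pool
                    for n in n_pool
                    if compatible(d, n, spec, step_vars)
                ]
                d_count: dict[str, int] = {}
                n_count: dict[str, int] = {}
                for d, n in pairs:
                    d_count[d["delivery_id"]] = d_count.get(d["delivery_id"], 0) + 1
                    n_count[n["infant_id"]] = n_count.get(n["infant_id"], 0) + 1
                accepted = [
                    (d, n)
                    for d, n in pairs
                    if d_count[d["delivery_id"]] == 1 and n_count[n["infant_id"]] == 1
                ]
                for d, n in accepted:
                    links.append(
                        {
                            "delivery_id": d["delivery_id"],
                            "infant_id": n["infant_id"],
                            "mother_id": d["mother_id"],
                            "phase": spec.phase_number,
                            "step": step_number,
                            "matched_on": "+".join(step_vars),
                        }
                    )
                taken_d = {d["delivery_id"] for d, _ in accepted}
                taken_n = {n["infant_id"] for _, n in accepted}
                d_pool = [d for d in d_pool if d["delivery_id"] not in taken_d]
                n_pool = [n for n in n_pool if n["infant_id"] not in taken_n]
                if not iterate_within_step or not accepted:
                    break

    link_df = pd.DataFrame(links, columns=LINK_COLUMNS)
    if not link_df.empty:
        link_df = link_df.sort_values(["phase", "step", "delivery_id"]).reset_index(drop=True)
    return link_df
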