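"""Identification of unique deliveries resulting in live births.

Delivery-coded claims for beneficiaries aged 12–50 at service are grouped,
per beneficiary, into distinct deliveries by agglomerative merging on claim
dates: clusters merge while the smallest midpoint distance is below the
minimum inter-delivery gap (default 270 days), so no two emitted deliveries
of one beneficiary can sit within a nine-month span of each other.  Each
delivery's date window spans its earliest to latest claim; windows wider
than the configured maximum (default 7 days) and deliveries carrying
multiple-gestation codes are excluded from matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_io import CodeLists, claims_with_any_code, explode_codes
from .config import PipelineConfig

DELIVERY_COLUMNS = [
    "delivery_id",
    "mother_id",
    "state",
    "claim_dates",
    "claim_ids",
    "n_claims",
    "window_start",
    "window_end",
    "midpoint",
    "multiple_gestation",
    "excluded_reason",
]


def midpoint_ordinal(ordinals: list[int]) -> int:
    """Date midway between the earliest and latest day, rounded down."""
    return min(ordinals) + (max(ordinals) - min(ordinals)) // 2


def cluster_dates(ordinals: list[int], min_gap: int) -> list[list[int]]:
    """Agglomerative midpoint-merge clustering of claim-day ordinals.

    Starts from singleton clusters and repeatedly merges the pair of
    clusters whose midpoints are closest, while that distance is strictly
    below ``min_gap``, recomputing midpoints after every merge.  Ties on
    distance are broken toward the pair whose earlier cluster midpoint is
    smallest, which makes the result independent of input order.  The
    output clusters therefore satisfy pairwise midpoint gaps >= ``min_gap``.
    """
    if not ordinals:
        return []
    # Claims on the same calendar day always belong to one delivery.
    clusters = [[d] for d in sorted(set(ordinals))]
    while len(clusters) > 1:
        mids = [midpoint_ordinal(c) for c in clusters]
        best: tuple[int, int, int] | None = None  # (dist, left_mid, j) for adjacent-ish pairs
        best_pair: tuple[int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = abs(mids[i] - mids[j])
                key = (dist, min(mids[i], mids[j]), max(mids[i], mids[j]))
                if best is None or key < best:
                    best = key
                    best_pair = (i, j)
        assert best is not None and best_pair is not None
        if best[0] >= min_gap:
            break
        i, j = best_pair
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
        clusters.sort(key=midpoint_ordinal)
    clusters.sort(key=midpoint_ordinal)
    return clusters


@dataclass
class SelectionStats:
    """Row accounting for the delivery-claim selection stage."""

    claims_in: int = 0
    delivery_coded: int = 0
    missing_dob_claims: int = 0
    age_excluded_claims: int = 0
    selected: int = 0
    extra: dict = field(default_factory=dict)


def beneficiary_dob(enrollment: pd.DataFrame) -> pd.Series:
    """First non-missing date of birth per beneficiary (earliest year wins)."""
    known = enrollment.dropna(subset=["date_of_birth"]).sort_values("year")
    return known.groupby("beneficiary_id")["date_of_birth"].first()


def age_in_years(dob: pd.Series, on: pd.Series) -> pd.Series:
    """Completed years of age at ``on`` (birthday-based, not year difference)."""
    before_birthday = (on.dt.month < dob.dt.month) | (
        (on.dt.month == dob.dt.month) & (on.dt.day < dob.dt.day)
    )
    return on.dt.year - dob.dt.year - before_birthday.astype(int)


def select_delivery_claims(
    claims: pd.DataFrame,
    code_lists: CodeLists,
    enrollment: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, SelectionStats]:
    """Claims bearing a delivery code whose beneficiary was aged
    ``min_age``–``max_age`` (inclusive) at the service date.

    Beneficiaries without a resolvable date of birth are excluded and
    counted; the operation filters and never fails.
    """
    stats = SelectionStats(claims_in=len(claims))
    mask = claims_with_any_code(claims, code_lists.get("delivery", set()))
    coded = claims[mask].copy()
    stats.delivery_coded = len(coded)
    if coded.empty:
        return coded, stats

    dob = beneficiary_dob(enrollment)
    coded["_dob"] = coded["beneficiary_id"].map(dob)
    missing = coded["_dob"].isna()
    stats.missing_dob_claims = int(missing.sum())
    coded = coded[~missing].copy()

    age = age_in_years(coded["_dob"], coded["service_date"])
    in_range = (age >= config.min_age) & (age <= config.max_age)
    stats.age_excluded_claims = int((~in_range).sum())
    out = coded[in_range].drop(columns="_dob").reset_index(drop=True)
    stats.selected = len(out)
    return out, stats


def _window_span(start: int, end: int, config: PipelineConfig) -> int:
    span = end - start
    return span + 1 if config.window_span_inclusive_count else span


def identify_deliveries(
    selected_claims: pd.DataFrame,
    code_lists: CodeLists,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Cluster each beneficiary's delivery claims into distinct deliveries.

    Returns one row per delivery with its claim dates, estimated date
    window, midpoint, multiple-gestation flag and exclusion reason
    (``none`` / ``wide_window`` / ``multiple_gestation``).  Every selected
    claim belongs to exactly one delivery.
    """
    if selected_claims.empty:
        return pd.DataFrame(columns=DELIVERY_COLUMNS)

    mult_ids: set[str] = set()
    mult_codes = code_lists.get("multiple_gestation", set())
    if mult_codes:
        long = explode_codes(selected_claims)
        mult_ids = set(
            long[[(c, s) in mult_codes for c, s in zip(long["code"], long["system"])]]["claim_id"]
        )

    epoch = pd.Timestamp("1970-01-01")
    work = selected_claims[["claim_id", "beneficiary_id", "state", "service_date"]].copy()
    work["_ord"] = (work["service_date"] - epoch).dt.days

    rows = []
    for (mother, state), grp in work.groupby(["beneficiary_id", "state"], sort=True):
        by_day: dict[int, list[str]] = {}
        for cid, day in zip(grp["claim_id"], grp["_ord"]):
            by_day.setdefault(int(day), []).append(str(cid))
        clusters = cluster_dates(list(by_day), config.min_interdelivery_midpoint_gap)
        for k, cluster in enumerate(clusters, start=1):
            days = sorted(cluster)
            claim_ids = sorted(cid for d in days for cid in by_day[d])
            start, end = days[0], days[-1]
            mid = midpoint_ordinal(days)
            wide = _window_span(start, end, config) > config.max_window_span
            multiple = any(cid in mult_ids for cid in claim_ids)
            if wide:
                reason = "wide_window"
            elif multiple:
                reason = "multiple_gestation"
            else:
                reason = "none"
            rows.append(
                {
                    "delivery_id": f"{mother}-D{k}",
                    "mother_id": mother,
                    "state": state,
                    "claim_dates": ";".join(
                        (epoch + pd.Timedelta(days=d)).strftime("%Y-%m-%d") for d in days
                    ),
                    "claim_ids": ";".join(claim_ids),
                    "n_claims": len(claim_ids),
                    "window_start": epoch + pd.Timedelta(days=start),
                    "window_end": epoch + pd.Timedelta(days=end),
                    "midpoint": epoch + pd.Timedelta(days=mid),
                    "multiple_gestation": multiple,
                    "excluded_reason": reason,
                }
            )

    events = pd.DataFrame(rows, columns=DELIVERY_COLUMNS)
    _assert_midpoint_gaps(events, config.min_interdelivery_midpoint_gap)
    return events


def cluster_delivery_claims(claims: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Deliveries for a single beneficiary's claims (thin per-beneficiary view).

    ``claims`` must share one beneficiary_id and state; the result is the
    same event table :func:`identify_deliveries` builds for that group.
    """
    if claims.empty:
        return pd.DataFrame(columns=DELIVERY_COLUMNS)
    if claims["beneficiary_id"].nunique() != 1 or claims["state"].nunique() != 1:
        raise ValueError("cluster_delivery_claims expects claims of one beneficiary and state")
    return identify_deliveries(claims, {}, config)


def estimate_window(events: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Recompute window bounds/midpoint from claim dates and re-apply the
    wide-window exclusion; idempotent on :func:`identify_deliveries` output."""
    out = events.copy()
    for idx, dates in out["claim_dates"].items():
        days = sorted(pd.Timestamp(d).toordinal() for d in str(dates).split(";"))
        start, end = days[0], days[-1]
        out.at[idx, "window_start"] = pd.Timestamp.fromordinal(start)
        out.at[idx, "window_end"] = pd.Timestamp.fromordinal(end)
        out.at[idx, "midpoint"] = pd.Timestamp.fromordinal(midpoint_ordinal(days))
        if _window_span(start, end, config) > config.max_window_span:
            out.at[idx, "excluded_reason"] = "wide_window"
    return out


def flag_multiple_gestation_delivery(
    events: pd.DataFrame, claims: pd.DataFrame, code_lists: CodeLists
) -> pd.Series:
    """True per event iff any claim in its cluster bears a multiple-gestation
    code (empty code list: vacuously false everywhere)."""
    mult_codes = code_lists.get("multiple_gestation", set())
    if events.empty or not mult_codes:
        return pd.Series(False, index=events.index)
    mask = claims_with_any_code(claims, mult_codes)
    mult_ids = set(claims.loc[mask, "claim_id"].astype(str))
    return events["claim_ids"].map(
        lambda ids: any(cid in mult_ids for cid in str(ids).split(";"))
    )


def _assert_midpoint_gaps(events: pd.DataFrame, min_gap: int) -> None:
    """Runtime invariant: per-beneficiary delivery midpoints >= min_gap apart."""
    for _, grp in events.groupby("mother_id"):
        mids = np.sort(grp["midpoint"].values)
        if len(mids) > 1:
            gaps = np.diff(mids).astype("timedelta64[D]").astype(int)
            if (gaps < min_gap).any():
                raise AssertionError(
                    f"delivery midpoint gap below {min_gap} days for {grp['mother_id'].iloc[0]}"
                )
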