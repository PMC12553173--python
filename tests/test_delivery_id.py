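"""Delivery identification: age filter, clustering, windows, twin flags.

The clustering oracle is an independent re-implementation: a naive greedy
merger over explicit midpoint recomputation, plus an exhaustive check that
the emitted partition is among all set partitions whose clusters satisfy
the pairwise midpoint-gap constraint.
"""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadlink import delivery_id
from dyadlink.config import PipelineConfig

from conftest import claim_row, claims_frame, enrollment_frame, enrollment_row


# ---------------------------------------------------------------------------
# Independent clustering oracle
# ---------------------------------------------------------------------------


def naive_midpoint(days):
    return min(days) + (max(days) - min(days)) // 2


def naive_greedy_clustering(days, min_gap):
    """Plain re-implementation: recompute every pairwise midpoint distance
    each round, merge the closest pair (ties to the smaller midpoints)."""
    clusters = [frozenset([d]) for d in set(days)]
    while len(clusters) > 1:
        candidates = []
        for a, b in itertools.combinations(clusters, 2):
            ma, mb = naive_midpoint(a), naive_midpoint(b)
            candidates.append((abs(ma - mb), min(ma, mb), max(ma, mb), a, b))
        dist, _, _, a, b = min(candidates, key=lambda t: t[:3])
        if dist >= min_gap:
            break
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return sorted(tuple(sorted(c)) for c in clusters)


def all_valid_partitions(days, min_gap):
    """All set partitions of the days whose clusters have pairwise midpoint
    gaps >= min_gap (exhaustive; for <= 6 distinct days)."""
    days = sorted(set(days))

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    valid = []
    for part in partitions(days):
        mids = [naive_midpoint(c) for c in part]
        if all(
            abs(ma - mb) >= min_gap for ma, mb in itertools.combinations(mids, 2)
        ):
            valid.append(sorted(tuple(sorted(c)) for c in part))
    return valid


class TestClustering:
    def test_close_claims_merge(self):
        assert delivery_id.cluster_dates([0, 100], 270) == [[0, 100]]

    def test_distant_claims_split(self):
        assert delivery_id.cluster_dates([0, 300], 270) == [[0], [300]]

    def test_four_claim_example_matches_oracle(self):
        days = [0, 2, 265, 530]
        result = [tuple(c) for c in delivery_id.cluster_dates(days, 270)]
        oracle = naive_greedy_clustering(days, 270)
        assert result == oracle
        assert sorted(result) in all_valid_partitions(days, 270)

    @given(
        st.lists(st.integers(min_value=0, max_value=1200), min_size=1, max_size=6),
        st.integers(min_value=0, max_value=5),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_naive_oracle_and_is_valid(self, days, _salt):
        result = [tuple(c) for c in delivery_id.cluster_dates(days, 270)]
        assert result == naive_greedy_clustering(days, 270)
        assert sorted(result) in all_valid_partitions(days, 270)

    @given(st.lists(st.integers(min_value=0, max_value=2000), min_size=1, max_size=10))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_emitted_midpoint_gaps_at_least_threshold(self, days):
        clusters = delivery_id.cluster_dates(days, 270)
        mids = [naive_midpoint(c) for c in clusters]
        assert all(
            abs(a - b) >= 270 for a, b in itertools.combinations(mids, 2)
        )
        # claim conservation: every distinct day in exactly one cluster
        assert sorted(d for c in clusters for d in c) == sorted(set(days))

    def test_order_independence(self):
        days = [530, 0, 265, 2, 533, 900]
        a = delivery_id.cluster_dates(days, 270)
        b = delivery_id.cluster_dates(list(reversed(days)), 270)
        assert a == b


class TestAgeFilter:
    @pytest.mark.parametrize(
        "service_date,expected_kept",
        [
            ("2011-12-31", 0),  # age 11, one day before 12th birthday
            ("2012-01-01", 1),  # age 12 on the birthday, inclusive
            ("2050-12-31", 1),  # age 50, still inclusive
            ("2051-01-01", 0),  # age 51
        ],
    )
    def test_age_boundaries(self, code_lists, config, service_date, expected_kept):
        claims = claims_frame(
            [claim_row(beneficiary_id="B1", service_date=service_date, codes="ICD10-DX:O80")]
        )
        enrollment = enrollment_frame(
            [enrollment_row(beneficiary_id="B1", date_of_birth="2000-01-01")]
        )
        selected, _ = delivery_id.select_delivery_claims(
            claims, code_lists, enrollment, config
        )
        assert len(selected) == expected_kept

    def test_claim_without_delivery_code_excluded(self, code_lists, config):
        claims = claims_frame([claim_row(codes="ICD10-DX:Z38.00")])
        enrollment = enrollment_frame([enrollment_row()])
        selected, _ = delivery_id.select_delivery_claims(claims, code_lists, enrollment, config)
        assert selected.empty

    def test_missing_dob_excluded_and_counted(self, code_lists, config):
        claims = claims_frame([claim_row(beneficiary_id="B9")])
        enrollment = enrollment_frame(
            [enrollment_row(beneficiary_id="B9", date_of_birth=None)]
        )
        selected, stats = delivery_id.select_delivery_claims(
            claims, code_lists, enrollment, config
        )
        assert selected.empty and stats.missing_dob_claims == 1


class TestWindow:
    def _events(self, dates, config, code_lists=None):
        claims = claims_frame(
            [
                claim_row(claim_id=f"C{i}", beneficiary_id="B1", service_date=d)
                for i, d in enumerate(dates)
            ]
        )
        return delivery_id.identify_deliveries(claims, code_lists or {}, config)

    def test_single_day_window_retained(self, config):
        events = self._events(["2015-03-01"], config)
        assert len(events) == 1
        ev = events.iloc[0]
        assert ev["window_start"] == ev["window_end"] == pd.Timestamp("2015-03-01")
        assert ev["excluded_reason"] == "none"

    def test_span_seven_retained_span_eight_excluded(self, config):
        kept = self._events(["2015-03-01", "2015-03-08"], config)  # span 7
        assert kept.iloc[0]["excluded_reason"] == "none"
        wide = self._events(["2015-03-01", "2015-03-09"], config)  # span 8
        assert wide.iloc[0]["excluded_reason"] == "wide_window"

    def test_midpoint_rounds_down(self, config):
        events = self._events(["2015-03-01", "2015-03-04"], config)  # gap 3 -> +1
        assert events.iloc[0]["midpoint"] == pd.Timestamp("2015-03-02")


class TestMultipleGestation:
    def test_twin_code_flags_event(self, config, code_lists):
        claims = claims_frame(
            [
                claim_row(claim_id="C1", codes="ICD10-DX:O80"),
                claim_row(claim_id="C2", service_date="2015-03-02", codes="ICD10-DX:O80;ICD10-DX:Z37.2"),
            ]
        )
        events = delivery_id.identify_deliveries(claims, code_lists, config)
        assert events.iloc[0]["multiple_gestation"]
        assert events.iloc[0]["excluded_reason"] == "multiple_gestation"

    def test_singleton_codes_not_flagged(self, config, code_lists):
        claims = claims_frame([claim_row(codes="ICD10-DX:O80")])
        events = delivery_id.identify_deliveries(claims, code_lists, config)
        assert not events.iloc[0]["multiple_gestation"]

    def test_empty_code_list_vacuously_false(self, config):
        claims = claims_frame([claim_row(codes="ICD10-DX:O80;ICD10-DX:Z37.2")])
        events = delivery_id.identify_deliveries(claims, {}, config)
        assert not events.iloc[0]["multiple_gestation"]


class TestEventInvariants:
    def test_claim_conservation_and_row_order_determinism(self, config):
        rows = [
            claim_row(claim_id=f"C{i}", beneficiary_id="B1", service_date=d)
            for i, d in enumerate(
                ["2015-03-01", "2015-03-03", "2016-02-01", "2016-02-02", "2013-01-01"]
            )
        ]
        forward = delivery_id.identify_deliveries(claims_frame(rows), {}, config)
        backward = delivery_id.identify_deliveries(
            claims_frame(list(reversed(rows))), {}, config
        )
        pd.testing.assert_frame_equal(forward, backward)
        all_ids = sorted(
            cid for ids in forward["claim_ids"] for cid in ids.split(";")
        )
        assert all_ids == sorted(f"C{i}" for i in range(5))

    def test_wide_window_takes_precedence_over_twin_flag(self, config, code_lists):
        claims = claims_frame(
            [
                claim_row(claim_id="C1", codes="ICD10-DX:O80;ICD10-DX:Z37.2"),
                claim_row(claim_id="C2", service_date="2015-03-20", codes="ICD10-DX:O80"),
            ]
        )
        events = delivery_id.identify_deliveries(claims, code_lists, config)
        assert events.iloc[0]["excluded_reason"] == "wide_window"

    def test_inclusive_day_count_mode(self):
        cfg = PipelineConfig(window_span_inclusive_count=True)
        claims = claims_frame(
            [
                claim_row(claim_id="C1", service_date="2015-03-01"),
                claim_row(claim_id="C2", service_date="2015-03-08"),
            ]
        )
        events = delivery_id.identify_deliveries(claims, {}, cfg)
        assert events.iloc[0]["excluded_reason"] == "wide_window"  # 8 distinct days
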