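"""Matching-variable derivation and cleaning: case-ID household limit,
multiracial removal, modal facility ZIP, and year-aligned key attachment."""

import pandas as pd
import pytest

from dyadlink import match_prep
from dyadlink.config import PipelineConfig

from conftest import claims_frame, claim_row, enrollment_frame, enrollment_row


class TestCleanCaseIds:
    def _household(self, n, case_id="H1", state="ZA", year=2015):
        return [
            enrollment_row(beneficiary_id=f"B{i}", state=state, year=year, case_id=case_id)
            for i in range(n)
        ]

    @pytest.mark.parametrize("n,kept", [(10, True), (11, False)])
    def test_household_size_boundary(self, config, n, kept):
        enr = enrollment_frame(self._household(n))
        out = match_prep.clean_case_ids(enr, config)
        if kept:
            assert (out["case_id"] == "H1").all()
        else:
            assert out["case_id"].isna().all()

    def test_same_case_id_in_different_state_years_counted_separately(self, config):
        enr = enrollment_frame(
            self._household(6, year=2014) + self._household(6, year=2015)
        )
        out = match_prep.clean_case_ids(enr, config)
        assert (out["case_id"] == "H1").all()

    def test_sentinel_values_removed(self, config):
        enr = enrollment_frame(
            [
                enrollment_row(beneficiary_id="B1", case_id="000000000"),
                enrollment_row(beneficiary_id="B2", case_id="0"),
                enrollment_row(beneficiary_id="B3", case_id="H7"),
            ]
        )
        out = match_prep.clean_case_ids(enr, config).set_index("beneficiary_id")
        assert pd.isna(out.loc["B1", "case_id"]) and pd.isna(out.loc["B2", "case_id"])
        assert out.loc["B3", "case_id"] == "H7"

    def test_idempotent(self, config):
        enr = enrollment_frame(self._household(12) + [enrollment_row(beneficiary_id="Z", case_id="H2")])
        once = match_prep.clean_case_ids(enr, config)
        twice = match_prep.clean_case_ids(once, config)
        pd.testing.assert_frame_equal(once, twice)


class TestCleanRace:
    def test_multiracial_removed_for_matching_only(self):
        enr = enrollment_frame(
            [
                enrollment_row(beneficiary_id="B1", race_ethnicity="Multiracial"),
                enrollment_row(beneficiary_id="B2", race_ethnicity="Hispanic"),
                enrollment_row(beneficiary_id="B3", race_ethnicity=None),
            ]
        )
        out = match_prep.clean_race(enr).set_index("beneficiary_id")
        assert pd.isna(out.loc["B1", "race_for_matching"])
        assert out.loc["B1", "race_ethnicity"] == "Multiracial"  # kept for reporting
        assert out.loc["B2", "race_for_matching"] == "Hispanic"
        assert pd.isna(out.loc["B3", "race_for_matching"])

    def test_idempotent(self):
        enr = enrollment_frame([enrollment_row(race_ethnicity="Multiracial")])
        once = match_prep.clean_race(enr)
        twice = match_prep.clean_race(once)
        pd.testing.assert_frame_equal(once, twice)


class TestFacilityZip:
    def _npi(self, rows):
        return pd.DataFrame(rows, columns=["npi", "year", "zip"])

    def _claims(self, specs):
        return pd.DataFrame(
            [
                {
                    "entity_id": "E1",
                    "claim_id": f"C{i}",
                    "service_date": pd.Timestamp(date),
                    "provider_npi": npi,
                    "claim_year": pd.Timestamp(date).year,
                }
                for i, (date, npi) in enumerate(specs)
            ]
        )

    def test_single_resolving_claim(self):
        claims = self._claims([("2015-03-01", "1000000001")])
        npi = self._npi([("1000000001", 2015, "60001")])
        assert match_prep.resolve_facility_zip(claims, npi)["E1"] == "60001"

    def test_absent_npi_gives_missing(self):
        claims = self._claims([("2015-03-01", "1000000009")])
        npi = self._npi([("1000000001", 2015, "60001")])
        assert "E1" not in match_prep.resolve_facility_zip(claims, npi).index

    def test_modal_zip_wins(self):
        claims = self._claims(
            [("2015-03-01", "1000000001"), ("2015-03-02", "1000000001"), ("2015-03-03", "1000000002")]
        )
        npi = self._npi([("1000000001", 2015, "60001"), ("1000000002", 2015, "60002")])
        assert match_prep.resolve_facility_zip(claims, npi)["E1"] == "60001"

    def test_tie_broken_by_earliest_claim_date(self):
        claims = self._claims([("2015-03-02", "1000000002"), ("2015-03-01", "1000000001")])
        npi = self._npi([("1000000001", 2015, "60009"), ("1000000002", 2015, "60002")])
        # one claim each; ZIP of the earlier claim wins even if lexicographically larger
        assert match_prep.resolve_facility_zip(claims, npi)["E1"] == "60009"

    def test_year_specific_lookup(self):
        claims = self._claims([("2014-03-01", "1000000001")])
        npi = self._npi([("1000000001", 2014, "60014"), ("1000000001", 2015, "60015")])
        assert match_prep.resolve_facility_zip(claims, npi)["E1"] == "60014"


class TestAttachMatchKeys:
    def _deliveries(self):
        return pd.DataFrame(
            [
                {
                    "delivery_id": "M1-D1",
                    "mother_id": "M1",
                    "state": "ZA",
                    "claim_dates": "2015-03-01",
                    "claim_ids": "C1",
                    "n_claims": 1,
                    "window_start": pd.Timestamp("2015-03-01"),
                    "window_end": pd.Timestamp("2015-03-01"),
                    "midpoint": pd.Timestamp("2015-03-01"),
                    "multiple_gestation": False,
                    "excluded_reason": "none",
                }
            ]
        )

    def test_full_enrollment_yields_all_keys(self, config):
        enr = enrollment_frame(
            [enrollment_row(beneficiary_id="M1", year=2015, residential_zip="60001",
                            race_ethnicity="Black", case_id="H1")]
        )
        claims = claims_frame(
            [claim_row(claim_id="C1", beneficiary_id="M1", provider_npi="1000000001")]
        )
        npi = pd.DataFrame([("1000000001", 2015, "60002")], columns=["npi", "year", "zip"])
        d, n, summary = match_prep.attach_match_keys(
            self._deliveries(), pd.DataFrame(), enr, npi, claims, config
        )
        row = d.iloc[0]
        assert row["residential_zip"] == "60001"
        assert row["facility_zip"] == "60002"
        assert row["race_ethnicity"] == "Black"
        assert row["case_id"] == "H1"
        assert summary.deliveries == {c: 0 for c in match_prep.MATCH_KEY_COLUMNS}

    def test_beneficiary_absent_from_enrollment_keeps_missing_keys(self, config):
        enr = enrollment_frame([enrollment_row(beneficiary_id="OTHER", year=2015)])
        claims = claims_frame([claim_row(claim_id="C1", beneficiary_id="M1")])
        npi = pd.DataFrame(columns=["npi", "year", "zip"])
        d, _, summary = match_prep.attach_match_keys(
            self._deliveries(), pd.DataFrame(), enr, npi, claims, config
        )
        assert len(d) == 1
        assert all(pd.isna(d.iloc[0][c]) for c in match_prep.MATCH_KEY_COLUMNS)
        assert summary.deliveries["case_id"] == 1

    def test_nearest_year_fallback_prefers_earlier_on_tie(self, config):
        enr = enrollment_frame(
            [
                enrollment_row(beneficiary_id="M1", year=2014, residential_zip="60014"),
                enrollment_row(beneficiary_id="M1", year=2016, residential_zip="60016"),
            ]
        )
        claims = claims_frame([claim_row(claim_id="C1", beneficiary_id="M1")])
        npi = pd.DataFrame(columns=["npi", "year", "zip"])
        d, _, _ = match_prep.attach_match_keys(
            self._deliveries(), pd.DataFrame(), enr, npi, claims, config
        )
        # event year 2015 absent; 2014 and 2016 equidistant -> earlier wins
        assert d.iloc[0]["residential_zip"] == "60014"

    def test_no_sentinel_survives_cleaning(self):
        cfg = PipelineConfig()
        enr = enrollment_frame(
            [enrollment_row(beneficiary_id="M1", year=2015, case_id="999999999")]
        )
        claims = claims_frame([claim_row(claim_id="C1", beneficiary_id="M1")])
        npi = pd.DataFrame(columns=["npi", "year", "zip"])
        d, _, _ = match_prep.attach_match_keys(
            self._deliveries(), pd.DataFrame(), enr, npi, claims, cfg
        )
        assert pd.isna(d.iloc[0]["case_id"])
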