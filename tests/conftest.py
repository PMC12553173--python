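"""Shared fixtures: a default config, tiny code lists, and pool builders."""

from __future__ import annotations

import pandas as pd
import pytest

from dyadlink.config import PipelineConfig


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def code_lists() -> dict:
    return {
        "delivery": {("O80", "ICD10-DX"), ("59400", "CPT")},
        "newborn_care": {("Z38.00", "ICD10-DX"), ("99460", "CPT")},
        "multiple_gestation": {("Z37.2", "ICD10-DX")},
    }


def make_delivery(
    delivery_id="D1",
    mother_id="M1",
    state="ZA",
    window_start="2015-03-01",
    window_end="2015-03-02",
    residential_zip="60001",
    facility_zip="60002",
    race_ethnicity="White",
    case_id="H1",
) -> dict:
    return {
        "delivery_id": delivery_id,
        "mother_id": mother_id,
        "state": state,
        "window_start": pd.Timestamp(window_start),
        "window_end": pd.Timestamp(window_end),
        "residential_zip": residential_zip,
        "facility_zip": facility_zip,
        "race_ethnicity": race_ethnicity,
        "case_id": case_id,
    }


def make_newborn(
    infant_id="N1",
    state="ZA",
    date_of_birth="2015-03-01",
    residential_zip="60001",
    facility_zip="60002",
    race_ethnicity="White",
    case_id="H1",
) -> dict:
    return {
        "infant_id": infant_id,
        "state": state,
        "date_of_birth": pd.Timestamp(date_of_birth),
        "residential_zip": residential_zip,
        "facility_zip": facility_zip,
        "race_ethnicity": race_ethnicity,
        "case_id": case_id,
    }


def delivery_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col in ("window_start", "window_end"):
        df[col] = pd.to_datetime(df[col])
    return df


def newborn_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["date_of_birth"] = pd.to_datetime(df["date_of_birth"])
    return df


def claim_row(
    claim_id="C1",
    beneficiary_id="B1",
    state="ZA",
    service_date="2015-03-01",
    codes="ICD10-DX:O80",
    provider_npi=None,
    source_file="inpatient",
    claim_year=None,
) -> dict:
    date = pd.Timestamp(service_date)
    return {
        "claim_id": claim_id,
        "beneficiary_id": beneficiary_id,
        "state": state,
        "service_date": date,
        "codes": codes,
        "provider_npi": provider_npi,
        "source_file": source_file,
        "claim_year": claim_year if claim_year is not None else int(date.year),
    }


def enrollment_row(
    beneficiary_id="B1",
    state="ZA",
    year=2015,
    date_of_birth="1990-01-01",
    enrollment_start="2014-01-01",
    residential_zip="60001",
    race_ethnicity="White",
    case_id="H1",
    sex="F",
) -> dict:
    return {
        "beneficiary_id": beneficiary_id,
        "state": state,
        "year": year,
        "date_of_birth": pd.Timestamp(date_of_birth) if date_of_birth else pd.NaT,
        "enrollment_start": pd.Timestamp(enrollment_start) if enrollment_start else pd.NaT,
        "residential_zip": residential_zip,
        "race_ethnicity": race_ethnicity,
        "case_id": case_id,
        "sex": sex,
    }


def enrollment_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col in ("date_of_birth", "enrollment_start"):
        df[col] = pd.to_datetime(df[col])
    return df


def claims_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["service_date"] = pd.to_datetime(df["service_date"])
    return df
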