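"""Tabular I/O for claims, enrollment, code lists, NPI and NVSS tables.

The pipeline's canonical in-memory containers are pandas DataFrames with the
column schemas defined here.  A claim row carries its diagnosis/procedure
codes as a single ``codes`` string of ``SYSTEM:code`` tokens joined by ``;``
(e.g. ``"ICD10-DX:O80;CPT:59409"``); :func:`explode_codes` unpacks them to a
long table for vectorised code-list lookups.

Source files with different column names (the MAX "Personal Summary" versus
TAF "Demographic Eligibility" naming, for instance) are absorbed by a
*dialect*: a mapping from canonical field names to source column names.
Rows that cannot be parsed are never silently dropped — every reader returns
a :class:`ReadResult` whose ``rejects`` frame accounts for each row-level
drop and field-level clearing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CODE_SYSTEMS = frozenset({"ICD9-DX", "ICD9-PR", "ICD10-DX", "ICD10-PR", "CPT"})
CODE_LIST_ROLES = frozenset({"delivery", "newborn_care", "multiple_gestation"})
RACE_CATEGORIES = (
    "White",
    "Hispanic",
    "Black",
    "Asian",
    "AIAN",
    "Hawaiian/PI",
    "Multiracial",
    "Unknown/Other",
)

CLAIM_COLUMNS = [
    "claim_id",
    "beneficiary_id",
    "state",
    "service_date",
    "codes",
    "provider_npi",
    "source_file",
    "claim_year",
]
ENROLLMENT_COLUMNS = [
    "beneficiary_id",
    "state",
    "year",
    "date_of_birth",
    "enrollment_start",
    "residential_zip",
    "race_ethnicity",
    "case_id",
    "sex",
]


class ConfigurationError(ValueError):
    """Raised for malformed dialects, code lists, or input schemas."""


class ReadResult(NamedTuple):
    """Parsed records plus a reject log.

    ``rejects`` columns: ``row`` (0-based input row), ``field``, ``value``,
    ``reason``, ``action`` (``dropped`` for whole-row rejects,
    ``field_cleared`` when the row is kept with the offending field set to
    missing).  Invariant: input rows == len(records) + (action=="dropped").sum().
    """

    records: pd.DataFrame
    rejects: pd.DataFrame


def _empty_rejects() -> pd.DataFrame:
    return pd.DataFrame(columns=["row", "field", "value", "reason", "action"])


def _reject_frame(entries: list[tuple]) -> pd.DataFrame:
    if not entries:
        return _empty_rejects()
    return pd.DataFrame(entries, columns=["row", "field", "value", "reason", "action"])


def _read_raw(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _apply_dialect(
    df: pd.DataFrame,
    dialect: Mapping[str, str] | None,
    required: Iterable[str],
    optional: Iterable[str],
) -> pd.DataFrame:
    """Rename source columns to canonical names and check presence."""
    if dialect:
        unknown = set(dialect) - set(required) - set(optional)
        if unknown:
            raise ConfigurationError(
                f"dialect maps unknown canonical fields: {sorted(unknown)}"
            )
        rename = {src: canon for canon, src in dialect.items() if src in df.columns}
        missing_src = [src for src in dialect.values() if src not in df.columns]
        if missing_src:
            raise ConfigurationError(
                f"dialect names source columns absent from file: {missing_src}"
            )
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {missing}")
    for col in optional:
        if col not in df.columns:
            df[col] = ""
    return df


def normalize_zip(value: object) -> str | None:
    """Normalise a ZIP to its first five digits; None when not recoverable.

    Nine-digit ZIPs (with or without hyphen) are truncated to the five-digit
    prefix.  Anything that does not start with five digits is invalid.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().replace("-", "")
    if len(text) >= 5 and text[:5].isdigit() and len(text) in (5, 9):
        return text[:5]
    return None


def normalize_npi(value: object) -> str | None:
    """An NPI is exactly ten digits; anything else is treated as missing."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text if len(text) == 10 and text.isdigit() else None


def parse_code_token(token: str) -> tuple[str, str]:
    """Parse ``SYSTEM:code`` into ``(code, system)``; raises on bad system."""
    system, sep, code = token.partition(":")
    if not sep or not code or system not in CODE_SYSTEMS:
        raise ValueError(f"malformed code token {token!r}")
    return code, system


def format_codes(codes: Iterable[tuple[str, str]]) -> str:
    """Inverse of :func:`explode_codes` for a single claim's code set."""
    return ";".join(f"{system}:{code}" for code, system in sorted(codes, key=lambda c: (c[1], c[0])))


def explode_codes(claims: pd.DataFrame) -> pd.DataFrame:
    """Long view of claim codes: one row per (claim_id, code, system)."""
    if claims.empty:
        return pd.DataFrame(columns=["claim_id", "code", "system"])
    tokens = claims.set_index("claim_id")["codes"].str.split(";").explode()
    tokens = tokens[tokens.astype(str).str.len() > 0]
    split = tokens.str.partition(":")
    out = pd.DataFrame(
        {"claim_id": tokens.index, "system": split[0].values, "code": split[2].values}
    )
    return out[["claim_id", "code", "system"]].reset_index(drop=True)


def claims_with_any_code(claims: pd.DataFrame, code_set: set[tuple[str, str]]) -> pd.Series:
    """Boolean mask (aligned to ``claims``) of claims bearing any listed code."""
    if claims.empty or not code_set:
        return pd.Series(False, index=claims.index)
    long = explode_codes(claims)
    hit = long[[(c, s) in code_set for c, s in zip(long["code"], long["system"])]]
    hit_ids = set(hit["claim_id"])
    return claims["claim_id"].isin(hit_ids)


def read_claims(path: str | Path, dialect: Mapping[str, str] | None = None) -> ReadResult:
    """Read a claims file into the canonical claim schema.

    Rows with unparseable service dates or malformed code tokens are dropped
    and logged; invalid NPIs are cleared to missing (row kept).  ``claim_id``
    defaults to the input row number, ``claim_year`` to the service year.
    """
    raw = _read_raw(path)
    raw = _apply_dialect(
        raw,
        dialect,
        required=["beneficiary_id", "state", "service_date", "codes"],
        optional=["provider_npi", "source_file", "claim_year", "claim_id"],
    )
    raw = raw.reset_index(drop=True)
    rejects: list[tuple] = []

    dates = pd.to_datetime(raw["service_date"], errors="coerce", format="mixed")
    bad_date = dates.isna()
    for idx in raw.index[bad_date]:
        rejects.append((idx, "service_date", raw.at[idx, "service_date"], "unparseable date", "dropped"))

    bad_codes = pd.Series(False, index=raw.index)
    for idx, cell in raw["codes"].items():
        if bad_date.at[idx]:
            continue
        tokens = [t for t in str(cell).split(";") if t]
        if not tokens:
            bad_codes.at[idx] = True
            rejects.append((idx, "codes", cell, "no codes on claim", "dropped"))
            continue
        try:
            for token in tokens:
                parse_code_token(token)
        except ValueError as err:
            bad_codes.at[idx] = True
            rejects.append((idx, "codes", cell, str(err), "dropped"))

    keep = ~(bad_date | bad_codes)
    df = raw[keep].copy()
    df["service_date"] = dates[keep]
    df["state"] = df["state"].astype(str).str.strip().str.upper()

    npi = df["provider_npi"].map(normalize_npi)
    for idx in df.index[npi.isna() & (df["provider_npi"].astype(str).str.strip() != "")]:
        rejects.append((idx, "provider_npi", df.at[idx, "provider_npi"], "not a 10-digit NPI", "field_cleared"))
    df["provider_npi"] = npi

    year = pd.to_numeric(df["claim_year"], errors="coerce")
    df["claim_year"] = year.fillna(df["service_date"].dt.year).astype(int)
    df["source_file"] = df["source_file"].replace("", "other_services")
    cid = df["claim_id"].astype(str)
    df["claim_id"] = cid.where(cid.str.len() > 0, df.index.astype(str))

    df = df[CLAIM_COLUMNS].reset_index(drop=True)
    reject_df = _reject_frame(rejects)
    n_dropped = int((reject_df["action"] == "dropped").sum()) if len(reject_df) else 0
    assert len(raw) == len(df) + n_dropped, "reject accounting broke"
    return ReadResult(df, reject_df)


DEFAULT_RACE_MAP: dict[str, str] = {c: c for c in RACE_CATEGORIES}


def read_enrollment(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    race_map: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read an enrollment/demographic file.

    Duplicate (beneficiary_id, state, year) keys are a hard error.  Invalid
    ZIPs, dates, race values and sexes are cleared to missing with a logged
    reason; the row itself is kept.
    """
    race_map = dict(DEFAULT_RACE_MAP if race_map is None else race_map)
    raw = _read_raw(path)
    raw = _apply_dialect(
        raw,
        dialect,
        required=["beneficiary_id", "state", "year"],
        optional=[
            "date_of_birth",
            "enrollment_start",
            "residential_zip",
            "race_ethnicity",
            "case_id",
            "sex",
        ],
    )
    raw = raw.reset_index(drop=True)
    rejects: list[tuple] = []

    df = raw.copy()
    df["state"] = df["state"].astype(str).str.strip().str.upper()
    df["year"] = pd.to_numeric(df["year"], errors="coerce")
    bad_year = df["year"].isna()
    for idx in df.index[bad_year]:
        rejects.append((idx, "year", raw.at[idx, "year"], "unparseable year", "dropped"))
    df = df[~bad_year].copy()
    df["year"] = df["year"].astype(int)

    dup = df.duplicated(subset=["beneficiary_id", "state", "year"], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, ["beneficiary_id", "state", "year"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ConfigurationError(
            "duplicate (beneficiary_id, state, year) enrollment keys: "
            + ", ".join(map(str, keys))
        )

    for col in ("date_of_birth", "enrollment_start"):
        parsed = pd.to_datetime(df[col], errors="coerce", format="mixed")
        had_value = df[col].astype(str).str.strip() != ""
        for idx in df.index[parsed.isna() & had_value]:
            rejects.append((idx, col, df.at[idx, col], "unparseable date", "field_cleared"))
        df[col] = parsed

    zips = df["residential_zip"].map(normalize_zip)
    had_zip = df["residential_zip"].astype(str).str.strip() != ""
    for idx in df.index[zips.isna() & had_zip]:
        rejects.append((idx, "residential_zip", df.at[idx, "residential_zip"], "not a valid 5-digit ZIP", "field_cleared"))
    df["residential_zip"] = zips

    race_src = df["race_ethnicity"].astype(str).str.strip()
    mapped = race_src.map(race_map)
    unmapped = mapped.isna() & (race_src != "")
    for idx in df.index[unmapped]:
        rejects.append((idx, "race_ethnicity", race_src.at[idx], "unmapped race value -> Unknown/Other", "field_cleared"))
        logger.warning("unmapped race/ethnicity value %r mapped to Unknown/Other", race_src.at[idx])
    mapped[unmapped] = "Unknown/Other"
    df["race_ethnicity"] = mapped.where(race_src != "", None)

    sex = df["sex"].astype(str).str.strip().str.upper().str[:1]
    df["sex"] = sex.map({"F": "F", "M": "M"}).fillna("Unknown")
    case = df["case_id"].astype(str).str.strip()
    df["case_id"] = case.where(case != "", None)

    df = df[ENROLLMENT_COLUMNS].reset_index(drop=True)
    reject_df = _reject_frame(rejects)
    n_dropped = int((reject_df["action"] == "dropped").sum()) if len(reject_df) else 0
    assert len(raw) == len(df) + n_dropped
    return ReadResult(df, reject_df)


def read_npi_table(path: str | Path) -> pd.DataFrame:
    """NPPES-style lookup: columns npi, year, zip; (npi, year) unique."""
    df = _read_raw(path)
    missing = [c for c in ("npi", "year", "zip") if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {missing}")
    df = df.copy()
    df["npi"] = df["npi"].map(normalize_npi)
    df["zip"] = df["zip"].map(normalize_zip)
    df["year"] = pd.to_numeric(df["year"], errors="coerce")
    df = df.dropna(subset=["npi", "year", "zip"])
    df["year"] = df["year"].astype(int)
    if df.duplicated(subset=["npi", "year"]).any():
        raise ConfigurationError("duplicate (npi, year) keys in NPI table")
    return df[["npi", "year", "zip"]].reset_index(drop=True)


def read_nvss_counts(path: str | Path) -> pd.DataFrame:
    """State-year counts of Medicaid-payer births: state, year, medicaid_births."""
    df = _read_raw(path)
    missing = [c for c in ("state", "year", "medicaid_births") if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {missing}")
    df = df.copy()
    df["state"] = df["state"].astype(str).str.strip().str.upper()
    df["year"] = pd.to_numeric(df["year"]).astype(int)
    df["medicaid_births"] = pd.to_numeric(df["medicaid_births"]).astype(int)
    if (df["medicaid_births"] < 0).any():
        raise ConfigurationError("medicaid_births must be non-negative")
    if df.duplicated(subset=["state", "year"]).any():
        raise ConfigurationError("duplicate (state, year) keys in NVSS table")
    return df[["state", "year", "medicaid_births"]].reset_index(drop=True)


CodeLists = dict[str, set[tuple[str, str]]]


def load_code_list(path: str | Path) -> CodeLists:
    """Load code lists keyed by role from YAML/JSON (role -> list of
    {code, system}) or CSV (columns role, code, system).

    Unknown roles or code systems are configuration errors; duplicate
    (code, system) entries within a role are deduplicated with a warning.
    """
    path = Path(path)
    if path.suffix in (".yaml", ".yml", ".json"):
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        rows = [
            (role, str(entry["code"]), str(entry["system"]))
            for role, entries in payload.items()
            for entry in entries
        ]
    else:
        df = pd.read_csv(path, dtype=str)
        missing = [c for c in ("role", "code", "system") if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing required column(s): {missing}")
        rows = list(df[["role", "code", "system"]].itertuples(index=False, name=None))

    lists: CodeLists = {}
    for role, code, system in rows:
        if role not in CODE_LIST_ROLES:
            raise ConfigurationError(f"unknown code-list role {role!r}; expected one of {sorted(CODE_LIST_ROLES)}")
        if system not in CODE_SYSTEMS:
            raise ConfigurationError(f"unknown code system {system!r} for code {code!r}")
        if not code:
            raise ConfigurationError(f"empty code in role {role!r}")
        entry = (code, system)
        bucket = lists.setdefault(role, set())
        if entry in bucket:
            logger.warning("duplicate code %s:%s in role %s deduplicated", system, code, role)
        bucket.add(entry)
    return lists


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a stage output as CSV or Parquet by extension (dates as ISO)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def read_table(path: str | Path, date_columns: Iterable[str] = ()) -> pd.DataFrame:
    """Read back a stage output, restoring the named date columns."""
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    for col in date_columns:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], errors="coerce")
    return df


def write_manifest(manifest: Mapping[str, object], path: str | Path) -> None:
    """Persist the run manifest (stage-by-stage row accounting) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(dict(manifest), fh, indent=2, default=str)
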