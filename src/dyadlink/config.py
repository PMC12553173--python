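"""Pipeline configuration: numeric thresholds and the matching phase/step schedule.

Every tunable constant of the linkage procedure lives in :class:`PipelineConfig`
so that a run is fully described by one YAML file.  Defaults encode the
published procedure: deliveries for beneficiaries aged 12–50, delivery
clusters separated by at least 270 days between midpoints, delivery windows
of at most 7 days, newborn-care claims within 7 days of birth, the
enrollment fallback triggered when code-based newborn counts fall below 95%
of NVSS, enrollment up to one day after birth, and household case IDs
invalidated when shared by more than 10 beneficiaries in a state-year.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

MatchVariable = Literal["residential_zip", "facility_zip", "race_ethnicity"]

#: The three demographic variables relaxed across the eight steps of a phase.
MATCH_VARIABLES: tuple[str, ...] = ("residential_zip", "facility_zip", "race_ethnicity")

#: Default eight-step relaxation: all three variables, any two, any one, none.
#: Subsets of equal size are ordered by the variable enumeration order above.
DEFAULT_STEP_SCHEDULE: tuple[tuple[MatchVariable, ...], ...] = (
    ("residential_zip", "facility_zip", "race_ethnicity"),
    ("residential_zip", "facility_zip"),
    ("residential_zip", "race_ethnicity"),
    ("facility_zip", "race_ethnicity"),
    ("residential_zip",),
    ("facility_zip",),
    ("race_ethnicity",),
    (),
)


class PhaseSpec(BaseModel):
    """One phase of the greedy matcher.

    A phase fixes the hard criteria (date tolerance around the delivery
    window, whether a shared case ID is required) and iterates through
    ``step_schedule``, progressively dropping demographic variables from the
    required-agreement set.
    """

    phase_number: int = Field(ge=1)
    date_tolerance: int = Field(ge=0, le=31)
    case_id_required: bool
    step_schedule: tuple[tuple[MatchVariable, ...], ...] = DEFAULT_STEP_SCHEDULE

    @field_validator("step_schedule")
    @classmethod
    def _steps_nonempty(cls, v):
        if len(v) == 0:
            raise ValueError("step_schedule must contain at least one step")
        return tuple(tuple(s) for s in v)


def default_phase_schedule() -> list[PhaseSpec]:
    """Six phases: 1–3 require a shared case ID with date tolerance 0/1/2
    days; 4–6 drop the case-ID requirement entirely, again at 0/1/2 days."""
    phases = []
    number = 1
    for case_id_required in (True, False):
        for tolerance in (0, 1, 2):
            phases.append(
                PhaseSpec(
                    phase_number=number,
                    date_tolerance=tolerance,
                    case_id_required=case_id_required,
                )
            )
            number += 1
    return phases


class PipelineConfig(BaseModel):
    """All numeric thresholds of the identification and linkage pipeline."""

    min_age: int = Field(default=12, ge=0)
    max_age: int = Field(default=50, ge=0)
    min_interdelivery_midpoint_gap: int = Field(default=270, ge=0)
    max_window_span: int = Field(default=7, ge=0)
    #: If True, measure the delivery window as the inclusive day count
    #: (end - start + 1) instead of the default end - start difference.
    window_span_inclusive_count: bool = False
    newborn_claim_lookahead: int = Field(default=7, ge=0)
    enrollment_fallback_coverage_threshold: float = Field(default=0.95, ge=0.0, le=2.0)
    enrollment_dob_slack: int = Field(default=1, ge=0)
    max_case_id_household_size: int = Field(default=10, ge=1)
    #: Case-ID values treated as structurally invalid (cleared before matching).
    case_id_sentinels: tuple[str, ...] = ("", "0", "000000000", "999999999")
    #: Re-check pair uniqueness within a step after each acceptance round
    #: until a fixed point, instead of the default single simultaneous pass.
    iterate_within_step: bool = False
    phase_schedule: list[PhaseSpec] = Field(default_factory=default_phase_schedule)
    random_seed: int = 0

    @field_validator("phase_schedule")
    @classmethod
    def _schedule_nonempty(cls, v):
        if not v:
            raise ValueError("phase_schedule must not be empty")
        return v

    @field_validator("max_age")
    @classmethod
    def _age_order(cls, v, info):
        if "min_age" in info.data and v < info.data["min_age"]:
            raise ValueError("max_age must be >= min_age")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML; missing keys take defaults."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(payload)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
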