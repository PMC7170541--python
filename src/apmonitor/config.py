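"""Configuration models and census-date helpers.

All dates are ISO-8601 calendar dates; intervals throughout the pipeline are
closed on both ends.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Optional

import yaml
from dateutil.relativedelta import relativedelta
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigurationError

ExclusionReason = Literal[
    "none",
    "not_active",
    "no_dementia",
    "no_recent_use",
    "single_reference",
    "stopped",
    "psychosis_ever",
    "other_dx_after_index",
]


def month_starts(first: dt.date, n: int) -> list[dt.date]:
    return [first + relativedelta(months=k) for k in range(n)]


def census_dates(first_month: dt.date, n_censuses: int, day: int = 28) -> list[dt.date]:
    """Monthly census dates on a fixed day of the month (28th by default)."""
    first = first_month.replace(day=1)
    return [d.replace(day=day) for d in month_starts(first, n_censuses)]


def census_range(start_ym: str, end_ym: str, day: int = 28) -> list[dt.date]:
    """Census dates for every month from ``start_ym`` to ``end_ym`` inclusive
    (both ``YYYY-MM`` strings)."""
    start = dt.datetime.strptime(start_ym, "%Y-%m").date()
    end = dt.datetime.strptime(end_ym, "%Y-%m").date()
    if end < start:
        raise ConfigurationError("census range: end month precedes start month")
    n = (end.year - start.year) * 12 + (end.month - start.month) + 1
    return census_dates(start, n, day=day)


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic EHR generator.

    Population parameters default to the published caseload figures: 32.1%
    antipsychotic exposure among dementia patients, 19.0% psychosis
    comorbidity, and a form-completion probability ramping from 0.22 to 0.58
    across 16 monthly censuses.
    """

    n_patients: int = Field(default=660, ge=0)
    start_date: dt.date = dt.date(2017, 1, 1)
    end_date: dt.date = dt.date(2019, 1, 31)
    first_census_month: str = "2017-10"
    n_censuses: int = Field(default=16, ge=1)
    census_day: int = Field(default=28, ge=1, le=28)

    dementia_prevalence: float = Field(default=0.85, ge=0.0, le=1.0)
    antipsychotic_prevalence: float = Field(default=0.321, ge=0.0, le=1.0)
    psychosis_comorbidity: float = Field(default=0.19, ge=0.0, le=1.0)
    other_dx_rate: float = Field(default=0.10, ge=0.0, le=1.0)
    text_only_dx_fraction: float = Field(default=0.3, ge=0.0, le=1.0)

    form_completion_start: float = Field(default=0.22, ge=0.0, le=1.0)
    form_completion_end: float = Field(default=0.58, ge=0.0, le=1.0)

    note_rate: float = Field(default=1.0, ge=0.0)
    mention_noise: float = Field(default=0.08, ge=0.0, le=1.0)
    stop_rate: float = Field(default=0.08, ge=0.0, le=1.0)
    negation_rate: float = Field(default=0.15, ge=0.0, le=1.0)
    inactive_rate: float = Field(default=0.08, ge=0.0, le=1.0)
    second_team_rate: float = Field(default=0.05, ge=0.0, le=1.0)

    exposure_window_days: int = Field(default=183, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_dates(self) -> "GeneratorConfig":
        if self.start_date >= self.end_date:
            raise ValueError("start_date: must precede end_date")
        censuses = self.census_dates()
        if censuses[0] < self.start_date or censuses[-1] > self.end_date:
            raise ValueError(
                "first_census_month/n_censuses: census dates fall outside "
                "[start_date, end_date]"
            )
        return self

    def census_dates(self) -> list[dt.date]:
        first = dt.datetime.strptime(self.first_census_month, "%Y-%m").date()
        return census_dates(first, self.n_censuses, day=self.census_day)

    def completion_probability(self, census_index: int) -> float:
        """Linear interpolation of the form-completion ramp at a census."""
        if self.n_censuses == 1:
            return self.form_completion_start
        t = census_index / (self.n_censuses - 1)
        return self.form_completion_start + t * (
            self.form_completion_end - self.form_completion_start
        )


class CensusSpec(BaseModel):
    """A census date plus every tunable ascertainment parameter."""

    census_date: dt.date
    window_days: int = Field(default=183, gt=0)
    algorithm_version: Literal["v1", "v2"] = "v2"
    sensitivity_mode: bool = False
    form_validity_days: Optional[int] = Field(default=None, gt=0)
    min_references_v2: int = Field(default=2, ge=2)
    rule1_per_drug: bool = False
    setting_specific_validity: bool = False
    inpatient_validity_days: int = Field(default=28, gt=0)

    @property
    def window_start(self) -> dt.date:
        return self.census_date - dt.timedelta(days=self.window_days)

    @property
    def effective_form_validity_days(self) -> int:
        return self.form_validity_days if self.form_validity_days is not None else self.window_days

    def at(self, census_date: dt.date) -> "CensusSpec":
        """The same parameters evaluated at another census date."""
        return self.model_copy(update={"census_date": census_date})


def _wrap_validation_error(exc: ValidationError) -> ConfigurationError:
    fields = ", ".join(
        ".".join(str(p) for p in err["loc"]) or err["msg"] for err in exc.errors()
    )
    return ConfigurationError(f"invalid configuration field(s): {fields}")


def generator_config_from_dict(raw: dict) -> GeneratorConfig:
    try:
        return GeneratorConfig(**raw)
    except ValidationError as exc:
        raise _wrap_validation_error(exc) from exc


def load_generator_config(path) -> GeneratorConfig:
    """Read a flat-key YAML file mirroring :class:`GeneratorConfig` fields."""
    raw = yaml.safe_load(open(path).read()) or {}
    return generator_config_from_dict(raw)
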