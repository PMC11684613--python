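"""Claims data model, study configuration, and calendar utilities.

The pipeline operates on five linked longitudinal claims tables
(patients, dispensings, diagnoses, visits, deaths) held as pandas
DataFrames inside a :class:`ClaimsBundle`.  Every design window and
threshold of the study lives in :class:`StudyConfig` so that the cohort
and persistence machinery contain no hard-coded dates.

Conventions
-----------
* All dates are calendar dates (no times); ISO-8601 strings in CSV.
* Birth is stored at year-month precision (claims convention); age in
  completed years is computed as if born on day 1 of the birth month.
* Day offsets are signed integers relative to the index date, with the
  index date itself being day 0.
* A fiscal year runs April 1 through March 31 and is labelled by the
  calendar year in which it starts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "IntegrityError",
    "SEXES",
    "DRUG_CLASSES",
    "ROUTES",
    "SUBTYPES",
    "ORAL_ASA5_SUBTYPES",
    "CLAIM_TYPES",
    "EPISODE_REASONS",
    "TABLE_COLUMNS",
    "ClaimsBundle",
    "StudyConfig",
    "fiscal_year_of",
    "age_years",
    "age_bin_labels",
    "age_group_of",
    "age_group_of_age",
    "parse_date",
]


class SchemaError(ValueError):
    """A table does not conform to the documented CSV schema."""


class IntegrityError(ValueError):
    """Referential or temporal integrity of a bundle is violated."""


SEXES = ("male", "female")
DRUG_CLASSES = ("ASA5", "SASP", "OTHER")
ROUTES = ("oral", "topical")
ORAL_ASA5_SUBTYPES = ("time_dependent", "ph_dependent", "mmx")
SUBTYPES = ORAL_ASA5_SUBTYPES + ("not_applicable",)
CLAIM_TYPES = ("regular", "dpc")
EPISODE_REASONS = ("gap", "death", "horizon_reached")

#: Canonical column order per table (also the CSV column order).
TABLE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "patients": ("patient_id", "sex", "birth_month", "enrollment_start"),
    "dispensings": (
        "patient_id",
        "date",
        "institution_id",
        "drug_code",
        "drug_class",
        "route",
        "subtype",
        "days_supply",
    ),
    "diagnoses": (
        "patient_id",
        "date",
        "institution_id",
        "disease_code",
        "is_uc",
        "suspected",
        "principal",
        "claim_type",
    ),
    "visits": ("patient_id", "date", "institution_id"),
    "deaths": ("patient_id", "date"),
}


def parse_date(value: str | dt.date) -> dt.date:
    """Parse an ISO-8601 ``YYYY-MM-DD`` string into a date."""
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass
class ClaimsBundle:
    """The five linked event tables plus the database coverage window.

    ``db_start``/``db_end`` bound every event date; ``db_start`` is the
    first date from which prior enrollment can be verified (the claims
    source used here begins accruing on April 1, 2013).
    """

    patients: pd.DataFrame
    dispensings: pd.DataFrame
    diagnoses: pd.DataFrame
    visits: pd.DataFrame
    deaths: pd.DataFrame
    db_start: dt.date = dt.date(2013, 4, 1)
    db_end: dt.date = dt.date(2021, 6, 30)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "patients": self.patients,
            "dispensings": self.dispensings,
            "diagnoses": self.diagnoses,
            "visits": self.visits,
            "deaths": self.deaths,
        }

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def _as_date(value) -> dt.date:
    return parse_date(value)


@dataclass(frozen=True)
class StudyConfig:
    """Every window and threshold of the persistence study design.

    Defaults reproduce the nationwide oral 5-ASA study design: accrual
    April 2015 through September 2019, a symmetric 28-day diagnosis
    window around the index date, a 365-day drug-free washout, prior
    enrollment proven by any visit on or before day -366, a 90-day
    grace period, evaluation days 0/30/90/180/365/500, age cut points
    at 20/40/65 years, and 95% confidence intervals.
    """

    accrual_start: dt.date = dt.date(2015, 4, 1)
    accrual_end: dt.date = dt.date(2019, 9, 30)
    dx_window_days: int = 28
    washout_days: int = 365
    enrollment_lookback_boundary_days: int = 366
    grace_days: int = 90
    horizon_days: int = 500
    evaluation_days: tuple[int, ...] = (0, 30, 90, 180, 365, 500)
    age_bins: tuple[int, ...] = (20, 40, 65)
    ci_level: float = 0.95
    fiscal_year_start_month: int = 4

    def __post_init__(self):
        object.__setattr__(self, "accrual_start", _as_date(self.accrual_start))
        object.__setattr__(self, "accrual_end", _as_date(self.accrual_end))
        object.__setattr__(self, "evaluation_days", tuple(int(d) for d in self.evaluation_days))
        object.__setattr__(self, "age_bins", tuple(int(b) for b in self.age_bins))
        if self.accrual_start >= self.accrual_end:
            raise ValueError("accrual_start must precede accrual_end")
        if self.grace_days <= 0:
            raise ValueError("grace_days must be positive")
        ev = self.evaluation_days
        if not ev or ev[0] != 0 or list(ev) != sorted(ev) or len(set(ev)) != len(ev):
            raise ValueError("evaluation_days must be sorted, unique and start at 0")
        if ev[-1] > self.horizon_days:
            raise ValueError("evaluation_days may not exceed horizon_days")
        if list(self.age_bins) != sorted(set(self.age_bins)):
            raise ValueError("age_bins must be strictly increasing")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if not 1 <= self.fiscal_year_start_month <= 12:
            raise ValueError("fiscal_year_start_month must be a month number")

    def with_grace(self, grace_days: int) -> "StudyConfig":
        return replace(self, grace_days=int(grace_days))

    def to_mapping(self) -> dict:
        return {
            "accrual_start": self.accrual_start.isoformat(),
            "accrual_end": self.accrual_end.isoformat(),
            "dx_window_days": self.dx_window_days,
            "washout_days": self.washout_days,
            "enrollment_lookback_boundary_days": self.enrollment_lookback_boundary_days,
            "grace_days": self.grace_days,
            "horizon_days": self.horizon_days,
            "evaluation_days": list(self.evaluation_days),
            "age_bins": list(self.age_bins),
            "ci_level": self.ci_level,
            "fiscal_year_start_month": self.fiscal_year_start_month,
        }

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown StudyConfig keys: {sorted(unknown)}")
        return cls(**dict(mapping))


def fiscal_year_of(date: dt.date | str, start_month: int = 4) -> int:
    """Fiscal-year label of a date (the calendar year the FY starts in).

    With the default April start, 2016-03-31 belongs to FY2015 and
    2016-04-01 to FY2016.
    """
    d = parse_date(date)
    return d.year if d.month >= start_month else d.year - 1


def age_years(birth_month: str, on_date: dt.date | str) -> int:
    """Age in completed years at ``on_date`` for a ``YYYY-MM`` birth month.

    Born-on-day-1 convention: within the birth month itself the year
    already counts as completed.
    """
    on = parse_date(on_date)
    try:
        by, bm = (int(p) for p in str(birth_month).split("-")[:2])
    except ValueError as exc:
        raise SchemaError(f"unparseable birth_month {birth_month!r}") from exc
    age = on.year - by - (1 if on.month < bm else 0)
    if age < 0:
        raise IntegrityError(f"birth_month {birth_month!r} is after {on.isoformat()}")
    return age


def age_bin_labels(age_bins: Sequence[int]) -> list[str]:
    """Display labels for half-open age bins given interior cut points.

    Cut points ``(20, 40, 65)`` yield ``["<20", "20-39", "40-64", ">64"]``.
    """
    bins = list(age_bins)
    labels = [f"<{bins[0]}"]
    for lo, hi in zip(bins[:-1], bins[1:]):
        labels.append(f"{lo}-{hi - 1}")
    labels.append(f">{bins[-1] - 1}")
    return labels


def age_group_of_age(age: int, age_bins: Sequence[int]) -> str:
    """Map an age in completed years to its half-open bin label."""
    if age < 0:
        raise IntegrityError("age must be non-negative")
    labels = age_bin_labels(age_bins)
    for cut, label in zip(age_bins, labels):
        if age < cut:
            return label
    return labels[-1]


def age_group_of(birth_month: str, on_date: dt.date | str, age_bins: Sequence[int]) -> str:
    """Age-group label at ``on_date`` for a year-month of birth."""
    return age_group_of_age(age_years(birth_month, on_date), age_bins)
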