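"""Core domain types for immunization coverage data quality assessment.

The unit of observation is one country-year-vaccine *coverage record*: the
doses administered (numerator), the estimated target cohort (denominator),
the administrative coverage percentage derived from them, and the country's
official coverage estimate.  Reference demographics (UN population and
child-mortality estimates) provide the external comparison targets, and a
country attributes table carries the classifications and eligibility
switches that decide which checks apply where.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = [
    "Vaccine",
    "CoverageRecord",
    "ReferenceDemographics",
    "CountryAttributes",
    "StudyConfig",
    "SMALL_POPULATION_CUTOFF",
]

#: Countries below this total population (in the last study year) lack UN
#: Population Division birth-cohort estimates and are excluded from checks
#: that compare denominators with external sources.
SMALL_POPULATION_CUTOFF = 90_000


class Vaccine(str, enum.Enum):
    """The four vaccine doses assessed."""

    BCG = "BCG"
    DTP1 = "DTP1"
    DTP3 = "DTP3"
    MCV1 = "MCV1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


@dataclass(frozen=True)
class CoverageRecord:
    """One reported country-year-vaccine observation.

    Missing values are encoded as ``None`` (never 0 — a zero count is a
    legal, if abnormal, report).  Percentages at or above 100 are legal
    inputs; detecting them is the job of the checks.
    """

    country: str
    year: int
    vaccine: Vaccine
    numerator: Optional[int] = None
    denominator: Optional[int] = None
    admin_coverage: Optional[float] = None
    official_coverage: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "vaccine", Vaccine(self.vaccine))
        for name in ("numerator", "denominator"):
            v = getattr(self, name)
            if _is_missing(v):
                object.__setattr__(self, name, None)
            else:
                iv = int(round(float(v)))
                if iv < 0:
                    raise ValueError(
                        f"{name} must be a nonnegative count, got {v!r} "
                        f"({self.country},{self.year},{self.vaccine.value})"
                    )
                object.__setattr__(self, name, iv)
        for name in ("admin_coverage", "official_coverage"):
            v = getattr(self, name)
            if _is_missing(v):
                object.__setattr__(self, name, None)
            else:
                fv = float(v)
                if fv < 0:
                    raise ValueError(
                        f"{name} must be >= 0, got {v!r} "
                        f"({self.country},{self.year},{self.vaccine.value})"
                    )
                object.__setattr__(self, name, fv)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.country, self.year, self.vaccine.value)

    def get(self, data_type: str):
        """Return the value of one of the four data types (or None)."""
        return getattr(self, data_type)


@dataclass(frozen=True)
class ReferenceDemographics:
    """UN reference demographics for one country-year.

    ``live_births`` and ``surviving_infants`` come from the UN Population
    Division; the infant mortality rate (per 1000 live births) and its 90%
    uncertainty interval come from UN-IGME.  Birth-cohort fields may be
    absent for very small countries.
    """

    country: str
    year: int
    live_births: Optional[int] = None
    surviving_infants: Optional[int] = None
    imr_point: Optional[float] = None
    imr_lower90: Optional[float] = None
    imr_upper90: Optional[float] = None
    total_population: Optional[int] = None

    def __post_init__(self):
        for name in ("live_births", "surviving_infants", "total_population"):
            v = getattr(self, name)
            if _is_missing(v):
                object.__setattr__(self, name, None)
            else:
                iv = int(round(float(v)))
                if iv <= 0:
                    raise ValueError(f"{name} must be > 0 when present, got {v!r}")
                object.__setattr__(self, name, iv)
        for name in ("imr_point", "imr_lower90", "imr_upper90"):
            v = getattr(self, name)
            object.__setattr__(self, name, None if _is_missing(v) else float(v))
        if (
            self.live_births is not None
            and self.surviving_infants is not None
            and self.surviving_infants > self.live_births
        ):
            raise ValueError(
                f"surviving_infants > live_births for {self.country} {self.year}"
            )
        if (
            self.imr_point is not None
            and self.imr_lower90 is not None
            and self.imr_upper90 is not None
            and not (self.imr_lower90 <= self.imr_point <= self.imr_upper90)
        ):
            raise ValueError(
                f"IMR point outside its own 90% UI for {self.country} {self.year}"
            )


@dataclass(frozen=True)
class CountryAttributes:
    """Classifications and eligibility switches for one country.

    Year-varying classifications (income group, population quintile, FCS
    status) are mappings year -> value because countries are regrouped
    separately for each year; a year missing from a map makes that
    country-year ineligible for that grouping in models, not an error.
    """

    country: str
    who_region: str
    membership_start_year: int = 1948
    bcg_in_schedule: bool = True
    centralized_system: bool = True
    small_population: bool = False
    gavi_support: bool = False
    coverage_level_stratum: str = ""
    birth_registration_stratum: str = ""
    income_group: Mapping[int, str] = field(default_factory=dict)
    population_quintile: Mapping[int, int] = field(default_factory=dict)
    fcs_status: Mapping[int, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class StudyConfig:
    """Study window, thresholds, and rule-interpretation switches.

    The assessment window is [first_year, last_year]; the lookback year is
    loaded only as the comparison baseline for the first year's
    year-to-year checks and is itself never assessed or flagged.

    Thresholds follow the published rules: relative deviations of >= 10%
    are abnormal, coverage at or above 100% is abnormal, and a
    recalculated administrative coverage must match the reported one
    within ``admin_match_tolerance`` percentage points (reported coverages
    are typically rounded, so exact equality would flag pure rounding).

    ``yoy_coverage_mode`` / ``yoy_count_mode`` select whether the
    year-to-year >=10% rule is applied on the absolute percentage-point
    scale or the relative scale for coverages and counts respectively.
    """

    first_year: int = 2000
    last_year: int = 2019
    lookback_year: int = 1999
    relative_deviation_threshold: float = 0.10
    coverage_cap: float = 100.0
    admin_match_tolerance: float = 0.5
    yoy_coverage_mode: str = "percentage_points"  # or "relative"
    yoy_count_mode: str = "relative"  # or "percentage_points"
    # Flag-rule switches (see flagging module).
    official_outweighs_admin: bool = True
    missing_official_flags: bool = False

    def __post_init__(self):
        if self.first_year > self.last_year:
            raise ValueError("first_year must be <= last_year")
        if self.relative_deviation_threshold <= 0:
            raise ValueError("relative_deviation_threshold must be > 0")
        if self.admin_match_tolerance <= 0:
            raise ValueError("admin_match_tolerance must be > 0")
        if self.yoy_coverage_mode not in ("percentage_points", "relative"):
            raise ValueError(f"bad yoy_coverage_mode {self.yoy_coverage_mode!r}")
        if self.yoy_count_mode not in ("relative", "percentage_points"):
            raise ValueError(f"bad yoy_count_mode {self.yoy_count_mode!r}")

    @property
    def yoy_points_threshold(self) -> float:
        """Percentage-point threshold implied by the relative threshold."""
        return self.relative_deviation_threshold * 100.0

    def with_(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)
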