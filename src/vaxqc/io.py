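"""Readers, validation, and eligibility rules for the three input tables.

All inputs are UTF-8 comma-separated text with a header row:

* coverage table — ``country,year,vaccine,numerator,denominator,
  admin_coverage,official_coverage``, one row per country-year-vaccine;
  empty cells denote missing values (never 0).
* reference table — ``country,year,live_births,surviving_infants,
  imr_point,imr_lower90,imr_upper90,total_population``.
* attributes table — one row per country with classifications; the
  year-varying classifications (income group, population quintile, FCS
  status) are encoded as ``year:value`` pairs separated by ``;``.

Eligibility rules decide which checks apply to which records: countries
without BCG in the routine schedule are excluded from BCG analyses and
from the implied-IMR checks (no live-births proxy); small-population
countries are excluded from comparisons with UN demographic estimates;
countries without a centralized immunization reporting system are
excluded from every analysis involving administrative coverage,
numerators, or denominators; and countries are assessed only from their
WHO membership year onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .checks import CHECKS, checks_for_vaccine
from .records import (
    SMALL_POPULATION_CUTOFF,
    CountryAttributes,
    CoverageRecord,
    ReferenceDemographics,
    StudyConfig,
    Vaccine,
)

__all__ = [
    "Dataset",
    "read_coverage_table",
    "read_reference_table",
    "read_attributes_table",
    "read_study_config",
    "applicable_years",
    "eligible_checks",
]

COVERAGE_COLUMNS = [
    "country", "year", "vaccine",
    "numerator", "denominator", "admin_coverage", "official_coverage",
]
REFERENCE_COLUMNS = [
    "country", "year", "live_births", "surviving_infants",
    "imr_point", "imr_lower90", "imr_upper90", "total_population",
]


class ValidationError(ValueError):
    """An input table violated a structural contract."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _opt(v):
    return None if pd.isna(v) else v


def read_coverage_table(path, config: StudyConfig) -> list[CoverageRecord]:
    """Read and validate a coverage CSV into records.

    Rows outside ``[lookback_year, last_year]`` are rejected, as are
    duplicate (country, year, vaccine) keys, malformed vaccine labels,
    and negative counts.
    """
    df = pd.read_csv(path)
    _require_columns(df, COVERAGE_COLUMNS, path)
    records: list[CoverageRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            vaccine = Vaccine(str(row.vaccine).strip())
        except ValueError as e:
            raise ValidationError(f"{path} row {i}: unknown vaccine {row.vaccine!r}") from e
        year = int(row.year)
        if year < config.lookback_year or year > config.last_year:
            raise ValidationError(
                f"{path} row {i}: year {year} outside "
                f"[{config.lookback_year}, {config.last_year}]"
            )
        key = (str(row.country), year, vaccine.value)
        if key in seen:
            raise ValidationError(f"{path} row {i}: duplicate key {key}")
        seen.add(key)
        try:
            records.append(
                CoverageRecord(
                    country=str(row.country),
                    year=year,
                    vaccine=vaccine,
                    numerator=_opt(row.numerator),
                    denominator=_opt(row.denominator),
                    admin_coverage=_opt(row.admin_coverage),
                    official_coverage=_opt(row.official_coverage),
                )
            )
        except ValueError as e:
            raise ValidationError(f"{path} row {i}: {e}") from e
    return records


def read_reference_table(path) -> list[ReferenceDemographics]:
    df = pd.read_csv(path)
    _require_columns(df, REFERENCE_COLUMNS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                ReferenceDemographics(
                    country=str(row.country),
                    year=int(row.year),
                    live_births=_opt(row.live_births),
                    surviving_infants=_opt(row.surviving_infants),
                    imr_point=_opt(row.imr_point),
                    imr_lower90=_opt(row.imr_lower90),
                    imr_upper90=_opt(row.imr_upper90),
                    total_population=_opt(row.total_population),
                )
            )
        except ValueError as e:
            raise ValidationError(f"{path} row {i}: {e}") from e
    return out


def _parse_year_map(cell, cast=str) -> dict:
    """Parse '2000:LIC;2001:LMIC' cells into {year: value} maps."""
    if cell is None or pd.isna(cell) or str(cell).strip() == "":
        return {}
    out = {}
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        y, v = part.split(":", 1)
        out[int(y)] = cast(v)
    return out


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise ValidationError(f"cannot parse boolean {v!r}")


def read_attributes_table(path) -> dict[str, CountryAttributes]:
    df = pd.read_csv(path)
    _require_columns(df, ["country", "who_region"], path)
    out: dict[str, CountryAttributes] = {}
    for row in df.itertuples(index=False):
        country = str(row.country)
        g = lambda name, default: getattr(row, name, default)
        pop_2019 = g("total_population_last_year", None)
        small = (
            _parse_bool(g("small_population", False))
            if hasattr(row, "small_population")
            else (pop_2019 is not None and pop_2019 < SMALL_POPULATION_CUTOFF)
        )
        out[country] = CountryAttributes(
            country=country,
            who_region=str(row.who_region),
            membership_start_year=int(g("membership_start_year", 1948)),
            bcg_in_schedule=_parse_bool(g("bcg_in_schedule", True)),
            centralized_system=_parse_bool(g("centralized_system", True)),
            small_population=small,
            gavi_support=_parse_bool(g("gavi_support", False)),
            coverage_level_stratum=str(g("coverage_level_stratum", "")),
            birth_registration_stratum=str(g("birth_registration_stratum", "")),
            income_group=_parse_year_map(g("income_group", None)),
            population_quintile=_parse_year_map(g("population_quintile", None), int),
            fcs_status=_parse_year_map(g("fcs_status", None), _parse_bool),
        )
    return out


def read_study_config(path=None, **overrides) -> StudyConfig:
    """Load a StudyConfig from a YAML file, with keyword overrides."""
    data = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return StudyConfig(**data)


# ---------------------------------------------------------------------------
# Eligibility


def applicable_years(attrs: CountryAttributes, config: StudyConfig) -> set[int]:
    """Assessed years for a country: from WHO membership (or the study
    start, whichever is later) through the last study year.  The lookback
    year enters only as comparison context and is never assessed."""
    start = max(config.first_year, attrs.membership_start_year)
    return set(range(start, config.last_year + 1))


def eligible_checks(
    record_or_vaccine: CoverageRecord | Vaccine | str,
    attrs: CountryAttributes,
) -> set[str]:
    """Check ids applicable to a record, given its country's attributes.

    Deterministic in (vaccine, attributes) only.  A BCG record for a
    country without BCG in the schedule yields the empty set (the record
    is excluded from assessment altogether).
    """
    vaccine = (
        record_or_vaccine.vaccine
        if isinstance(record_or_vaccine, CoverageRecord)
        else Vaccine(record_or_vaccine)
    )
    if vaccine is Vaccine.BCG and not attrs.bcg_in_schedule:
        return set()
    out = checks_for_vaccine(vaccine)
    if not attrs.bcg_in_schedule:
        # No BCG denominator exists to serve as the live-births proxy.
        out -= {"congruence.iimr_zero_neg", "congruence.iimr_vs_ui"}
    if attrs.small_population:
        out -= {"congruence.denom_vs_unpd", "congruence.iimr_vs_ui"}
    if not attrs.centralized_system:
        out = {cid for cid in out if CHECKS[cid].data_type == "official_coverage"}
    return out


# ---------------------------------------------------------------------------
# Dataset container


@dataclass
class Dataset:
    """Indexed bundle of the three input tables plus the study config."""

    records: dict[tuple[str, int, str], CoverageRecord]
    reference: dict[tuple[str, int], ReferenceDemographics]
    attributes: dict[str, CountryAttributes]
    config: StudyConfig = field(default_factory=StudyConfig)

    @classmethod
    def from_frames(cls, records, reference, attributes, config=None) -> "Dataset":
        config = config or StudyConfig()
        rec_index = {}
        for r in records:
            if r.key in rec_index:
                raise ValidationError(f"duplicate coverage key {r.key}")
            rec_index[r.key] = r
        ref_index = {(r.country, r.year): r for r in reference}
        attrs = dict(attributes)
        missing = {r.country for r in rec_index.values()} - set(attrs)
        if missing:
            raise ValidationError(f"countries without attributes: {sorted(missing)}")
        return cls(rec_index, ref_index, attrs, config)

    @classmethod
    def read(cls, coverage_path, reference_path, attributes_path, config=None) -> "Dataset":
        config = config or StudyConfig()
        return cls.from_frames(
            read_coverage_table(coverage_path, config),
            read_reference_table(reference_path),
            read_attributes_table(attributes_path),
            config,
        )

    def record(self, country: str, year: int, vaccine) -> Optional[CoverageRecord]:
        return self.records.get((country, year, Vaccine(vaccine).value))

    def ref(self, country: str, year: int) -> Optional[ReferenceDemographics]:
        return self.reference.get((country, year))

    def attrs(self, country: str) -> CountryAttributes:
        try:
            return self.attributes[country]
        except KeyError:
            raise ValidationError(f"no attributes for country {country!r}") from None

    def countries(self) -> list[str]:
        return sorted({c for (c, _, _) in self.records} | set(self.attributes))

    def assessed_units(self):
        """Yield every (country, year, vaccine) unit that is assessed."""
        cfg = self.config
        for country in sorted(self.attributes):
            attrs = self.attributes[country]
            vaccines = [v for v in Vaccine if v is not Vaccine.BCG or attrs.bcg_in_schedule]
            for year in sorted(applicable_years(attrs, cfg)):
                for v in vaccines:
                    yield country, year, v
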