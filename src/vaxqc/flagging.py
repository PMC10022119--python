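"""Coverage-report assembly, flag decisions, and summary tables.

All information a country reports for one vaccine dose in one year is
summarized as one *coverage report*, the unit of flagging.  A report is
flagged when at least one quality check on its underlying data fails,
with one deliberate exception: countries reporting both administrative
and official figures are not disadvantaged by anomalies confined to the
administrative side — official data that passes every check *outweighs*
administrative anomalies and the report stays unflagged.

Two borderline situations are decided here (both switchable in
:class:`~vaxqc.records.StudyConfig`):

* a report with passing administrative data but no official figure is
  **not** flagged for the missing official value alone;
* a report with no assessed data at all is flagged (basis
  ``missing_data``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .checks import (
    CHECKS,
    CheckResult,
    check_completeness,
    check_coverage_cap,
    check_denominator_vs_reference,
    check_dropout,
    check_iimr,
    check_integrity,
    check_repeat_previous_year,
    check_year_to_year,
)
from .io import Dataset, applicable_years, eligible_checks
from .records import CoverageRecord, StudyConfig, Vaccine

__all__ = [
    "CoverageReport",
    "assemble_report",
    "flag_report",
    "assess_dataset",
    "summarize_checks",
    "flag_table",
    "results_table",
]

ADMIN_TYPES = ("numerator", "denominator", "admin_coverage")


@dataclass
class CoverageReport:
    """All check results for one country-year-vaccine, plus the flag."""

    country: str
    year: int
    vaccine: Vaccine
    admin_results: list[CheckResult] = field(default_factory=list)
    official_results: list[CheckResult] = field(default_factory=list)
    flagged: Optional[bool] = None
    flag_basis: str = "none"
    notes: str = ""

    @property
    def results(self) -> list[CheckResult]:
        return self.admin_results + self.official_results

    def fails(self) -> list[CheckResult]:
        return [r for r in self.results if r.status == "fail"]


def assemble_report(
    dataset: Dataset, country: str, year: int, vaccine: Vaccine | str
) -> Optional[CoverageReport]:
    """Run every eligible check for one country-year-vaccine.

    Pulls the preceding-year record for the repeat and year-to-year
    checks, the same-year BCG record for the implied-IMR checks, and the
    same-year DTP1 record for the dropout checks.  Returns ``None`` for a
    unit that is excluded altogether (BCG for a country without a BCG
    birth dose, or a year before WHO membership).
    """
    vaccine = Vaccine(vaccine)
    attrs = dataset.attrs(country)
    cfg = dataset.config
    if year not in applicable_years(attrs, cfg):
        return None
    eligible = eligible_checks(vaccine, attrs)
    if not eligible:
        return None

    record = dataset.record(country, year, vaccine) or CoverageRecord(
        country=country, year=year, vaccine=vaccine
    )
    previous = dataset.record(country, year - 1, vaccine)
    results: list[CheckResult] = []

    results += check_completeness(record, eligible)
    if "congruence.denom_vs_unpd" in eligible:
        results.append(
            check_denominator_vs_reference(
                record, dataset.ref(country, year), cfg.relative_deviation_threshold
            )
        )
    if "congruence.iimr_zero_neg" in eligible:
        bcg = dataset.record(country, year, Vaccine.BCG)
        iimr_results = check_iimr(
            bcg.denominator if bcg else None,
            record.denominator,
            dataset.ref(country, year),
            vaccine,
            small_population=attrs.small_population,
        )
        results += [r for r in iimr_results if r.check_id in eligible]
    if "consistency.repeat_numerator" in eligible:
        results += check_repeat_previous_year(record, previous)
    cap_results = check_coverage_cap(record, cfg.coverage_cap)
    results += [r for r in cap_results if r.check_id in eligible]
    yoy_results = check_year_to_year(record, previous, cfg)
    results += [r for r in yoy_results if r.check_id in eligible]
    if vaccine is Vaccine.DTP3:
        dtp1 = dataset.record(country, year, Vaccine.DTP1)
        dropout_results = check_dropout(dtp1, record)
        results += [r for r in dropout_results if r.check_id in eligible]
    if "integrity.recalc_match" in eligible:
        results += check_integrity(record, cfg.admin_match_tolerance)

    report = CoverageReport(country=country, year=year, vaccine=vaccine)
    for r in results:
        if CHECKS[r.check_id].data_type == "official_coverage":
            report.official_results.append(r)
        else:
            report.admin_results.append(r)
    return flag_report(report, record, cfg)


def flag_report(
    report: CoverageReport,
    record: Optional[CoverageRecord] = None,
    config: Optional[StudyConfig] = None,
) -> CoverageReport:
    """Apply the flag decision rule to an assembled report.

    Let A = any failing admin-stream check, O_present = an official
    coverage value was reported, O_pass = O_present and no failing
    official-stream check.  Then, with the default switches::

        flagged = not O_pass and (A or substantive official fail
                                    or nothing reported)

    A missing official value by itself (``completeness.official_coverage``)
    never flags a report whose administrative data passes; set
    ``missing_official_flags`` to change that.  Set
    ``official_outweighs_admin`` to False to disable the outweigh rule.
    """
    config = config or StudyConfig()

    eligible_types = {CHECKS[r.check_id].data_type for r in report.results}
    if record is not None:
        any_data = any(record.get(dt) is not None for dt in eligible_types)
        o_present = (
            "official_coverage" in eligible_types
            and record.official_coverage is not None
        )
    else:  # infer from completeness results when the record is unavailable
        comp = {
            r.check_id: r.status
            for r in report.results
            if r.check_id.startswith("completeness.")
        }
        any_data = any(s == "pass" for s in comp.values())
        o_present = comp.get("completeness.official_coverage") == "pass"

    admin_fail = any(r.status == "fail" for r in report.admin_results)
    official_sub_fail = any(
        r.status == "fail"
        and r.check_id != "completeness.official_coverage"
        for r in report.official_results
    )
    official_missing = (
        "official_coverage" in eligible_types and not o_present
    )
    o_pass = o_present and not official_sub_fail

    official_anomaly = official_sub_fail or (
        config.missing_official_flags and official_missing and any_data
    )

    if not any_data:
        report.flagged = True
        report.flag_basis = "missing_data"
    elif config.official_outweighs_admin and o_pass:
        report.flagged = False
        report.flag_basis = "none"
        if admin_fail:
            report.notes = "admin anomalies outweighed by passing official data"
    else:
        report.flagged = bool(admin_fail or official_anomaly)
        if admin_fail and official_anomaly:
            report.flag_basis = "both"
        elif admin_fail:
            report.flag_basis = "admin_anomaly"
        elif official_anomaly:
            report.flag_basis = "official_anomaly"
        else:
            report.flag_basis = "none"
    return report


def assess_dataset(dataset: Dataset) -> list[CoverageReport]:
    """Assemble and flag a report for every assessed unit in the dataset."""
    reports = []
    for country, year, vaccine in dataset.assessed_units():
        rep = assemble_report(dataset, country, year, vaccine)
        if rep is not None:
            reports.append(rep)
    return reports


# ---------------------------------------------------------------------------
# Output tables


def results_table(reports: Iterable[CoverageReport]) -> pd.DataFrame:
    """Long-format table of every check result."""
    rows = []
    for rep in reports:
        for r in rep.results:
            rows.append(
                dict(
                    country=rep.country,
                    year=rep.year,
                    vaccine=rep.vaccine.value,
                    check_id=r.check_id,
                    dimension=r.dimension,
                    data_type=r.data_type,
                    status=r.status,
                    detail=r.detail,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "country", "year", "vaccine", "check_id",
            "dimension", "data_type", "status", "detail",
        ],
    )


def summarize_checks(reports: Iterable[CoverageReport]) -> pd.DataFrame:
    """Tally data points and countries affected, per check and rolled up.

    One row per check id (data points failing / data points checked,
    countries with at least one fail / countries checked) plus one rollup
    row per data type and a grand total: a data point of a given type is
    *affected* when any check implicating that type fails for its unit.
    """
    res = results_table(reports)
    rows = []
    if len(res):
        checked = res[res.status.isin(["pass", "fail"])]
        for cid, grp in checked.groupby("check_id", sort=True):
            fails = grp[grp.status == "fail"]
            rows.append(
                dict(
                    row_type="check",
                    check_id=cid,
                    dimension=CHECKS[cid].dimension,
                    data_type=CHECKS[cid].data_type,
                    points_affected=len(fails),
                    points_checked=len(grp),
                    countries_affected=fails.country.nunique(),
                    countries_checked=grp.country.nunique(),
                )
            )
    # Rollup per data type: a data point is the (country, year, vaccine,
    # data_type) cell; it exists wherever any check attributed to that
    # type was eligible (completeness checks make that exhaustive).
    unit_cols = ["country", "year", "vaccine"]
    for dt in ("numerator", "denominator", "admin_coverage", "official_coverage", "total"):
        if dt == "total":
            sub = res
        else:
            affecting = [cid for cid, d in CHECKS.items() if dt in d.affects]
            sub = res[res.check_id.isin(affecting)]
        if not len(sub):
            continue
        expected = sub.drop_duplicates(unit_cols) if dt == "total" else sub[
            sub.check_id == f"completeness.{dt}"
        ]
        failing = sub[sub.status == "fail"]
        if dt == "total":
            # count each (unit, data type) cell once
            cells = res[res.status.isin(["pass", "fail", "not_applicable"])].copy()
            cells["dt"] = cells.check_id.map(lambda c: CHECKS[c].data_type)
            comp = cells[cells.check_id.str.startswith("completeness.")]
            n_points = len(comp)
            aff_cells = set()
            for _, r in failing.iterrows():
                for a in CHECKS[r.check_id].affects:
                    aff_cells.add((r.country, r.year, r.vaccine, a))
            n_affected = len(aff_cells)
            countries_checked = res.country.nunique()
            countries_affected = failing.country.nunique()
        else:
            n_points = len(expected)
            aff = failing.drop_duplicates(unit_cols)
            n_affected = failing.drop_duplicates(unit_cols).shape[0]
            countries_checked = expected.country.nunique()
            countries_affected = aff.country.nunique()
        rows.append(
            dict(
                row_type="rollup",
                check_id=f"any.{dt}",
                dimension="all",
                data_type=dt,
                points_affected=n_affected,
                points_checked=n_points,
                countries_affected=countries_affected,
                countries_checked=countries_checked,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "row_type", "check_id", "dimension", "data_type",
            "points_affected", "points_checked",
            "countries_affected", "countries_checked",
        ],
    )
    if len(df):
        df["pct_affected"] = (
            100.0 * df.points_affected / df.points_checked.where(df.points_checked > 0)
        ).round(1)
    return df


def flag_table(reports: Iterable[CoverageReport]) -> pd.DataFrame:
    """Long-format flag panel, one row per assessed report."""
    rows = [
        dict(
            country=rep.country,
            year=rep.year,
            vaccine=rep.vaccine.value,
            flagged=int(bool(rep.flagged)),
            flag_basis=rep.flag_basis,
        )
        for rep in reports
    ]
    return pd.DataFrame(
        rows, columns=["country", "year", "vaccine", "flagged", "flag_basis"]
    )
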