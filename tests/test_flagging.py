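"""Report assembly, the flag rule, and summary tables."""

import pandas as pd
import pytest

from vaxqc import (
    GeneratorConfig,
    StudyConfig,
    Vaccine,
    assemble_report,
    assess_dataset,
    flag_report,
    flag_table,
    generate_dataset,
    summarize_checks,
)
from vaxqc.checks import CheckResult
from vaxqc.flagging import CoverageReport
from vaxqc.io import Dataset
from vaxqc.records import CountryAttributes, CoverageRecord, ReferenceDemographics


def _res(cid, status, data_type=None):
    from vaxqc.checks import CHECKS

    d = CHECKS[cid]
    return CheckResult(cid, d.dimension, d.data_type, status, "x" if status == "fail" else "")


def make_report(admin, official):
    return CoverageReport("AAA", 2005, Vaccine.DTP3, admin_results=admin, official_results=official)


def test_official_pass_outweighs_admin_anomalies():
    rep = make_report(
        [_res("consistency.cap_admin", "fail")],
        [_res("completeness.official_coverage", "pass"), _res("consistency.cap_official", "pass")],
    )
    rec = CoverageRecord("AAA", 2005, "DTP3", 120, 100, 120.0, 92.0)
    rep = flag_report(rep, rec)
    assert rep.flagged is False and "outweighed" in rep.notes


def test_official_cap_failure_flags_even_with_clean_admin():
    rep = make_report(
        [_res("integrity.recalc_match", "pass")],
        [_res("completeness.official_coverage", "pass"), _res("consistency.cap_official", "fail")],
    )
    rec = CoverageRecord("AAA", 2005, "DTP3", 90, 100, 90.0, 100.0)
    rep = flag_report(rep, rec)
    assert rep.flagged is True and rep.flag_basis == "official_anomaly"


def test_nothing_reported_flags_as_missing_data():
    rep = make_report(
        [_res("completeness.numerator", "fail"), _res("completeness.denominator", "fail"),
         _res("completeness.admin_coverage", "fail")],
        [_res("completeness.official_coverage", "fail")],
    )
    rec = CoverageRecord("AAA", 2005, "DTP3")
    rep = flag_report(rep, rec)
    assert rep.flagged is True and rep.flag_basis == "missing_data"


def test_missing_official_alone_does_not_flag_passing_admin():
    rep = make_report(
        [_res("completeness.numerator", "pass"), _res("integrity.recalc_match", "pass")],
        [_res("completeness.official_coverage", "fail")],
    )
    rec = CoverageRecord("AAA", 2005, "DTP3", 90, 100, 90.0, None)
    rep = flag_report(rep, rec)
    assert rep.flagged is False


def test_missing_official_flag_switch():
    cfg = StudyConfig(missing_official_flags=True)
    rep = make_report(
        [_res("completeness.numerator", "pass")],
        [_res("completeness.official_coverage", "fail")],
    )
    rec = CoverageRecord("AAA", 2005, "DTP3", 90, 100, 90.0, None)
    assert flag_report(rep, rec, cfg).flagged is True


def test_outweigh_rule_switchable():
    cfg = StudyConfig(official_outweighs_admin=False)
    rep = make_report(
        [_res("consistency.cap_admin", "fail")],
        [_res("completeness.official_coverage", "pass"), _res("consistency.cap_official", "pass")],
    )
    rec = CoverageRecord("AAA", 2005, "DTP3", 120, 100, 120.0, 92.0)
    assert flag_report(rep, rec, cfg).flagged is True


def test_flag_monotonicity_within_rule():
    """Adding a failing official check can only remove O_pass; adding a
    failing admin check to a report protected by passing official data
    never flips it to flagged."""
    rec = CoverageRecord("AAA", 2005, "DTP3", 120, 100, 120.0, 92.0)
    protected = make_report(
        [_res("consistency.cap_admin", "fail")],
        [_res("completeness.official_coverage", "pass"), _res("consistency.cap_official", "pass")],
    )
    protected = flag_report(protected, rec)
    assert protected.flagged is False
    more_admin = make_report(
        [_res("consistency.cap_admin", "fail"), _res("integrity.recalc_match", "fail")],
        [_res("completeness.official_coverage", "pass"), _res("consistency.cap_official", "pass")],
    )
    assert flag_report(more_admin, rec).flagged is False
    with_official_fail = make_report(
        [_res("consistency.cap_admin", "fail")],
        [_res("completeness.official_coverage", "pass"), _res("consistency.cap_official", "fail")],
    )
    assert flag_report(with_official_fail, rec).flagged is True


# ---------------------------------------------------------------------------
# assembly on small constructed datasets


def small_dataset(attrs_kw=None, records=(), years=(2000, 2019)):
    attrs = CountryAttributes(country="AAA", who_region="AFR", **(attrs_kw or {}))
    ref = [
        ReferenceDemographics(
            "AAA", y, live_births=100_000, surviving_infants=96_000,
            imr_point=40.0, imr_lower90=36.0, imr_upper90=44.0, total_population=4_000_000,
        )
        for y in range(1999, 2020)
    ]
    cfg = StudyConfig(first_year=years[0], last_year=years[1])
    return Dataset.from_frames(list(records), ref, {"AAA": attrs}, cfg)


def test_assemble_clean_record_unflagged():
    recs = [
        CoverageRecord("AAA", 2005, "BCG", 99_000, 100_500, 98.5, 98.3),
        CoverageRecord("AAA", 2005, "DTP3", 88_000, 96_500, 91.2, 91.0),
        CoverageRecord("AAA", 2005, "DTP1", 92_000, 96_400, 95.4, 95.2),
    ]
    ds = small_dataset(records=recs)
    rep = assemble_report(ds, "AAA", 2005, "DTP3")
    assert rep.flagged is False
    assert not rep.fails()


def test_assemble_non_centralized_has_empty_admin_stream():
    ds = small_dataset(
        attrs_kw=dict(centralized_system=False),
        records=[CoverageRecord("AAA", 2005, "DTP3", None, None, None, 93.0)],
    )
    rep = assemble_report(ds, "AAA", 2005, "DTP3")
    assert rep.admin_results == []
    assert rep.flagged is False


def test_assemble_bcg_excluded_without_schedule():
    ds = small_dataset(attrs_kw=dict(bcg_in_schedule=False))
    assert assemble_report(ds, "AAA", 2005, "BCG") is None


def test_assemble_before_membership_returns_none():
    ds = small_dataset(attrs_kw=dict(membership_start_year=2011))
    assert assemble_report(ds, "AAA", 2005, "DTP3") is None
    assert assemble_report(ds, "AAA", 2011, "DTP3") is not None


def test_lookback_year_never_assessed():
    ds = small_dataset(records=[CoverageRecord("AAA", 1999, "DTP3", 1, 2, 50.0, 50.0)])
    assert assemble_report(ds, "AAA", 1999, "DTP3") is None


def test_eligible_results_cover_each_check_exactly_once():
    recs = [
        CoverageRecord("AAA", 2005, "BCG", 99_000, 100_500, 98.5, 98.3),
        CoverageRecord("AAA", 2005, "DTP3", 88_000, 96_500, 91.2, 91.0),
    ]
    ds = small_dataset(records=recs)
    rep = assemble_report(ds, "AAA", 2005, "DTP3")
    from vaxqc.io import eligible_checks

    ids = [r.check_id for r in rep.results]
    assert sorted(ids) == sorted(eligible_checks("DTP3", ds.attrs("AAA")))


# ---------------------------------------------------------------------------
# tables


def test_flag_table_row_algebra():
    cfg = GeneratorConfig(seed=5, n_countries=10, anomaly_rates={}, frac_no_bcg=0.1,
                          frac_small_pop=0.0, frac_non_centralized=0.0)
    ds, _ = generate_dataset(cfg)
    reports = assess_dataset(ds)
    ft = flag_table(reports)
    expected = 0
    from vaxqc.io import applicable_years

    for c, a in ds.attributes.items():
        n_vacc = 4 if a.bcg_in_schedule else 3
        expected += len(applicable_years(a, ds.config)) * n_vacc
    assert len(ft) == expected == len(reports)
    assert set(ft.columns) == {"country", "year", "vaccine", "flagged", "flag_basis"}


def test_summarize_planted_counts():
    base = dict(numerator=88_000, denominator=96_500, admin_coverage=91.2)
    recs = []
    for y in range(2000, 2010):
        official = 100.5 if y in (2003, 2004, 2005) else 91.0
        recs.append(CoverageRecord("AAA", y, "MCV1", official_coverage=official, **base))
        base = dict(numerator=base["numerator"] + 500, denominator=base["denominator"] + 500,
                    admin_coverage=round((base["numerator"] + 500) / (base["denominator"] + 500) * 100, 1))
    ds = small_dataset(records=recs, years=(2000, 2009))
    reports = [assemble_report(ds, "AAA", y, "MCV1") for y in range(2000, 2010)]
    summary = summarize_checks(reports)
    row = summary[summary.check_id == "consistency.cap_official"].iloc[0]
    assert (row.points_affected, row.points_checked) == (3, 10)
    assert (row.countries_affected, row.countries_checked) == (1, 1)


def test_summarize_clean_dataset_all_zero(clean_dataset):
    reports = assess_dataset(clean_dataset)
    summary = summarize_checks(reports)
    assert (summary.points_affected == 0).all()
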