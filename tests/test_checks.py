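"""Unit and property tests for the quality-check battery."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaxqc.checks import (
    check_completeness,
    check_coverage_cap,
    check_denominator_vs_reference,
    check_dropout,
    check_iimr,
    check_integrity,
    check_repeat_previous_year,
    check_year_to_year,
    checks_for_vaccine,
    dropout_rate,
    implied_imr,
    recalc_admin_coverage,
)
from vaxqc.records import CoverageRecord, ReferenceDemographics, StudyConfig, Vaccine


def rec(vaccine="DTP3", country="AAA", year=2005, **kw):
    return CoverageRecord(country=country, year=year, vaccine=vaccine, **kw)


def ref(**kw):
    base = dict(
        country="AAA", year=2005, live_births=100_000, surviving_infants=95_000,
        imr_point=50.0, imr_lower90=40.0, imr_upper90=60.0, total_population=4_000_000,
    )
    base.update(kw)
    return ReferenceDemographics(**base)


def status_of(results, cid):
    return {r.check_id: r.status for r in results}[cid]


# ---------------------------------------------------------------------------
# elementary formulas


@pytest.mark.parametrize(
    "births,surv,expected",
    [(100_000, 95_000, 0.05), (100_000, 100_000, 0.0), (100_000, 105_000, -0.05)],
)
def test_implied_imr_formula(births, surv, expected):
    assert implied_imr(births, surv) == pytest.approx(expected)


@pytest.mark.parametrize(
    "d1,d3,expected", [(100, 90, 10.0), (100, 100, 0.0), (100, 110, -10.0)]
)
def test_dropout_rate_formula(d1, d3, expected):
    assert dropout_rate(d1, d3) == pytest.approx(expected)


@pytest.mark.parametrize(
    "n,d,expected", [(90, 100, 90.0), (100, 100, 100.0), (101, 100, 101.0)]
)
def test_recalc_admin_coverage_formula(n, d, expected):
    assert recalc_admin_coverage(n, d) == pytest.approx(expected)


def test_formula_guards():
    with pytest.raises(ValueError):
        implied_imr(0, 100)
    with pytest.raises(ValueError):
        dropout_rate(0, 10)
    with pytest.raises(ValueError):
        recalc_admin_coverage(10, 0)


@settings(derandomize=True, max_examples=200)
@given(a=st.integers(min_value=1, max_value=10**8))
def test_identities_at_equal_inputs(a):
    assert implied_imr(a, a) == 0.0
    assert dropout_rate(a, a) == 0.0
    assert math.isclose(recalc_admin_coverage(a, a), 100.0)


@settings(derandomize=True, max_examples=200)
@given(
    n=st.integers(min_value=0, max_value=10**7),
    d=st.integers(min_value=1, max_value=10**7),
)
def test_recalc_roundtrip_identity(n, d):
    assert recalc_admin_coverage(n, d) * d / 100.0 == pytest.approx(n)


# ---------------------------------------------------------------------------
# completeness


def test_completeness_all_present():
    r = rec(numerator=90, denominator=100, admin_coverage=90.0, official_coverage=92.0)
    results = check_completeness(r, checks_for_vaccine("DTP3"))
    assert len(results) == 4 and all(x.status == "pass" for x in results)


def test_completeness_single_missing_field():
    r = rec(denominator=100, admin_coverage=90.0, official_coverage=92.0)
    results = check_completeness(r, checks_for_vaccine("DTP3"))
    by = {x.check_id: x.status for x in results}
    assert by["completeness.numerator"] == "fail"
    assert all(v == "pass" for k, v in by.items() if k != "completeness.numerator")


def test_completeness_restricted_to_eligible_set():
    r = rec(official_coverage=92.0)
    results = check_completeness(r, {"completeness.official_coverage"})
    assert [x.check_id for x in results] == ["completeness.official_coverage"]
    assert results[0].status == "pass"


# ---------------------------------------------------------------------------
# congruence


def test_denominator_deviation_boundary_inclusive():
    r = rec(vaccine="BCG", denominator=110_000)
    assert check_denominator_vs_reference(r, ref(), 0.10).status == "fail"


def test_denominator_below_threshold_passes():
    r = rec(vaccine="DTP3", denominator=95_000)
    assert check_denominator_vs_reference(r, ref(surviving_infants=100_000), 0.10).status == "pass"


def test_denominator_missing_not_applicable():
    assert check_denominator_vs_reference(rec(), ref(), 0.10).status == "not_applicable"


def test_denominator_target_selection_by_vaccine():
    # live births for the birth dose, surviving infants otherwise
    r_bcg = rec(vaccine="BCG", denominator=100_000)
    r_dtp = rec(vaccine="DTP3", denominator=100_000)
    assert check_denominator_vs_reference(r_bcg, ref(), 0.10).status == "pass"
    assert check_denominator_vs_reference(r_dtp, ref(surviving_infants=90_000), 0.10).status == "fail"


def test_iimr_inside_interval_passes():
    results = check_iimr(100_000, 95_000, ref(), "DTP3")
    assert status_of(results, "congruence.iimr_zero_neg") == "pass"
    assert status_of(results, "congruence.iimr_vs_ui") == "pass"


def test_iimr_zero_is_abnormal():
    results = check_iimr(100_000, 100_000, ref(), "DTP3")
    assert status_of(results, "congruence.iimr_zero_neg") == "fail"


def test_iimr_below_interval_fails():
    results = check_iimr(100_000, 99_500, ref(), "DTP3")  # 5 per 1000 < 40
    assert status_of(results, "congruence.iimr_vs_ui") == "fail"


def test_iimr_missing_bcg_denominator():
    results = check_iimr(None, 95_000, ref(), "MCV1")
    assert all(r.status == "not_applicable" for r in results)


def test_iimr_small_population_skips_interval_check():
    results = check_iimr(100_000, 95_000, ref(), "DTP1", small_population=True)
    assert status_of(results, "congruence.iimr_zero_neg") == "pass"
    assert status_of(results, "congruence.iimr_vs_ui") == "not_applicable"


# ---------------------------------------------------------------------------
# consistency


def test_repeat_exact_value_fails():
    prev = rec(year=2004, numerator=84_213)
    cur = rec(year=2005, numerator=84_213)
    assert status_of(check_repeat_previous_year(cur, prev), "consistency.repeat_numerator") == "fail"


def test_repeat_differs_by_one_passes():
    prev = rec(year=2004, numerator=84_213, denominator=100_000)
    cur = rec(year=2005, numerator=84_214, denominator=100_001)
    results = check_repeat_previous_year(cur, prev)
    assert all(r.status == "pass" for r in results)


def test_repeat_without_baseline():
    results = check_repeat_previous_year(rec(numerator=5), None)
    assert all(r.status == "not_applicable" for r in results)


def test_repeat_rejects_mismatched_keys():
    with pytest.raises(ValueError):
        check_repeat_previous_year(rec(year=2005), rec(year=2003))


@pytest.mark.parametrize(
    "field,value,expected",
    [
        ("official_coverage", 100.0, "fail"),
        ("admin_coverage", 99.9, "pass"),
        ("admin_coverage", 123.0, "fail"),
    ],
)
def test_coverage_cap(field, value, expected):
    cid = "consistency.cap_official" if field == "official_coverage" else "consistency.cap_admin"
    assert status_of(check_coverage_cap(rec(**{field: value})), cid) == expected


def test_coverage_cap_missing_is_na():
    assert status_of(check_coverage_cap(rec(official_coverage=90.0)), "consistency.cap_admin") == "not_applicable"


def test_yoy_count_relative_boundary():
    cfg = StudyConfig()
    prev = rec(year=2004, denominator=100_000)
    cur = rec(year=2005, denominator=111_000)
    assert status_of(check_year_to_year(cur, prev, cfg), "consistency.yoy_denominator") == "fail"


def test_yoy_coverage_points_boundary():
    cfg = StudyConfig()
    prev = rec(year=2004, admin_coverage=80.0)
    ok = rec(year=2005, admin_coverage=89.0)
    edge = rec(year=2005, admin_coverage=90.0)
    assert status_of(check_year_to_year(ok, prev, cfg), "consistency.yoy_admin") == "pass"
    assert status_of(check_year_to_year(edge, prev, cfg), "consistency.yoy_admin") == "fail"


def test_yoy_modes_match_bruteforce_grid():
    """Both year-to-year modes agree with a direct recomputation over a
    grid of value pairs, including the >= boundary."""
    cfg_pts = StudyConfig(yoy_coverage_mode="percentage_points", yoy_count_mode="relative")
    cfg_rel = StudyConfig(yoy_coverage_mode="relative", yoy_count_mode="percentage_points")
    grid = [0.0, 1.0, 50.0, 79.9, 80.0, 88.0, 89.99, 90.0, 95.0, 100.0, 110.0]
    for prev_v in grid:
        for cur_v in grid:
            prev = rec(year=2004, admin_coverage=prev_v, denominator=int(prev_v * 1000) or None)
            cur = rec(year=2005, admin_coverage=cur_v, denominator=int(cur_v * 1000) or None)
            res_pts = {r.check_id: r.status for r in check_year_to_year(cur, prev, cfg_pts)}
            res_rel = {r.check_id: r.status for r in check_year_to_year(cur, prev, cfg_rel)}
            # coverage, percentage-point rule
            expect = "fail" if abs(cur_v - prev_v) >= 10.0 else "pass"
            assert res_pts["consistency.yoy_admin"] == expect
            # coverage, relative rule
            if prev_v == 0:
                assert res_rel["consistency.yoy_admin"] == "not_applicable"
            else:
                expect = "fail" if abs(cur_v - prev_v) / prev_v >= 0.10 else "pass"
                assert res_rel["consistency.yoy_admin"] == expect
            # counts, relative rule (missing when grid value was 0 -> None)
            pd_, cd_ = prev.denominator, cur.denominator
            if pd_ is None or cd_ is None:
                assert res_pts["consistency.yoy_denominator"] == "not_applicable"
            else:
                expect = "fail" if abs(cd_ - pd_) / pd_ >= 0.10 else "pass"
                assert res_pts["consistency.yoy_denominator"] == expect


def test_dropout_zero_rate_fails():
    d1 = rec(vaccine="DTP1", numerator=100_000)
    d3 = rec(vaccine="DTP3", numerator=100_000)
    assert status_of(check_dropout(d1, d3), "consistency.dropout_numerator") == "fail"


def test_dropout_positive_rate_passes():
    d1 = rec(vaccine="DTP1", admin_coverage=95.0)
    d3 = rec(vaccine="DTP3", admin_coverage=90.0)
    assert status_of(check_dropout(d1, d3), "consistency.dropout_admin") == "pass"


def test_dropout_negative_rate_fails():
    d1 = rec(vaccine="DTP1", official_coverage=90.0)
    d3 = rec(vaccine="DTP3", official_coverage=95.0)
    assert status_of(check_dropout(d1, d3), "consistency.dropout_official") == "fail"


def test_dropout_missing_input_na():
    d1 = rec(vaccine="DTP1", numerator=100, admin_coverage=95.0)
    d3 = rec(vaccine="DTP3", numerator=90)
    assert status_of(check_dropout(d1, d3), "consistency.dropout_official") == "not_applicable"


# ---------------------------------------------------------------------------
# integrity


def test_integrity_exact_match_passes():
    results = check_integrity(rec(numerator=90, denominator=100, admin_coverage=90.0))
    assert all(r.status == "pass" for r in results)


def test_integrity_recalculated_cap_boundary():
    results = check_integrity(rec(numerator=100, denominator=100, admin_coverage=100.0))
    assert status_of(results, "consistency.recalc_cap") == "fail"


def test_integrity_mismatch_beyond_tolerance():
    results = check_integrity(rec(numerator=90, denominator=100, admin_coverage=93.0), 0.5)
    assert status_of(results, "integrity.recalc_match") == "fail"


def test_integrity_rounding_within_tolerance_passes():
    results = check_integrity(rec(numerator=905, denominator=1000, admin_coverage=90.0), 0.5)
    assert status_of(results, "integrity.recalc_match") == "pass"


def test_integrity_zero_denominator_fails_both():
    results = check_integrity(rec(numerator=90, denominator=0, admin_coverage=90.0))
    assert all(r.status == "fail" and "denominator zero" in r.detail for r in results)


def test_integrity_missing_inputs_na():
    results = check_integrity(rec(admin_coverage=90.0))
    assert all(r.status == "not_applicable" for r in results)


# ---------------------------------------------------------------------------
# purity


def test_checks_are_pure():
    r = rec(numerator=90, denominator=100, admin_coverage=93.0, official_coverage=101.0)
    first = check_integrity(r) + check_coverage_cap(r)
    second = check_integrity(r) + check_coverage_cap(r)
    assert first == second
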