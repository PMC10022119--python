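"""Data-quality checks for reported immunization coverage.

Four dimensions are assessed:

* **completeness** — is each expected data type (numerator, denominator,
  administrative coverage, official coverage) actually reported?
* **congruence** — do reported denominators agree with external UN
  demographic estimates, directly and through the implied infant
  mortality rate (IIMR)?
* **consistency** — are values free of contradictions over time and
  across doses: exact repeats of the preceding year, coverage at or above
  100%, year-to-year changes of >= 10%, and zero-or-negative DTP1->DTP3
  dropout rates?
* **integrity** — does the reported administrative coverage equal the
  coverage recalculated from its own numerator and denominator?

Every check is a pure function of its arguments returning
:class:`CheckResult` values; a result is ``not_applicable`` whenever a
required input is missing or the check is ineligible for the country.
Checks only classify — nothing is imputed or corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .records import CoverageRecord, ReferenceDemographics, StudyConfig, Vaccine

__all__ = [
    "CheckResult",
    "CheckDef",
    "CHECKS",
    "checks_for_vaccine",
    "implied_imr",
    "dropout_rate",
    "recalc_admin_coverage",
    "check_completeness",
    "check_denominator_vs_reference",
    "check_iimr",
    "check_repeat_previous_year",
    "check_coverage_cap",
    "check_year_to_year",
    "check_dropout",
    "check_integrity",
]

PASS = "pass"
FAIL = "fail"
NA = "not_applicable"

DATA_TYPES = ("numerator", "denominator", "admin_coverage", "official_coverage")


@dataclass(frozen=True)
class CheckResult:
    """Outcome of one check on one coverage record."""

    check_id: str
    dimension: str  # completeness | congruence | consistency | integrity
    data_type: str  # primary data type the check is attributed to
    status: str  # pass | fail | not_applicable
    detail: str = ""

    def __post_init__(self):
        if self.status not in (PASS, FAIL, NA):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == FAIL and not self.detail:
            raise ValueError(f"failing check {self.check_id} requires detail")


@dataclass(frozen=True)
class CheckDef:
    """Static description of one check in the battery."""

    check_id: str
    dimension: str
    data_type: str
    #: all data types whose points count as "affected" when this check fails
    affects: tuple[str, ...]
    #: vaccines the check applies to
    vaccines: tuple[str, ...]


_ALL = ("BCG", "DTP1", "DTP3", "MCV1")
_NON_BCG = ("DTP1", "DTP3", "MCV1")

#: The full check taxonomy.  recalc_cap carries the consistency label
#: (coverage >= 100% is a consistency-type contradiction) while
#: recalc_match is the integrity check proper; both are produced by the
#: integrity recalculation and both implicate numerator and denominator.
CHECKS: dict[str, CheckDef] = {
    c.check_id: c
    for c in [
        CheckDef("completeness.numerator", "completeness", "numerator", ("numerator",), _ALL),
        CheckDef("completeness.denominator", "completeness", "denominator", ("denominator",), _ALL),
        CheckDef("completeness.admin_coverage", "completeness", "admin_coverage", ("admin_coverage",), _ALL),
        CheckDef("completeness.official_coverage", "completeness", "official_coverage", ("official_coverage",), _ALL),
        CheckDef("congruence.denom_vs_unpd", "congruence", "denominator", ("denominator",), _ALL),
        CheckDef("congruence.iimr_zero_neg", "congruence", "denominator", ("denominator",), _NON_BCG),
        CheckDef("congruence.iimr_vs_ui", "congruence", "denominator", ("denominator",), _NON_BCG),
        CheckDef("consistency.repeat_numerator", "consistency", "numerator", ("numerator",), _ALL),
        CheckDef("consistency.repeat_denominator", "consistency", "denominator", ("denominator",), _ALL),
        CheckDef("consistency.cap_admin", "consistency", "admin_coverage", ("admin_coverage",), _ALL),
        CheckDef("consistency.cap_official", "consistency", "official_coverage", ("official_coverage",), _ALL),
        CheckDef("consistency.yoy_denominator", "consistency", "denominator", ("denominator",), _ALL),
        CheckDef("consistency.yoy_admin", "consistency", "admin_coverage", ("admin_coverage",), _ALL),
        CheckDef("consistency.yoy_official", "consistency", "official_coverage", ("official_coverage",), _ALL),
        CheckDef("consistency.dropout_numerator", "consistency", "numerator", ("numerator",), ("DTP3",)),
        CheckDef("consistency.dropout_admin", "consistency", "admin_coverage", ("admin_coverage",), ("DTP3",)),
        CheckDef("consistency.dropout_official", "consistency", "official_coverage", ("official_coverage",), ("DTP3",)),
        CheckDef("consistency.recalc_cap", "consistency", "numerator", ("numerator", "denominator"), _ALL),
        CheckDef("integrity.recalc_match", "integrity", "numerator", ("numerator", "denominator"), _ALL),
    ]
}


def checks_for_vaccine(vaccine: Vaccine | str) -> set[str]:
    """All check ids that can apply to a record of the given vaccine."""
    v = Vaccine(vaccine).value
    return {cid for cid, d in CHECKS.items() if v in d.vaccines}


def _result(check_id: str, status: str, detail: str = "") -> CheckResult:
    d = CHECKS[check_id]
    return CheckResult(check_id, d.dimension, d.data_type, status, detail)


# ---------------------------------------------------------------------------
# Elementary formulas


def implied_imr(live_birth_proxy: float, surviving_proxy: float) -> float:
    """Implied infant mortality rate from reported denominators.

    ``(live_birth_proxy - surviving_proxy) / live_birth_proxy``, using the
    BCG denominator as the live-births proxy and a DTP1/DTP3/MCV1
    denominator as the surviving-infants proxy.  Returned as a fraction;
    may be negative (which is itself an anomaly).
    """
    if live_birth_proxy is None or surviving_proxy is None:
        raise ValueError("implied_imr requires both proxies")
    if live_birth_proxy <= 0:
        raise ValueError("live-birth proxy must be > 0")
    return (live_birth_proxy - surviving_proxy) / live_birth_proxy


def dropout_rate(dtp1_value: float, dtp3_value: float) -> float:
    """DTP dropout rate in percent: ``(DTP1 - DTP3) / DTP1 x 100``."""
    if dtp1_value is None or dtp3_value is None:
        raise ValueError("dropout_rate requires both values")
    if dtp1_value <= 0:
        raise ValueError("DTP1 value must be > 0")
    return (dtp1_value - dtp3_value) / dtp1_value * 100.0


def recalc_admin_coverage(numerator: float, denominator: float) -> float:
    """Administrative coverage recalculated as numerator/denominator x 100."""
    if denominator is None or denominator <= 0:
        raise ValueError("denominator must be > 0")
    return numerator / denominator * 100.0


# ---------------------------------------------------------------------------
# Checks


def check_completeness(record: CoverageRecord, eligible: set[str]) -> list[CheckResult]:
    """One completeness result per eligible data type; fail iff missing."""
    out = []
    for dt in DATA_TYPES:
        cid = f"completeness.{dt}"
        if cid not in eligible:
            continue
        value = record.get(dt)
        if value is None:
            out.append(_result(cid, FAIL, f"{dt} missing"))
        else:
            out.append(_result(cid, PASS))
    return out


def check_denominator_vs_reference(
    record: CoverageRecord,
    ref: Optional[ReferenceDemographics],
    threshold: float,
) -> CheckResult:
    """Compare the reported denominator with the UN birth-cohort estimate.

    Live births are the target for BCG (a birth dose); surviving infants
    for DTP1/DTP3/MCV1.  Relative deviations >= ``threshold`` fail.
    """
    cid = "congruence.denom_vs_unpd"
    if record.denominator is None:
        return _result(cid, NA, "denominator missing")
    target = None
    if ref is not None:
        target = ref.live_births if record.vaccine is Vaccine.BCG else ref.surviving_infants
    if target is None:
        return _result(cid, NA, "reference cohort unavailable")
    if target <= 0:
        return _result(cid, NA, f"reference cohort nonpositive ({target})")
    dev = abs(record.denominator - target) / target
    if dev >= threshold:
        return _result(cid, FAIL, f"deviation {dev:.3f} >= {threshold:.2f} (target {target})")
    return _result(cid, PASS)


def check_iimr(
    bcg_denominator: Optional[int],
    other_denominator: Optional[int],
    ref: Optional[ReferenceDemographics],
    vaccine: Vaccine | str,
    small_population: bool = False,
) -> list[CheckResult]:
    """IIMR checks for a DTP1/DTP3/MCV1 record.

    (a) zero-or-negative IIMR fails; (b) IIMR (per 1000) outside the 90%
    uncertainty interval of the UN-IGME infant mortality estimate fails.
    (b) is not applicable for small-population countries, which have no
    UN-IGME interval context of comparable quality.
    """
    v = Vaccine(vaccine)
    if v is Vaccine.BCG:
        raise ValueError("IIMR checks apply to DTP1/DTP3/MCV1 records only")
    out = []
    if bcg_denominator is None or other_denominator is None or bcg_denominator <= 0:
        why = "BCG denominator missing" if not bcg_denominator else "denominator missing"
        out.append(_result("congruence.iimr_zero_neg", NA, why))
        out.append(_result("congruence.iimr_vs_ui", NA, why))
        return out
    iimr = implied_imr(bcg_denominator, other_denominator)
    if iimr <= 0:
        out.append(
            _result("congruence.iimr_zero_neg", FAIL, f"implied IMR {iimr:.4f} <= 0")
        )
    else:
        out.append(_result("congruence.iimr_zero_neg", PASS))
    if small_population:
        out.append(_result("congruence.iimr_vs_ui", NA, "small-population country"))
    elif ref is None or ref.imr_lower90 is None or ref.imr_upper90 is None:
        out.append(_result("congruence.iimr_vs_ui", NA, "UN-IGME interval unavailable"))
    else:
        per1000 = iimr * 1000.0
        if per1000 < ref.imr_lower90 or per1000 > ref.imr_upper90:
            out.append(
                _result(
                    "congruence.iimr_vs_ui",
                    FAIL,
                    f"implied IMR {per1000:.1f}/1000 outside "
                    f"[{ref.imr_lower90:.1f}, {ref.imr_upper90:.1f}]",
                )
            )
        else:
            out.append(_result("congruence.iimr_vs_ui", PASS))
    return out


def check_repeat_previous_year(
    current: CoverageRecord, previous: Optional[CoverageRecord]
) -> list[CheckResult]:
    """Detect numerators/denominators copied verbatim from the prior year."""
    out = []
    for dt, cid in (
        ("numerator", "consistency.repeat_numerator"),
        ("denominator", "consistency.repeat_denominator"),
    ):
        if previous is None:
            out.append(_result(cid, NA, "no preceding-year record"))
            continue
        if previous.country != current.country or previous.vaccine != current.vaccine:
            raise ValueError("repeat check requires same country and vaccine")
        if previous.year != current.year - 1:
            raise ValueError("repeat check requires consecutive years")
        cur, prev = current.get(dt), previous.get(dt)
        if cur is None or prev is None:
            out.append(_result(cid, NA, f"{dt} missing on one side"))
        elif cur == prev:
            out.append(_result(cid, FAIL, f"{dt} {cur} identical to preceding year"))
        else:
            out.append(_result(cid, PASS))
    return out


def check_coverage_cap(record: CoverageRecord, cap: float = 100.0) -> list[CheckResult]:
    """Coverage levels equal to or above 100% are abnormal."""
    out = []
    for dt, cid in (
        ("admin_coverage", "consistency.cap_admin"),
        ("official_coverage", "consistency.cap_official"),
    ):
        value = record.get(dt)
        if value is None:
            out.append(_result(cid, NA, f"{dt} missing"))
        elif value >= cap:
            out.append(_result(cid, FAIL, f"{dt} {value:g} >= {cap:g}"))
        else:
            out.append(_result(cid, PASS))
    return out


def _yoy_one(cur, prev, mode: str, rel_threshold: float, pts_threshold: float):
    """Return (fails, detail) for one year-to-year comparison, or None if N/A."""
    if cur is None or prev is None:
        return None
    if mode == "relative":
        if prev == 0:
            return None
        change = abs(cur - prev) / abs(prev)
        if change >= rel_threshold:
            return True, f"relative change {change:.3f} >= {rel_threshold:.2f}"
        return False, ""
    change = abs(cur - prev)
    if change >= pts_threshold:
        return True, f"change {change:g} >= {pts_threshold:g} points"
    return False, ""


def check_year_to_year(
    current: CoverageRecord,
    previous: Optional[CoverageRecord],
    config: StudyConfig,
) -> list[CheckResult]:
    """Year-to-year differences of >= 10% in denominators and coverages.

    Counts are compared on the relative scale and coverages on the
    absolute percentage-point scale by default; both rules are switchable
    in :class:`~vaxqc.records.StudyConfig`.
    """
    specs = (
        ("denominator", "consistency.yoy_denominator", config.yoy_count_mode),
        ("admin_coverage", "consistency.yoy_admin", config.yoy_coverage_mode),
        ("official_coverage", "consistency.yoy_official", config.yoy_coverage_mode),
    )
    out = []
    for dt, cid, mode in specs:
        if previous is None:
            out.append(_result(cid, NA, "no preceding-year record"))
            continue
        res = _yoy_one(
            current.get(dt),
            previous.get(dt),
            mode,
            config.relative_deviation_threshold,
            config.yoy_points_threshold,
        )
        if res is None:
            out.append(_result(cid, NA, f"{dt} missing or zero baseline"))
        elif res[0]:
            out.append(_result(cid, FAIL, f"{dt}: {res[1]}"))
        else:
            out.append(_result(cid, PASS))
    return out


def check_dropout(
    dtp1_record: Optional[CoverageRecord], dtp3_record: CoverageRecord
) -> list[CheckResult]:
    """DTP1->DTP3 dropout rates that are zero or negative are abnormal.

    Computed on numerators and on both coverage types; results are
    attributed to the DTP3 record.
    """
    specs = (
        ("numerator", "consistency.dropout_numerator"),
        ("admin_coverage", "consistency.dropout_admin"),
        ("official_coverage", "consistency.dropout_official"),
    )
    out = []
    for dt, cid in specs:
        v1 = dtp1_record.get(dt) if dtp1_record is not None else None
        v3 = dtp3_record.get(dt)
        if v1 is None or v3 is None:
            out.append(_result(cid, NA, f"{dt} missing for DTP1 or DTP3"))
        elif v1 <= 0:
            out.append(_result(cid, NA, f"DTP1 {dt} is zero"))
        else:
            rate = dropout_rate(v1, v3)
            if rate <= 0:
                out.append(_result(cid, FAIL, f"dropout rate {rate:.2f}% <= 0 on {dt}"))
            else:
                out.append(_result(cid, PASS))
    return out


def check_integrity(record: CoverageRecord, tolerance: float = 0.5) -> list[CheckResult]:
    """Recalculate administrative coverage from its numerator/denominator.

    (a) a recalculated coverage >= 100% fails; (b) a recalculated coverage
    differing from the reported administrative coverage by more than
    ``tolerance`` percentage points fails.  A zero denominator with a
    present numerator fails both outright.
    """
    cap_id, match_id = "consistency.recalc_cap", "integrity.recalc_match"
    n, d, admin = record.numerator, record.denominator, record.admin_coverage
    if n is None or d is None:
        why = "numerator or denominator missing"
        return [_result(cap_id, NA, why), _result(match_id, NA, why)]
    if d == 0:
        return [
            _result(cap_id, FAIL, "denominator zero"),
            _result(match_id, FAIL, "denominator zero"),
        ]
    recalc = recalc_admin_coverage(n, d)
    out = []
    if recalc >= 100.0:
        out.append(_result(cap_id, FAIL, f"recalculated coverage {recalc:.1f} >= 100"))
    else:
        out.append(_result(cap_id, PASS))
    if admin is None:
        out.append(_result(match_id, NA, "admin coverage missing"))
    elif abs(recalc - admin) > tolerance:
        out.append(
            _result(
                match_id,
                FAIL,
                f"recalculated {recalc:.2f} vs reported {admin:g} "
                f"(|diff| > {tolerance:g})",
            )
        )
    else:
        out.append(_result(match_id, PASS))
    return out
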