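"""Seeded synthetic inputs with ground-truth anomaly labels.

Generates a complete, internally consistent stand-in for the annual
country reporting inputs: a coverage table (country-year-vaccine rows
with numerator, denominator, administrative and official coverage),
reference demographics (birth cohorts and infant-mortality estimates
with 90% uncertainty intervals), and a country attributes table — plus
a :class:`GroundTruth` object recording which anomalies were injected
where and which reports are therefore expected to be flagged.

The clean generator is constructed so that *every* quality check passes:
denominators track the reference cohorts within a few percent, implied
infant mortality rates sit inside their uncertainty intervals, coverage
levels stay below 100%, year-to-year changes stay well under 10%, DTP1
always exceeds DTP3, and administrative coverage equals its recalculated
value up to reporting rounding.  Anomalies are then *injected* as
minimal perturbations, each designed to violate exactly one check;
collateral violations (unavoidable, since the checks overlap — e.g. a
denominator shift moves both the external-comparison and year-to-year
checks) are predicted by a literal rule evaluator and recorded in the
ground truth rather than forbidden.

The generator emulates the structure of real reporting, not its values:
no attempt is made to mimic actual countries or the real geographic
distribution of anomalies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import Dataset, applicable_years, eligible_checks
from .records import (
    CountryAttributes,
    CoverageRecord,
    ReferenceDemographics,
    StudyConfig,
    Vaccine,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_reference",
    "generate_attributes",
    "generate_clean_coverage",
    "inject_anomalies",
    "generate_dataset",
    "simulate_flag_panel",
    "write_dataset",
]

REGIONS = ("AFR", "AMR", "EMR", "EUR", "SEAR", "WPR")
INCOME_GROUPS = ("LIC", "LMIC", "UMIC", "HIC")
COVERAGE_STRATA = ("<80", "80-<90", "90-<95", ">=95")
BIRTH_REG_STRATA = ("<80", "80-<95", ">=95")

#: Checks the injector knows how to plant.
INJECTABLE_CHECKS = (
    "completeness.numerator",
    "completeness.denominator",
    "completeness.admin_coverage",
    "completeness.official_coverage",
    "congruence.denom_vs_unpd",
    "congruence.iimr_zero_neg",
    "congruence.iimr_vs_ui",
    "consistency.repeat_numerator",
    "consistency.repeat_denominator",
    "consistency.cap_admin",
    "consistency.cap_official",
    "consistency.yoy_denominator",
    "consistency.yoy_admin",
    "consistency.yoy_official",
    "consistency.dropout_numerator",
    "consistency.dropout_admin",
    "consistency.dropout_official",
    "consistency.recalc_cap",
    "integrity.recalc_match",
)


def _default_anomaly_rates() -> dict[str, float]:
    return {cid: 0.02 for cid in INJECTABLE_CHECKS}


def _default_vaccine_effects() -> dict[str, float]:
    # Log-odds offsets per dose, sized to the published spread of flag
    # probabilities across doses (BCG lowest, DTP1 highest).
    return {"BCG": -0.91, "DTP1": 0.93, "DTP3": 0.07, "MCV1": -0.81}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic data generation.

    Defaults mirror the real reporting landscape: a 2000-2019 window
    with a 1999 lookback year, roughly one country in five without a BCG
    birth dose, a handful of very small countries without UN birth
    cohorts, a handful without centralized reporting, a global flag
    propensity around 18% declining by about 5% per year on the odds
    scale, and between-country heterogeneity of one logit SD.
    """

    n_countries: int = 50
    first_year: int = 2000
    last_year: int = 2019
    lookback_year: int = 1999
    seed: int = 0
    # flag-probability generative model
    alpha: float = float(logit(0.182))
    sigma_country: float = 1.0
    sigma_year_slope: float = 0.0
    beta_year: float = float(np.log(0.95))
    vaccine_effects: dict = field(default_factory=_default_vaccine_effects)
    # anomaly injection
    anomaly_rates: dict = field(default_factory=_default_anomaly_rates)
    # country composition (fractions of the 194 WHO member states)
    frac_no_bcg: float = 42 / 194
    frac_small_pop: float = 11 / 194
    frac_non_centralized: float = 14 / 194
    # reporting noise
    true_coverage_mean: float = 85.0
    true_coverage_sd: float = 8.0
    denominator_noise_sd: float = 0.02

    def __post_init__(self):
        for cid, r in self.anomaly_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"anomaly rate for {cid} must be in [0,1], got {r}")
        if self.first_year > self.last_year:
            raise ValueError("first_year must be <= last_year")

    @property
    def years(self) -> range:
        return range(self.first_year, self.last_year + 1)

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            first_year=self.first_year,
            last_year=self.last_year,
            lookback_year=self.lookback_year,
        )


def _country_codes(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    codes = []
    for combo in itertools.product(letters, repeat=3):
        codes.append("".join(combo))
        if len(codes) == n:
            return codes
    raise ValueError("too many countries")


# ---------------------------------------------------------------------------
# Hidden country profiles shared by the generator stages


@dataclass
class _Profile:
    country: str
    population: dict[int, int]
    live_births: dict[int, int]
    imr: dict[int, float]  # per 1000
    coverage: dict[tuple[str, int], float]  # (vaccine, year) -> true %
    denom_factor: dict[int, float]  # shared country-year reporting noise
    small_population: bool
    bcg_in_schedule: bool
    centralized: bool
    membership_start_year: int
    who_region: str


def _profiles(config: GeneratorConfig) -> dict[str, _Profile]:
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_countries
    codes = _country_codes(n)
    years_all = list(range(config.lookback_year, config.last_year + 1))

    idx = rng.permutation(n)
    n_small = int(round(config.frac_small_pop * n))
    n_nobcg = int(round(config.frac_no_bcg * n))
    n_noncen = int(round(config.frac_non_centralized * n))
    small_set = set(idx[:n_small])
    # overlap between categories is allowed, as in the real country lists
    nobcg_set = set(rng.permutation(n)[:n_nobcg])
    noncen_set = set(rng.permutation(n)[:n_noncen])

    # a few countries join mid-period (mirroring real membership history)
    membership = {i: 1948 for i in range(n)}
    if n >= 12:
        late = rng.choice(n, size=3, replace=False)
        for i, yr in zip(late, (2002, 2006, 2011)):
            membership[int(i)] = yr

    profiles: dict[str, _Profile] = {}
    for i, code in enumerate(codes):
        small = i in small_set
        if small:
            # must remain under the 90,000 cutoff in the last study year
            pop0 = float(rng.uniform(1.5e4, 6.5e4))
        else:
            pop0 = float(np.exp(rng.normal(16.0, 1.3)))
            pop0 = max(pop0, 5e5)
        growth = float(rng.normal(0.015, 0.007))
        growth = float(np.clip(growth, -0.005, 0.015 if small else 0.03))
        cbr = float(rng.uniform(0.018, 0.032))  # births per capita
        imr0 = float(rng.uniform(25.0, 75.0))
        imr_decline = float(rng.uniform(0.97, 0.99))

        population, live_births, imr = {}, {}, {}
        for t, year in enumerate(years_all):
            pop = pop0 * (1.0 + growth) ** t
            population[year] = int(round(pop))
            live_births[year] = int(round(pop * cbr))
            imr[year] = imr0 * imr_decline**t

        base_cov = float(
            np.clip(rng.normal(config.true_coverage_mean, config.true_coverage_sd), 55.0, 95.0)
        )
        gap13 = float(rng.uniform(2.0, 6.0))  # DTP1 - DTP3 true gap
        offsets = {"BCG": 2.0, "DTP1": gap13, "DTP3": 0.0, "MCV1": -2.0}
        coverage = {}
        walk = 0.0
        for year in years_all:
            walk = float(np.clip(walk + rng.uniform(-1.0, 1.0), -4.0, 4.0))
            # clip the common level before adding dose offsets so the
            # DTP1-DTP3 gap (and the BCG/MCV1 offsets) survive clipping
            level = float(np.clip(base_cov + walk, 44.0, 91.0))
            for v in ("BCG", "DTP1", "DTP3", "MCV1"):
                coverage[(v, year)] = level + offsets[v]

        base_noise = float(rng.uniform(-0.04, 0.04))
        denom_factor = {}
        jitter = 0.0
        for year in years_all:
            jitter = float(np.clip(jitter + rng.uniform(-0.004, 0.004), -0.008, 0.008))
            denom_factor[year] = 1.0 + base_noise + jitter

        profiles[code] = _Profile(
            country=code,
            population=population,
            live_births=live_births,
            imr=imr,
            coverage=coverage,
            denom_factor=denom_factor,
            small_population=small,
            bcg_in_schedule=i not in nobcg_set,
            centralized=i not in noncen_set,
            membership_start_year=membership[i],
            who_region=REGIONS[int(rng.integers(0, len(REGIONS)))],
        )
    return profiles


# ---------------------------------------------------------------------------
# Public generator operations


def generate_reference(config: GeneratorConfig) -> list[ReferenceDemographics]:
    """Reference demographics for every country-year (lookback included).

    Birth cohorts are absent for small-population countries, as the UN
    Population Division does not estimate them; the infant mortality
    point always sits inside its own 90% interval and surviving infants
    never exceed live births, by construction.
    """
    profiles = _profiles(config)
    out = []
    for code in sorted(profiles):
        p = profiles[code]
        for year in sorted(p.population):
            m = p.imr[year]
            births = None if p.small_population else p.live_births[year]
            surviving = (
                None if births is None else int(round(births * (1.0 - m / 1000.0)))
            )
            out.append(
                ReferenceDemographics(
                    country=code,
                    year=year,
                    live_births=births,
                    surviving_infants=surviving,
                    imr_point=round(m, 2),
                    imr_lower90=round(0.9 * m, 2),
                    imr_upper90=round(1.1 * m, 2),
                    total_population=p.population[year],
                )
            )
    return out


def generate_attributes(config: GeneratorConfig) -> dict[str, CountryAttributes]:
    """Country attribute table consistent with the reference demographics."""
    profiles = _profiles(config)
    rng = np.random.default_rng([config.seed, 102])
    codes = sorted(profiles)
    years = list(config.years)

    # population quintiles per year, from that year's population ranks
    quintiles: dict[str, dict[int, int]] = {c: {} for c in codes}
    for year in years:
        pops = np.array([profiles[c].population[year] for c in codes], dtype=float)
        ranks = pops.argsort().argsort()
        q = 1 + (ranks * 5) // len(codes)
        for c, qi in zip(codes, q):
            quintiles[c][year] = int(qi)

    out = {}
    for c in codes:
        p = profiles[c]
        # income trajectory: start somewhere, occasionally move up
        g = int(rng.integers(0, len(INCOME_GROUPS)))
        income = {}
        for year in years:
            if rng.random() < 0.03 and g < len(INCOME_GROUPS) - 1:
                g += 1
            income[year] = INCOME_GROUPS[g]
        mean_dtp = np.mean(
            [p.coverage[("DTP1", y)] for y in years[-3:]]
            + [p.coverage[("DTP3", y)] for y in years[-3:]]
        )
        if mean_dtp < 80:
            stratum = "<80"
        elif mean_dtp < 90:
            stratum = "80-<90"
        elif mean_dtp < 95:
            stratum = "90-<95"
        else:
            stratum = ">=95"
        fcs_country = rng.random() < 0.2
        fcs = {year: bool(fcs_country and rng.random() < 0.8) for year in years if year >= 2004}
        out[c] = CountryAttributes(
            country=c,
            who_region=p.who_region,
            membership_start_year=p.membership_start_year,
            bcg_in_schedule=p.bcg_in_schedule,
            centralized_system=p.centralized,
            small_population=p.small_population,
            gavi_support=bool(income[years[0]] in ("LIC", "LMIC") and rng.random() < 0.8),
            coverage_level_stratum=stratum,
            birth_registration_stratum=BIRTH_REG_STRATA[int(rng.integers(0, 3))],
            income_group=income,
            population_quintile=quintiles[c],
            fcs_status=fcs,
        )
    return out


def _cohort_target(profile: _Profile, vaccine: str, year: int) -> float:
    births = float(profile.live_births[year])
    if vaccine == "BCG":
        return births
    return births * (1.0 - profile.imr[year] / 1000.0)


def generate_clean_coverage(
    config: GeneratorConfig,
    reference: Optional[list[ReferenceDemographics]] = None,
    attributes: Optional[dict[str, CountryAttributes]] = None,
) -> list[CoverageRecord]:
    """Coverage records on which every quality check passes.

    Denominators follow the reference cohorts with a shared country-year
    noise factor (so implied IMRs stay near the true IMR) plus a tiny
    per-vaccine jitter; numerators follow smooth true coverage levels
    with DTP1 strictly above DTP3; administrative coverage is the
    recalculated value rounded to one decimal; official coverage tracks
    it with sub-point noise.  Countries without centralized reporting
    supply official coverage only.
    """
    profiles = _profiles(config)
    rng = np.random.default_rng([config.seed, 103])
    records: list[CoverageRecord] = []
    vaccines = ("BCG", "DTP1", "DTP3", "MCV1")
    prev_vals: dict[tuple, tuple] = {}

    for code in sorted(profiles):
        p = profiles[code]
        start = max(config.first_year, p.membership_start_year)
        years = list(range(start, config.last_year + 1))
        if start == config.first_year:
            years = [config.lookback_year] + years
        for year in years:
            for v in vaccines:
                if v == "BCG" and not p.bcg_in_schedule:
                    continue
                cov = p.coverage[(v, year)]
                if not p.centralized:
                    official = round(cov + float(rng.uniform(-0.4, 0.4)), 1)
                    records.append(
                        CoverageRecord(code, year, Vaccine(v), None, None, None, official)
                    )
                    continue
                target = _cohort_target(p, v, year)
                jitter = float(rng.uniform(-4e-4, 4e-4))
                den = int(round(target * p.denom_factor[year] * (1.0 + jitter)))
                prev = prev_vals.get((code, v))
                if prev is not None and den == prev[1]:
                    den += 1
                num = int(round(den * cov / 100.0))
                if prev is not None and num == prev[0]:
                    num += 1
                admin = round(num / den * 100.0, 1)
                official = round(
                    min(admin + float(rng.uniform(-0.4, 0.4)), 99.4), 1
                )
                prev_vals[(code, v)] = (num, den)
                records.append(
                    CoverageRecord(code, year, Vaccine(v), num, den, admin, official)
                )
    return records


# ---------------------------------------------------------------------------
# Anomaly injection


@dataclass
class GroundTruth:
    """Which anomalies were planted, what must fail, what must be flagged.

    ``injections`` lists the intended violations; ``expected_failures``
    is the full fail set (intended plus collateral) predicted by a
    literal rule evaluation of the perturbed data; ``expected_flags``
    applies the flag rule to that fail set.
    """

    injections: pd.DataFrame
    expected_failures: set
    expected_flags: pd.DataFrame

    def injections_csv(self) -> pd.DataFrame:
        return self.injections.copy()


def _set(record: CoverageRecord, **kw) -> CoverageRecord:
    return replace(record, **kw)


def inject_anomalies(
    records: list[CoverageRecord],
    config: GeneratorConfig,
    reference: Optional[list[ReferenceDemographics]] = None,
    attributes: Optional[dict[str, CountryAttributes]] = None,
) -> tuple[list[CoverageRecord], GroundTruth]:
    """Minimally perturb clean records to violate specific checks.

    Each selected record receives exactly one injection, perturbing the
    fewest fields needed to break the chosen check; an injection that is
    impossible at a site (no preceding year, missing companion record)
    is skipped there.  Lookback-year records are never perturbed.
    """
    reference = reference if reference is not None else generate_reference(config)
    attributes = attributes if attributes is not None else generate_attributes(config)
    rng = np.random.default_rng([config.seed, 104])
    scfg = config.study_config()

    index: dict[tuple, CoverageRecord] = {r.key: r for r in records}
    refidx = {(r.country, r.year): r for r in reference}
    touched: set[tuple] = set()
    # companion records an earlier injection depends on; modifying them
    # later could silently undo the intended violation
    frozen: set[tuple] = set()
    injected_rows = []

    def prev_rec(key):
        return index.get((key[0], key[1] - 1, key[2]))

    def bcg_rec(key):
        return index.get((key[0], key[1], "BCG"))

    def dtp1_rec(key):
        return index.get((key[0], key[1], "DTP1"))

    assessed_keys = [
        k
        for k in sorted(index)
        if k[1] >= scfg.first_year
        and k[1] in applicable_years(attributes[k[0]], scfg)
    ]

    for cid in sorted(config.anomaly_rates):
        rate = config.anomaly_rates[cid]
        if rate <= 0 or cid not in INJECTABLE_CHECKS:
            continue
        for key in assessed_keys:
            if rng.random() >= rate:
                continue
            if key in touched or key in frozen:
                continue
            rec = index[key]
            attrs = attributes[key[0]]
            if cid not in eligible_checks(rec.vaccine, attrs):
                continue
            new = _inject_one(cid, rec, prev_rec(key), bcg_rec(key), dtp1_rec(key),
                              refidx.get((key[0], key[1])), rng)
            if new is None:
                continue
            index[key] = new
            touched.add(key)
            if cid.startswith(("consistency.repeat", "consistency.yoy")):
                frozen.add((key[0], key[1] - 1, key[2]))
            elif cid.startswith("consistency.dropout"):
                frozen.add((key[0], key[1], "DTP1"))
            elif cid.startswith("congruence.iimr"):
                frozen.add((key[0], key[1], "BCG"))
            injected_rows.append(
                dict(country=key[0], year=key[1], vaccine=key[2], check_id=cid)
            )

    out_records = [index[k] for k in sorted(index)]
    expected = _expected_failures(out_records, reference, attributes, scfg)
    flags = _expected_flags(out_records, attributes, scfg, expected)
    gt = GroundTruth(
        injections=pd.DataFrame(
            injected_rows, columns=["country", "year", "vaccine", "check_id"]
        ),
        expected_failures=expected,
        expected_flags=flags,
    )
    return out_records, gt


def _inject_one(cid, rec, prev, bcg, dtp1, ref, rng) -> Optional[CoverageRecord]:
    """Apply one injection; return the perturbed record or None if
    impossible at this site."""
    if cid == "completeness.numerator":
        return _set(rec, numerator=None) if rec.numerator is not None else None
    if cid == "completeness.denominator":
        return _set(rec, denominator=None) if rec.denominator is not None else None
    if cid == "completeness.admin_coverage":
        return _set(rec, admin_coverage=None) if rec.admin_coverage is not None else None
    if cid == "completeness.official_coverage":
        return _set(rec, official_coverage=None) if rec.official_coverage is not None else None

    if cid == "congruence.denom_vs_unpd":
        if rec.denominator is None or rec.numerator is None:
            return None
        f = 1.15
        return _set(
            rec,
            denominator=int(round(rec.denominator * f)),
            numerator=int(round(rec.numerator * f)),
        )
    if cid == "congruence.iimr_zero_neg":
        if bcg is None or bcg.denominator is None or rec.denominator is None:
            return None
        den = int(round(bcg.denominator * 1.02))
        num = (
            int(round(den * rec.admin_coverage / 100.0))
            if rec.admin_coverage is not None
            else rec.numerator
        )
        return _set(rec, denominator=den, numerator=num)
    if cid == "congruence.iimr_vs_ui":
        if (
            bcg is None
            or bcg.denominator is None
            or rec.denominator is None
            or ref is None
            or ref.imr_lower90 is None
        ):
            return None
        den = int(round(bcg.denominator * (1.0 - 0.5 * ref.imr_lower90 / 1000.0)))
        if den >= bcg.denominator:  # would turn zero/negative instead
            return None
        num = (
            int(round(den * rec.admin_coverage / 100.0))
            if rec.admin_coverage is not None
            else rec.numerator
        )
        return _set(rec, denominator=den, numerator=num)

    if cid == "consistency.repeat_numerator":
        if prev is None or prev.numerator is None or rec.numerator is None:
            return None
        return _set(rec, numerator=prev.numerator)
    if cid == "consistency.repeat_denominator":
        if prev is None or prev.denominator is None or rec.denominator is None:
            return None
        return _set(rec, denominator=prev.denominator)
    if cid == "consistency.cap_admin":
        if rec.admin_coverage is None:
            return None
        return _set(rec, admin_coverage=round(float(rng.uniform(100.0, 103.0)), 1))
    if cid == "consistency.cap_official":
        if rec.official_coverage is None:
            return None
        return _set(rec, official_coverage=round(float(rng.uniform(100.0, 103.0)), 1))
    if cid == "consistency.yoy_denominator":
        # anchored on the previous-year value so the >=10% change holds
        # regardless of what this record's own denominator currently is
        if prev is None or not prev.denominator or rec.denominator is None:
            return None
        den = int(round(prev.denominator * 1.12))
        if rec.admin_coverage is not None:
            num = int(round(den * rec.admin_coverage / 100.0))
        elif rec.numerator is not None:
            num = int(round(rec.numerator * den / rec.denominator))
        else:
            num = None
        return _set(rec, denominator=den, numerator=num)
    if cid == "consistency.yoy_admin":
        if prev is None or prev.admin_coverage is None or rec.admin_coverage is None:
            return None
        delta = 12.4 if prev.admin_coverage <= 85.0 else -12.4
        return _set(rec, admin_coverage=round(max(prev.admin_coverage + delta, 0.0), 1))
    if cid == "consistency.yoy_official":
        if prev is None or prev.official_coverage is None or rec.official_coverage is None:
            return None
        delta = 12.4 if prev.official_coverage <= 85.0 else -12.4
        return _set(rec, official_coverage=round(max(prev.official_coverage + delta, 0.0), 1))
    if cid == "consistency.dropout_numerator":
        if dtp1 is None or dtp1.numerator is None or rec.numerator is None:
            return None
        return _set(rec, numerator=dtp1.numerator)
    if cid == "consistency.dropout_admin":
        if dtp1 is None or dtp1.admin_coverage is None or rec.admin_coverage is None:
            return None
        return _set(rec, admin_coverage=dtp1.admin_coverage)
    if cid == "consistency.dropout_official":
        if dtp1 is None or dtp1.official_coverage is None or rec.official_coverage is None:
            return None
        return _set(rec, official_coverage=dtp1.official_coverage)
    if cid == "consistency.recalc_cap":
        if rec.denominator is None or rec.numerator is None or rec.denominator == 0:
            return None
        return _set(rec, numerator=int(np.ceil(rec.denominator * 1.02)))
    if cid == "integrity.recalc_match":
        if rec.numerator is None or rec.denominator in (None, 0) or rec.admin_coverage is None:
            return None
        recalc = rec.numerator / rec.denominator * 100.0
        delta = 2.0 if recalc <= 95.0 else -2.0
        return _set(rec, admin_coverage=round(recalc + delta, 1))
    raise ValueError(f"no injector for {cid}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Literal rule evaluation (independent prediction of the fail set)


def _expected_failures(records, reference, attributes, scfg: StudyConfig) -> set:
    """Predict every failing (country, year, vaccine, check_id) by
    evaluating the published rules directly on the data."""
    index = {r.key: r for r in records}
    refidx = {(r.country, r.year): r for r in reference}
    fails: set = set()
    rel = scfg.relative_deviation_threshold
    pts = scfg.yoy_points_threshold

    for country in sorted(attributes):
        attrs = attributes[country]
        for year in sorted(applicable_years(attrs, scfg)):
            for v in ("BCG", "DTP1", "DTP3", "MCV1"):
                if v == "BCG" and not attrs.bcg_in_schedule:
                    continue
                elig = eligible_checks(v, attrs)
                rec = index.get((country, year, v)) or CoverageRecord(
                    country, year, Vaccine(v)
                )
                prev = index.get((country, year - 1, v))
                ref = refidx.get((country, year))
                key = (country, year, v)

                def add(cid):
                    fails.add(key + (cid,))

                for dt in ("numerator", "denominator", "admin_coverage", "official_coverage"):
                    if f"completeness.{dt}" in elig and rec.get(dt) is None:
                        add(f"completeness.{dt}")
                if "congruence.denom_vs_unpd" in elig and rec.denominator is not None and ref:
                    target = ref.live_births if v == "BCG" else ref.surviving_infants
                    if target and abs(rec.denominator - target) / target >= rel:
                        add("congruence.denom_vs_unpd")
                if v != "BCG" and rec.denominator is not None:
                    bcg = index.get((country, year, "BCG"))
                    if bcg is not None and bcg.denominator:
                        iimr = (bcg.denominator - rec.denominator) / bcg.denominator
                        if "congruence.iimr_zero_neg" in elig and iimr <= 0:
                            add("congruence.iimr_zero_neg")
                        if (
                            "congruence.iimr_vs_ui" in elig
                            and ref is not None
                            and ref.imr_lower90 is not None
                            and not (ref.imr_lower90 <= iimr * 1000.0 <= ref.imr_upper90)
                        ):
                            add("congruence.iimr_vs_ui")
                if prev is not None:
                    for dt, cid in (
                        ("numerator", "consistency.repeat_numerator"),
                        ("denominator", "consistency.repeat_denominator"),
                    ):
                        if (
                            cid in elig
                            and rec.get(dt) is not None
                            and prev.get(dt) is not None
                            and rec.get(dt) == prev.get(dt)
                        ):
                            add(cid)
                    if (
                        "consistency.yoy_denominator" in elig
                        and rec.denominator is not None
                        and prev.denominator
                        and abs(rec.denominator - prev.denominator) / prev.denominator >= rel
                    ):
                        add("consistency.yoy_denominator")
                    for dt, cid in (
                        ("admin_coverage", "consistency.yoy_admin"),
                        ("official_coverage", "consistency.yoy_official"),
                    ):
                        if (
                            cid in elig
                            and rec.get(dt) is not None
                            and prev.get(dt) is not None
                            and abs(rec.get(dt) - prev.get(dt)) >= pts
                        ):
                            add(cid)
                for dt, cid in (
                    ("admin_coverage", "consistency.cap_admin"),
                    ("official_coverage", "consistency.cap_official"),
                ):
                    if cid in elig and rec.get(dt) is not None and rec.get(dt) >= scfg.coverage_cap:
                        add(cid)
                if v == "DTP3":
                    d1 = index.get((country, year, "DTP1"))
                    for dt, cid in (
                        ("numerator", "consistency.dropout_numerator"),
                        ("admin_coverage", "consistency.dropout_admin"),
                        ("official_coverage", "consistency.dropout_official"),
                    ):
                        if cid not in elig or d1 is None:
                            continue
                        v1, v3 = d1.get(dt), rec.get(dt)
                        if v1 is not None and v3 is not None and v1 > 0 and v1 - v3 <= 0:
                            add(cid)
                if rec.numerator is not None and rec.denominator is not None:
                    if rec.denominator == 0:
                        if "consistency.recalc_cap" in elig:
                            add("consistency.recalc_cap")
                        if "integrity.recalc_match" in elig:
                            add("integrity.recalc_match")
                    else:
                        recalc = rec.numerator / rec.denominator * 100.0
                        if "consistency.recalc_cap" in elig and recalc >= 100.0:
                            add("consistency.recalc_cap")
                        if (
                            "integrity.recalc_match" in elig
                            and rec.admin_coverage is not None
                            and abs(recalc - rec.admin_coverage) > scfg.admin_match_tolerance
                        ):
                            add("integrity.recalc_match")
    return fails


_OFFICIAL_CHECKS = {
    "completeness.official_coverage",
    "consistency.cap_official",
    "consistency.yoy_official",
    "consistency.dropout_official",
}


def _expected_flags(records, attributes, scfg: StudyConfig, fails: set) -> pd.DataFrame:
    """Apply the flag rule to the predicted fail set."""
    index = {r.key: r for r in records}
    rows = []
    for country in sorted(attributes):
        attrs = attributes[country]
        for year in sorted(applicable_years(attrs, scfg)):
            for v in ("BCG", "DTP1", "DTP3", "MCV1"):
                if v == "BCG" and not attrs.bcg_in_schedule:
                    continue
                elig = eligible_checks(v, attrs)
                rec = index.get((country, year, v)) or CoverageRecord(
                    country, year, Vaccine(v)
                )
                unit_fails = {
                    cid for (c, y, vv, cid) in fails if (c, y, vv) == (country, year, v)
                }
                elig_types = set()
                for dt in ("numerator", "denominator", "admin_coverage"):
                    if f"completeness.{dt}" in elig:
                        elig_types.add(dt)
                if "completeness.official_coverage" in elig:
                    elig_types.add("official_coverage")
                any_data = any(rec.get(dt) is not None for dt in elig_types)
                o_present = (
                    "official_coverage" in elig_types
                    and rec.official_coverage is not None
                )
                admin_fail = any(c not in _OFFICIAL_CHECKS for c in unit_fails)
                off_sub_fail = any(
                    c in _OFFICIAL_CHECKS and c != "completeness.official_coverage"
                    for c in unit_fails
                )
                if not any_data:
                    flagged = True
                elif o_present and not off_sub_fail:
                    flagged = False
                else:
                    flagged = admin_fail or off_sub_fail
                rows.append(
                    dict(country=country, year=year, vaccine=v, expected_flag=int(flagged))
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full dataset and panel generation


def generate_dataset(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Generate reference, attributes, clean coverage, and injections."""
    reference = generate_reference(config)
    attributes = generate_attributes(config)
    clean = generate_clean_coverage(config, reference, attributes)
    records, gt = inject_anomalies(clean, config, reference, attributes)
    ds = Dataset.from_frames(records, reference, attributes, config.study_config())
    return ds, gt


def simulate_flag_panel(config: GeneratorConfig):
    """Draw a flag panel directly from the generative probability model.

    flags ~ Bernoulli(expit(alpha + u_c + (beta_year + s_c) * t + vaccine
    effect)) with u_c ~ N(0, sigma_country^2), s_c ~ N(0,
    sigma_year_slope^2) and t the year centered at the first study year.
    Returns (panel, true_params).
    """
    rng = np.random.default_rng([config.seed, 105])
    codes = _country_codes(config.n_countries)
    u = rng.normal(0.0, config.sigma_country, size=len(codes))
    s = rng.normal(0.0, config.sigma_year_slope, size=len(codes)) if config.sigma_year_slope > 0 else np.zeros(len(codes))
    vaccines = ("BCG", "DTP1", "DTP3", "MCV1")
    rows = []
    for i, code in enumerate(codes):
        for year in config.years:
            t = year - config.first_year
            for v in vaccines:
                eta = (
                    config.alpha
                    + u[i]
                    + (config.beta_year + s[i]) * t
                    + config.vaccine_effects.get(v, 0.0)
                )
                rows.append(
                    dict(
                        country=code,
                        year=year,
                        vaccine=v,
                        flagged=int(rng.random() < expit(eta)),
                    )
                )
    panel = pd.DataFrame(rows)
    true_params = dict(
        alpha=config.alpha,
        beta_year=config.beta_year,
        sigma_country=config.sigma_country,
        sigma_year_slope=config.sigma_year_slope,
        vaccine_effects=dict(config.vaccine_effects),
    )
    return panel, true_params


# ---------------------------------------------------------------------------
# CSV writers (the same dialects the readers accept)


def _year_map_cell(mapping) -> str:
    return ";".join(f"{y}:{v}" for y, v in sorted(mapping.items()))


def write_dataset(
    dataset: Dataset, outdir, ground_truth: Optional[GroundTruth] = None
) -> dict[str, str]:
    """Write coverage/reference/attributes (and ground truth) CSVs."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    cov = pd.DataFrame(
        [
            dict(
                country=r.country,
                year=r.year,
                vaccine=r.vaccine.value,
                numerator=r.numerator,
                denominator=r.denominator,
                admin_coverage=r.admin_coverage,
                official_coverage=r.official_coverage,
            )
            for _, r in sorted(dataset.records.items())
        ]
    )
    paths["coverage"] = str(outdir / "coverage.csv")
    cov.to_csv(paths["coverage"], index=False)

    ref = pd.DataFrame(
        [
            dict(
                country=r.country,
                year=r.year,
                live_births=r.live_births,
                surviving_infants=r.surviving_infants,
                imr_point=r.imr_point,
                imr_lower90=r.imr_lower90,
                imr_upper90=r.imr_upper90,
                total_population=r.total_population,
            )
            for _, r in sorted(dataset.reference.items())
        ]
    )
    paths["reference"] = str(outdir / "reference.csv")
    ref.to_csv(paths["reference"], index=False)

    attrs = pd.DataFrame(
        [
            dict(
                country=a.country,
                who_region=a.who_region,
                membership_start_year=a.membership_start_year,
                bcg_in_schedule=a.bcg_in_schedule,
                centralized_system=a.centralized_system,
                small_population=a.small_population,
                gavi_support=a.gavi_support,
                coverage_level_stratum=a.coverage_level_stratum,
                birth_registration_stratum=a.birth_registration_stratum,
                income_group=_year_map_cell(a.income_group),
                population_quintile=_year_map_cell(a.population_quintile),
                fcs_status=_year_map_cell(a.fcs_status),
            )
            for _, a in sorted(dataset.attributes.items())
        ]
    )
    paths["attributes"] = str(outdir / "attributes.csv")
    attrs.to_csv(paths["attributes"], index=False)

    if ground_truth is not None:
        paths["injections"] = str(outdir / "ground_truth_injections.csv")
        ground_truth.injections.to_csv(paths["injections"], index=False)
        ef = pd.DataFrame(
            sorted(ground_truth.expected_failures),
            columns=["country", "year", "vaccine", "check_id"],
        )
        paths["expected_failures"] = str(outdir / "ground_truth_failures.csv")
        ef.to_csv(paths["expected_failures"], index=False)
        paths["expected_flags"] = str(outdir / "ground_truth_flags.csv")
        ground_truth.expected_flags.to_csv(paths["expected_flags"], index=False)
    return paths
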