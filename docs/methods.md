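# Methods

This note documents the models, rules, numerical choices, and known
limitations of `vaxqc`.

## Data model and eligibility

The unit of observation is the country-year-vaccine record with four
data types: numerator (doses administered), denominator (estimated
target children), administrative coverage (numerator/denominator ×
100, as reported), and official coverage (the country's best estimate,
possibly survey-based). Missing values are a distinct state, never 0:
a zero count is a legal — if abnormal — report. Percentages at or
above 100 are accepted on input; detecting them is the job of the
checks, not the parser.

The assessment window is 2000–2019 by default, with 1999 loaded as a
*lookback* year that serves only as the baseline for the first year's
year-to-year comparisons and is itself never assessed or flagged.
Eligibility rules restrict which checks run where:

* countries without the BCG birth dose in their routine schedule have
  no BCG reports, and no implied-IMR checks for the other doses (the
  BCG denominator is the live-births proxy those checks need);
* countries under 90,000 inhabitants in the last study year lack UN
  Population Division birth-cohort estimates and skip every comparison
  against them (external denominator check, IIMR-vs-interval check);
* countries without a centralized immunization reporting system are
  assessed only on official coverage;
* countries that joined the WHO mid-period are assessed from their
  membership year.

Schedule membership is treated as time-invariant; how mid-period
schedule changes should be handled is genuinely open, and a
time-varying switch would complicate the eligibility algebra for
little benefit at this scope. Year-varying classifications (income
group, population-size quintile, fragile/conflict-affected status) are
year→value maps; a missing year silently removes that country-year
from models grouped on that variable rather than erroring.

## Check battery

All thresholds are inclusive where the rule says "≥" ("≥ 10%",
"equal or over 100%", "zero or negative"). Two interpretation
choices are configurable because the published wording does not pin
them down:

* **Year-to-year "≥ 10%"** is applied as *relative* change for counts
  (matching the convention of the external denominator comparison) and
  as *absolute percentage points* for coverages (which are already
  percentages). Both modes are implemented and switchable
  (`yoy_count_mode`, `yoy_coverage_mode`).
* **"Did not match"** for the integrity recalculation uses a tolerance
  of 0.5 percentage points (`admin_match_tolerance`), because reported
  coverages are typically rounded to one decimal or integer; exact
  equality would flag pure rounding.

Further conventions: the IIMR-vs-interval comparison is on the
per-1000 scale with inclusive interval membership; the two IIMR
conditions (zero-or-negative, outside the interval) are independent
checks, both of which can fail on the same record; a zero denominator
with a present numerator is an integrity failure, not a crash;
numerator year-to-year change is not a separate check (the
repeat-previous-year check covers numerators, and the summary tallies
carry no numerator year-to-year row); integrity applies to
administrative coverage only, not official; and the recalculated-
coverage-≥100% result carries the consistency dimension label (it is a
coverage-cap contradiction) while the match test carries integrity,
though both are emitted by the integrity recalculation. IIMR and
dropout results are attributed to the non-BCG (respectively DTP3)
record's administrative stream, matching how such anomalies are
tallied by data type.

## Flag rule

Let A = any failing administrative-stream check, O_present = an
official coverage value was reported, O_pass = O_present with no
failing official-stream check. Then

    flagged = not O_pass and (A or substantive official fail
                                or nothing reported)

Two borderline cases are decided (and switchable):

* official data that passes all checks outweighs any administrative
  anomaly, including missing administrative fields
  (`official_outweighs_admin`, default on);
* a missing official value alone does not flag a report whose
  administrative data passes (`missing_official_flags`, default off) —
  otherwise every administrative-only reporter would be flagged every
  year, which would contradict flag probabilities anywhere near the
  plausible range;
* a report with no assessed data at all is flagged with basis
  `missing_data`.

## Mixed model

The flag panel is modelled as y_i ~ Bernoulli(p_i) with
logit p_i = x_i'β + z_i'b_{g(i)}, b_g ~ N(0, D), country as the
level-two grouping factor, and D diagonal: the random intercept and
any random slopes (year, vaccine-dose indicators) are independent
variance components. Independence keeps the profiled likelihood
well-behaved at a few hundred groups; a full covariance adds little
for the estimands reported here and is deliberately not implemented.

Estimation maximizes the Laplace-approximated marginal likelihood (one
quadrature point, the same approximation class as standard frequentist
GLMM software). For each candidate D the joint penalized likelihood is
maximized over (β, b) by Newton iterations with step-halving, solving
the random-effect block per group via a Schur complement; the profiled
Laplace log-likelihood

    l(β, b̂) − ½ Σ_g b̂_g'D⁻¹b̂_g − ½ Σ_g log det(I + D Z_g'W_g Z_g)

is then optimized over log σ by L-BFGS-B (bounds e^−9.2 ≤ σ ≤ 20),
falling back to Nelder-Mead when the finite-difference line search is
upset by the tiny warm-start noise of the inner solver. Inner
convergence is declared at a relative penalized-likelihood change of
10⁻¹⁰; a variance estimate at the lower bound is floored to zero with
a warning. With all variances fixed at zero the fit reduces *exactly*
to ordinary logistic regression (verified against statsmodels to
10⁻⁴); with a random intercept it matches `lme4::glmer` (nAGQ=1) to
about 0.1 on coefficients on test panels.

Inference is Wald throughout, on the logit scale, with the
fixed-effect covariance taken as the inverse observed information at
the mode, conditional on the estimated variance components (the usual
GLMM convention; variance-component uncertainty is not propagated).
Significance is read at p = 0.05.

**Marginal probabilities** are conditional on a typical country
(random effects at zero) and average over the levels of the other
fixed factors with equal weights on the linear-predictor scale,
emulating estimated-marginal-means conventions; continuous year is set
to its panel mean. The contrast of a level against its classification
mean is a sum-to-zero contrast on the logit scale. Whether published
group probabilities of this kind are population-averaged or
conditional is generally not stated; conditional is the default here
and the difference is a known limitation when comparing against
population-averaged figures (conditional probabilities are attenuated
toward 0/1 relative to marginal ones when σ is large).

**Trends** are reported as yearly percent change in flag *odds*,
(e^β_year − 1) × 100 (negative = decline), with the CI transformed
from the logit scale. Published per-year percent changes rarely state
their scale; a probability-scale analogue (geometric yearly change of
the predicted probability between the first and last year) is provided
as `probability_scale_trend`. Year is centered (default at 2000)
before fitting; centering shifts the intercept but provably not the
trend or the predictions.

**Spline trends** use a natural cubic spline in centered year with df
columns (truncated-power basis: boundary knots at the observed
extremes, df − 1 interior knots at quantiles; linear beyond the
boundaries). df = 1 degenerates exactly to the linear-in-year model.
Default df = 5.

## Synthetic-data generator

The generator emulates the *structure* of the real reporting system —
not actual countries' values or the real geography of anomalies. The
default scale is 50 countries × 20 years × 4 doses (≈ 3,700 reports),
large enough for model recovery and small enough for seconds-scale
tests; model-recovery settings use 194 countries (the real membership
count). Country composition mirrors the real landscape: fractions
42/194 without BCG, 11/194 small-population, 14/194 non-centralized,
and three countries joining in 2002, 2006, and 2011. The flag-panel
generative model defaults to an 18.2% baseline probability, a −5%/year
odds trend, 1-logit country heterogeneity, and per-dose offsets sized
to the published spread across doses.

Clean data is constructed so every check passes: populations grow
smoothly (≤ 3%/year), infant mortality declines 1–3%/year from 25–75
per 1000, denominators track the reference cohorts through a shared
country-year noise factor (|noise| ≤ 4.8%) plus a per-dose jitter of
≤ 0.04% — small enough that the implied IMR stays inside its ± 10%
interval even at the lowest mortality the generator produces — true
coverage walks slowly with DTP1 above DTP3 by a 2–6 point dropout,
administrative coverage is the recalculated value rounded to one
decimal, and official coverage tracks it within ± 0.4 points.
Post-rounding collisions with the prior year's counts are bumped by
one dose.

Anomalies are injected as minimal perturbations, each designed to
violate one named check (blank a field, scale a denominator by 1.15,
set coverage to 100–103, copy the previous year's count, equalize
DTP1/DTP3, shift the reported coverage off its recalculation, …).
Because the checks overlap, some collateral violations are
unavoidable — a shifted denominator moves the external comparison,
the year-to-year test, and the implied IMR at once. The generator
therefore predicts the *full* expected fail set by evaluating every
rule literally on the perturbed data (an independent code path from
the check battery) and records it in the ground truth; year-to-year
injections are anchored on the previous-year value, and companion
records an injection depends on (previous year, same-year BCG or DTP1)
are frozen against later injections so every intended violation
actually materializes. At most one injection lands per
country-year-vaccine unit.

All generation is deterministic under the seed (hierarchical seed
sequences per stage), and the CSV writers emit the same dialects the
readers accept, so simulate → write → read → check round-trips
byte-identically.

What passing tests on synthetic data do *not* show: real reporting has
correlated, regime-like anomalies (a country switching information
systems, conflict years), heaped and rounded values, genuinely
ambiguous borderline reports, and denominator revisions — none of
which the minimal-perturbation model imitates. Results on synthetic
data validate the *machinery* (rules, flag logic, estimation), not the
real-world prevalence of any anomaly.

## Limitations

* Headline estimates from the real reporting snapshot are not
  reproducible here: they depend on a versioned external data
  extract. The pipeline reproduces the *method*, exercised on
  synthetic data with known truth.
* Wald inference and the Laplace approximation can be optimistic at
  small group counts or probabilities near 0/1.
* Flags are binary; no severity weighting, and no imputation or
  correction of abnormal values — checks only classify.
* Birth-registration level and fragile/conflict status are handled as
  ordinary grouping variables, not as separately tuned models.
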