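# vaxqc — quality assessment of reported immunization coverage data

`vaxqc` is a reusable pipeline for assessing the quality of child
immunization coverage data as countries report it annually (numerator =
doses administered, denominator = estimated target children,
administrative coverage = numerator/denominator × 100, plus an official
coverage estimate) for four vaccine doses: BCG birth dose, DTP1, DTP3,
and MCV1. It is aimed at epidemiologists and immunization-programme
analysts who want to screen country-year-vaccine reporting for
anomalies and model how data quality differs across country groups and
evolves over time.

The pipeline has three stages:

1. **Checks.** Every country-year-vaccine record is screened on four
   dimensions. *Completeness*: is each expected data type reported?
   *Congruence*: does the denominator agree with UN birth-cohort
   estimates (relative deviation ≥ 10% is abnormal), and does the
   implied infant mortality rate,
   IIMR = (live-birth proxy − surviving-infant proxy) / live-birth proxy
   (BCG denominator as the live-births proxy), stay positive and inside
   the 90% uncertainty interval of the UN-IGME infant-mortality
   estimate? *Consistency*: numerators/denominators repeated verbatim
   from the preceding year, coverage ≥ 100%, year-to-year changes ≥
   10%, and DTP dropout rates, (DTP1 − DTP3)/DTP1 × 100, that are zero
   or negative. *Integrity*: administrative coverage recalculated as
   numerator/denominator × 100 must be < 100% and match the reported
   value. Countries without BCG in the schedule, with fewer than 90,000
   inhabitants, without a centralized reporting system, or before their
   WHO membership year are excluded from the checks that do not apply
   to them.

2. **Flagging.** All results for one country-year-vaccine form one
   *coverage report*; a report is flagged when any check fails, except
   that official data passing every check outweighs anomalies confined
   to the administrative side.

3. **Modelling.** The 0/1 flag panel is fit with binomial logistic
   mixed models, logit P(flag) = x'β + z'b_country with
   b_country ~ N(0, D), estimated by Laplace-approximated maximum
   likelihood (country random intercept, optional year and vaccine-dose
   random slopes). The package reports typical-country marginal flag
   probabilities with Wald CIs, contrasts of each country group against
   its classification mean, yearly percent changes in flag odds
   ((e^β_year − 1) × 100), and natural-spline trend curves.

A seeded synthetic-data generator produces the full input set (coverage
table, UN-style reference demographics, country attributes) with
ground-truth anomaly labels, so the whole pipeline is testable without
any external data.

## Worked example

```python
import numpy as np
from scipy.special import logit
from vaxqc import (GeneratorConfig, ModelSpec, simulate_flag_panel,
                   fit_flag_model, global_probability, trend_percent_change)

config = GeneratorConfig(seed=7, n_countries=194,
                         alpha=float(logit(0.18)),
                         beta_year=float(np.log(0.95)), sigma_country=1.0)
panel, truth = simulate_flag_panel(config)
gp = global_probability(fit_flag_model(panel, ModelSpec()))
tr = trend_percent_change(fit_flag_model(panel, ModelSpec(year="linear")))
```

Running `python examples/model_flag_trends.py` (which does the above
plus per-dose marginals) prints:

```
panel: 15520 reports, 194 countries, empirical flag rate 0.150

global flag probability: 12.3% (95% CI 10.9-13.9)
yearly change in flag odds: -4.8% per year (95% CI -5.6 to -4.0, p=1.6e-32); true value -5.0%

flag probability by vaccine dose (vs classification mean):
  BCG: 5.1% (4.2-6.1), p vs mean = 5.26e-46
  DTP1: 25.8% (22.8-29.0), p vs mean = 7.68e-182
  ...
```

The global probability is the inverse-logit of the intercept-only
model's intercept — the flag probability of a *typical* country
(random effects at zero), pooled over years; with a declining trend it
sits below the year-2000 baseline of 18%. The trend estimate recovers
the generating −5% yearly odds decline within its confidence interval.
`examples/run_quality_checks.py` shows the check battery recovering
planted anomalies exactly, and `examples/csv_pipeline.py` the
file-based workflow.

## Command line

```bash
vaxqc simulate --seed 1 --countries 50 --out data/
vaxqc check --coverage data/coverage.csv --reference data/reference.csv \
            --attrs data/attributes.csv --out results/
vaxqc model --flags results/reports.csv --spec trend --out results/trend/
vaxqc all --seed 1 --out run/        # simulate -> check -> model
```

Each command writes CSV outputs plus a JSON manifest with input digests
and the seed, and the whole chain is byte-identical under a fixed seed.

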