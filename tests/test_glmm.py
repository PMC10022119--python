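"""Mixed-model estimation and inference on flag panels."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from vaxqc import (
    GeneratorConfig,
    ModelSpec,
    fit_flag_model,
    global_probability,
    group_probabilities,
    simulate_flag_panel,
    spline_trend,
    trend_percent_change,
)
from vaxqc.glmm import ConvergenceError
from vaxqc.trends import build_design, natural_spline_basis


@pytest.fixture(scope="module")
def homogeneous_panel():
    """sigma=0, no trend, flat 20% flag probability."""
    cfg = GeneratorConfig(
        seed=21, n_countries=60, sigma_country=0.0, beta_year=0.0,
        alpha=float(logit(0.2)), vaccine_effects={},
    )
    panel, _ = simulate_flag_panel(cfg)
    return panel


@pytest.fixture(scope="module")
def heterogeneous_panel():
    cfg = GeneratorConfig(seed=33, n_countries=80, sigma_country=1.0,
                          vaccine_effects={})
    return simulate_flag_panel(cfg)[0]


def test_intercept_only_matches_empirical_rate(homogeneous_panel):
    """With no between-country variance or trend, the intercept must sit
    at the logit of the empirical flag rate (within binomial error)."""
    fm = fit_flag_model(homogeneous_panel, ModelSpec())
    rate = homogeneous_panel.flagged.mean()
    n = len(homogeneous_panel)
    se_logit = 1.0 / np.sqrt(n * rate * (1 - rate))
    assert fm.converged
    assert fm.fit.coefficients["intercept"] == pytest.approx(logit(rate), abs=4 * se_logit)
    gp = global_probability(fm)
    assert gp.probability == pytest.approx(rate, abs=0.02)
    assert gp.ci_low <= gp.probability <= gp.ci_high


def test_zero_variance_data_gives_near_zero_variance_estimate(homogeneous_panel):
    with pytest.warns(RuntimeWarning, match="floored"):
        fm = fit_flag_model(homogeneous_panel, ModelSpec())
    assert fm.fit.random_sd["intercept"] == 0.0


def test_sigma_zero_limit_equals_plain_logistic(heterogeneous_panel):
    import statsmodels.api as sm

    spec = ModelSpec(fixed=("vaccine",), year="linear")
    fm = fit_flag_model(heterogeneous_panel, spec, fix_sigma=[0.0])
    X, y, _, _, _ = build_design(heterogeneous_panel, spec)
    ref = sm.Logit(y, X).fit(disp=0)
    assert np.abs(fm.fit.coefficients.to_numpy() - ref.params).max() < 1e-4


def test_laplace_fit_matches_lme4(tmp_path):
    """Independent oracle: lme4::glmer with the same Laplace approximation."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    cfg = GeneratorConfig(seed=42, n_countries=30, sigma_country=1.0)
    panel, _ = simulate_flag_panel(cfg)
    csv = tmp_path / "panel.csv"
    panel.to_csv(csv, index=False)
    fm = fit_flag_model(panel, ModelSpec(fixed=("vaccine",), year="linear"))
    script = f"""
    suppressMessages(library(lme4))
    d <- read.csv("{csv}")
    d$year_c <- d$year - 2000
    m <- glmer(flagged ~ vaccine + year_c + (1|country), data=d, family=binomial, nAGQ=1)
    cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")
    """
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    vals = [float(x) for x in out.stdout.split()]
    r_coefs, r_sd, r_ll = np.array(vals[:5]), vals[5], vals[6]
    assert np.abs(fm.fit.coefficients.to_numpy() - r_coefs).max() < 0.1
    assert fm.fit.random_sd["intercept"] == pytest.approx(r_sd, abs=0.05)
    assert fm.fit.loglik == pytest.approx(r_ll, abs=0.5)


def test_trend_recovery_and_transform(heterogeneous_panel):
    fm = fit_flag_model(heterogeneous_panel, ModelSpec(year="linear"))
    tr = trend_percent_change(fm)
    beta = fm.fit.coefficients["year"]
    assert tr.percent_change_per_year == pytest.approx((np.exp(beta) - 1) * 100)
    assert tr.ci_low <= tr.percent_change_per_year <= tr.ci_high
    # generating trend was log(0.95): a 5% yearly decline in odds
    assert tr.ci_low < -5.0 < tr.ci_high
    assert tr.p_value < 0.01


def test_year_centering_equivariance(heterogeneous_panel):
    a = fit_flag_model(heterogeneous_panel, ModelSpec(year="linear", year_center=2000))
    b = fit_flag_model(heterogeneous_panel, ModelSpec(year="linear", year_center=2010))
    ta, tb = trend_percent_change(a), trend_percent_change(b)
    assert ta.percent_change_per_year == pytest.approx(tb.percent_change_per_year, abs=0.05)
    assert a.fit.coefficients["intercept"] != pytest.approx(b.fit.coefficients["intercept"], abs=0.1)


def test_group_probabilities_vaccine_effects():
    cfg = GeneratorConfig(seed=9, n_countries=80, sigma_country=0.5, beta_year=0.0)
    panel, tp = simulate_flag_panel(cfg)
    fm = fit_flag_model(panel, ModelSpec(fixed=("vaccine",)))
    mps = {m.group: m for m in group_probabilities(fm, "vaccine")}
    assert set(mps) == {"BCG", "DTP1", "DTP3", "MCV1"}
    # planted ordering: DTP1 highest, BCG and MCV1 lowest
    assert mps["DTP1"].probability > mps["DTP3"].probability > mps["BCG"].probability
    assert mps["DTP1"].p_vs_classification_mean < 0.01
    for m in mps.values():
        assert 0.0 <= m.ci_low <= m.probability <= m.ci_high <= 1.0


def test_group_probabilities_requires_factor(heterogeneous_panel):
    fm = fit_flag_model(heterogeneous_panel, ModelSpec(year="linear"))
    with pytest.raises(ValueError, match="not a fixed factor"):
        group_probabilities(fm, "who_region")


def test_global_probability_guards(heterogeneous_panel):
    fm = fit_flag_model(heterogeneous_panel, ModelSpec(fixed=("vaccine",)))
    with pytest.raises(ValueError, match="intercept-only"):
        global_probability(fm)
    fm2 = fit_flag_model(heterogeneous_panel, ModelSpec())
    fm2.fit.converged = False
    with pytest.raises(ConvergenceError):
        global_probability(fm2)


def test_trend_requires_linear_year(heterogeneous_panel):
    fm = fit_flag_model(heterogeneous_panel, ModelSpec())
    with pytest.raises(ValueError, match="linear year"):
        trend_percent_change(fm)


def test_group_trend_requires_interaction(heterogeneous_panel):
    fm = fit_flag_model(heterogeneous_panel, ModelSpec(year="linear"))
    with pytest.raises(ValueError, match="interaction"):
        trend_percent_change(fm, "DTP1")


# ---------------------------------------------------------------------------
# splines


def test_natural_spline_degenerates_to_line():
    x = np.linspace(0, 19, 20)
    basis = natural_spline_basis(x, np.array([0.0, 19.0]))
    assert basis.shape == (20, 1)
    assert np.allclose(basis[:, 0], x)


def test_natural_spline_linear_beyond_boundaries():
    knots = np.array([0.0, 5.0, 10.0, 15.0, 19.0])
    x = np.array([-5.0, -4.0, 23.0, 24.0])
    b = natural_spline_basis(x, knots)
    # second differences vanish where the spline is linear
    left = b[1] - b[0]
    right = b[3] - b[2]
    assert np.allclose(b[1] - b[0], left)
    assert np.all(np.isfinite(right))


def test_spline_df1_matches_linear_fit(heterogeneous_panel):
    lin = fit_flag_model(heterogeneous_panel, ModelSpec(year="linear"))
    spl = fit_flag_model(heterogeneous_panel, ModelSpec(year="spline", spline_df=1))
    a = spline_trend(lin)
    b = spline_trend(spl)
    assert np.allclose(a.probability.to_numpy(), b.probability.to_numpy(), atol=1e-5)


def test_spline_tracks_linear_trend_within_ci(heterogeneous_panel):
    lin = fit_flag_model(heterogeneous_panel, ModelSpec(year="linear"))
    spl = fit_flag_model(heterogeneous_panel, ModelSpec(year="spline", spline_df=5))
    a = spline_trend(lin).set_index("year")
    b = spline_trend(spl).set_index("year")
    inside = (b.probability >= a.ci_low - 0.02) & (b.probability <= a.ci_high + 0.02)
    assert inside.all()
    for _, row in b.iterrows():
        assert 0.0 <= row.ci_low <= row.probability <= row.ci_high <= 1.0


def test_flat_data_gives_flat_spline(homogeneous_panel):
    spl = fit_flag_model(homogeneous_panel, ModelSpec(year="spline", spline_df=5))
    curve = spline_trend(spl)
    assert curve.probability.max() - curve.probability.min() < 0.05


def test_random_slope_components_fit():
    cfg = GeneratorConfig(seed=55, n_countries=60, sigma_country=1.0,
                          sigma_year_slope=0.05, vaccine_effects={})
    panel, _ = simulate_flag_panel(cfg)
    fm = fit_flag_model(panel, ModelSpec(year="linear", random_slopes=("year",)))
    assert fm.converged
    assert fm.fit.random_sd["intercept"] > 0.5
    assert 0.0 <= fm.fit.random_sd["year"] < 0.2


def test_requires_two_countries():
    panel = pd.DataFrame(
        dict(country=["AAA"] * 10, year=range(2000, 2010), vaccine="DTP3",
             flagged=[0, 1] * 5)
    )
    with pytest.raises(ValueError, match="2 countries"):
        fit_flag_model(panel, ModelSpec())
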