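"""Flag-probability models: global level, group contrasts, and trends.

Works on the long-format flag panel (one row per country-year-vaccine
report with a 0/1 ``flagged`` outcome).  Country is always the level-two
random effect; year and vaccine dose can additionally enter as random
slopes.  Three model families are provided:

* an intercept-only model for the global flag probability;
* a main model with vaccine dose and a country classification as fixed
  factors, giving per-level marginal probabilities and their contrasts
  against the classification mean;
* trend models with year (linear, optionally interacted with a
  classification) giving yearly percent changes in the odds of a flag,
  or with year as a natural cubic spline for plottable trend curves.

Marginal probabilities are *conditional on a typical country* (random
effects at zero) and average over the other fixed factors' levels with
equal weights on the logit scale, emulating estimated-marginal-means
conventions.  Yearly "percent change" is reported on the odds scale,
``(exp(beta_year) - 1) x 100``; a probability-scale analogue (the
geometric yearly change of the predicted probability between the first
and last year) is also computed since published trend figures rarely
state their scale.  Inference is Wald throughout, on the logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import MixedLogitFit, fit_binomial_glmm
from .records import CountryAttributes

__all__ = [
    "ModelSpec",
    "FlagModel",
    "MarginalProbability",
    "TrendEstimate",
    "attach_attributes",
    "natural_spline_basis",
    "fit_flag_model",
    "global_probability",
    "group_probabilities",
    "trend_percent_change",
    "spline_trend",
]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one flag-probability model.

    ``fixed`` lists categorical fixed factors (e.g. ``("vaccine",
    "who_region")``); ``year`` is ``None``, ``"linear"`` or ``"spline"``;
    ``year_interaction`` names a factor whose levels get their own year
    slopes (or spline curves).  Year is centered at ``year_center``
    before fitting.  ``random_slopes`` may contain ``"year"`` and/or
    ``"vaccine"``; the country random intercept is always present.
    """

    fixed: tuple[str, ...] = ()
    year: Optional[str] = None
    year_interaction: Optional[str] = None
    spline_df: int = 5
    random_slopes: tuple[str, ...] = ()
    year_center: int = 2000

    def __post_init__(self):
        if self.year not in (None, "linear", "spline"):
            raise ValueError(f"bad year term {self.year!r}")
        if self.spline_df < 1:
            raise ValueError("spline_df must be >= 1")
        if self.year_interaction is not None and self.year is None:
            raise ValueError("year_interaction requires a year term")
        for rs in self.random_slopes:
            if rs not in ("year", "vaccine"):
                raise ValueError(f"unsupported random slope {rs!r}")


@dataclass
class MarginalProbability:
    group: str
    probability: float
    ci_low: float
    ci_high: float
    p_vs_classification_mean: Optional[float] = None

    def __post_init__(self):
        assert 0.0 <= self.ci_low <= self.probability <= self.ci_high <= 1.0


@dataclass
class TrendEstimate:
    group: str
    percent_change_per_year: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self):
        assert self.ci_low <= self.percent_change_per_year <= self.ci_high


# ---------------------------------------------------------------------------
# Panel preparation and design matrices


def attach_attributes(
    panel: pd.DataFrame,
    attributes: dict[str, CountryAttributes],
    columns: Sequence[str] = ("who_region",),
) -> pd.DataFrame:
    """Join country classifications onto the flag panel.

    Static attributes become constant columns; year-varying ones
    (``income_group``, ``population_quintile``, ``fcs_status``) are
    looked up per (country, year) and left missing (making the row
    ineligible for that grouping) when a year is absent from the map.
    """
    out = panel.copy()
    year_varying = {"income_group", "population_quintile", "fcs_status"}
    for col in columns:
        values = []
        for country, year in zip(out["country"], out["year"]):
            a = attributes[country]
            if col in year_varying:
                values.append(getattr(a, col).get(int(year)))
            else:
                values.append(getattr(a, col))
        out[col] = values
    return out


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form, no intercept).

    With K knots (boundary knots included) the basis has K-1 columns:
    x itself plus K-2 curvature terms that are linear beyond the
    boundary knots.  K=2 therefore degenerates to a straight line.
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    K = len(knots)
    if K < 2:
        raise ValueError("need at least 2 knots")
    cols = [x]

    def d(k):
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
        return num / (knots[-1] - knots[k])

    if K > 2:
        dK1 = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dK1)
    return np.column_stack(cols)


def _spline_knots(years_centered: np.ndarray, df: int) -> np.ndarray:
    """Knots for a df-column natural spline: boundary + df-1 interior
    quantiles of the observed (centered) years."""
    qs = np.linspace(0, 1, df + 1)
    knots = np.quantile(np.unique(years_centered), qs)
    return np.unique(knots)


@dataclass
class _DesignMeta:
    colnames: list[str]
    factors: dict[str, list]  # factor -> sorted levels (first = reference)
    factor_cols: dict[str, dict]  # factor -> {level: column index}
    year_kind: Optional[str]
    year_cols: list[int]
    inter_cols: dict  # level -> list of column indices (year x factor)
    inter_factor: Optional[str]
    knots: Optional[np.ndarray]
    year_center: int
    year_mean_c: float
    years_c: np.ndarray  # distinct centered years observed


def _year_basis(meta: _DesignMeta, t_centered) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t_centered, dtype=float))
    if meta.year_kind == "linear":
        return t[:, None]
    return natural_spline_basis(t, meta.knots)


def build_design(panel: pd.DataFrame, spec: ModelSpec):
    """Build the fixed-effect design matrix for a flag panel.

    Rows with a missing value in any required factor are dropped (a
    country-year missing from a year-varying classification simply does
    not contribute to that model).  Returns (X, y, groups, meta, used
    panel).
    """
    df = panel.copy()
    needed = list(spec.fixed)
    if spec.year_interaction and spec.year_interaction not in needed:
        needed.append(spec.year_interaction)
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"panel lacks required column {col!r}")
    if needed:
        df = df.dropna(subset=needed)
    df = df.reset_index(drop=True)

    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    factors: dict[str, list] = {}
    factor_cols: dict[str, dict] = {}

    for factor in needed:
        levels = sorted(df[factor].astype(str).unique())
        factors[factor] = levels
        factor_cols[factor] = {}
        vals = df[factor].astype(str).to_numpy()
        for level in levels[1:]:
            factor_cols[factor][level] = len(names)
            cols.append((vals == level).astype(float))
            names.append(f"{factor}[{level}]")

    year_cols: list[int] = []
    inter_cols: dict = {}
    knots = None
    years_c = np.array([])
    year_mean_c = 0.0
    if spec.year is not None:
        tc = df["year"].to_numpy(dtype=float) - spec.year_center
        years_c = np.unique(tc)
        year_mean_c = float(tc.mean())
        if spec.year == "spline":
            knots = _spline_knots(tc, spec.spline_df)
        meta_tmp = _DesignMeta(
            names, factors, factor_cols, spec.year, [], {}, spec.year_interaction,
            knots, spec.year_center, year_mean_c, years_c,
        )
        basis = _year_basis(meta_tmp, tc)
        for k in range(basis.shape[1]):
            year_cols.append(len(names))
            cols.append(basis[:, k])
            names.append("year" if spec.year == "linear" else f"ns(year)[{k}]")
        if spec.year_interaction:
            f = spec.year_interaction
            vals = df[f].astype(str).to_numpy()
            for level in factors[f][1:]:
                idxs = []
                ind = (vals == level).astype(float)
                for k in range(basis.shape[1]):
                    idxs.append(len(names))
                    cols.append(basis[:, k] * ind)
                    suffix = "year" if spec.year == "linear" else f"ns(year)[{k}]"
                    names.append(f"{suffix}:{f}[{level}]")
                inter_cols[level] = idxs

    X = np.column_stack(cols)
    meta = _DesignMeta(
        names, factors, factor_cols, spec.year, year_cols, inter_cols,
        spec.year_interaction, knots, spec.year_center, year_mean_c, years_c,
    )
    y = df["flagged"].to_numpy(dtype=float)
    groups = df["country"].to_numpy()
    return X, y, groups, meta, df


def _random_design(df: pd.DataFrame, spec: ModelSpec, year_center: int):
    """Random-effect design: intercept plus requested slopes."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    if "year" in spec.random_slopes:
        cols.append(df["year"].to_numpy(dtype=float) - year_center)
        names.append("year")
    if "vaccine" in spec.random_slopes:
        levels = sorted(df["vaccine"].astype(str).unique())
        vals = df["vaccine"].astype(str).to_numpy()
        for level in levels[1:]:
            cols.append((vals == level).astype(float))
            names.append(f"vaccine[{level}]")
    return np.column_stack(cols), names


@dataclass
class FlagModel:
    """A fitted flag-probability model with its design metadata."""

    fit: MixedLogitFit
    spec: ModelSpec
    meta: _DesignMeta

    @property
    def converged(self) -> bool:
        return self.fit.converged


def fit_flag_model(
    panel: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    fix_sigma=None,
    start_sigma: float = 0.5,
) -> FlagModel:
    """Fit a flag-probability model on a long-format flag panel."""
    if panel["country"].nunique() < 2:
        raise ValueError("panel must contain at least 2 countries")
    X, y, groups, meta, used = build_design(panel, spec)
    Z, znames = _random_design(used, spec, spec.year_center)
    fit = fit_binomial_glmm(
        y, X, groups,
        Z=Z,
        fixed_names=meta.colnames,
        random_names=znames,
        fix_sigma=fix_sigma,
        start_sigma=start_sigma,
    )
    return FlagModel(fit=fit, spec=spec, meta=meta)


# ---------------------------------------------------------------------------
# Inference helpers


def _wald_interval_prob(eta: float, se: float) -> tuple[float, float, float]:
    p = float(1.0 / (1.0 + np.exp(-eta)))
    lo = float(1.0 / (1.0 + np.exp(-(eta - Z95 * se))))
    hi = float(1.0 / (1.0 + np.exp(-(eta + Z95 * se))))
    return p, lo, hi


def _emm_vector(
    model: FlagModel,
    at: Optional[dict] = None,
    year_value_c: Optional[float] = None,
) -> np.ndarray:
    """Linear-predictor weight vector for a marginal mean.

    Factors named in ``at`` are pinned to a level; every other factor is
    averaged over its levels with equal weights.  The year basis is
    evaluated at ``year_value_c`` (centered; defaults to the panel mean).
    """
    at = at or {}
    meta = model.meta
    p = len(meta.colnames)
    L = np.zeros(p)
    L[0] = 1.0

    weights: dict[str, dict] = {}
    for factor, levels in meta.factors.items():
        w = {lv: 1.0 / len(levels) for lv in levels}
        if factor in at:
            w = {lv: 0.0 for lv in levels}
            lv = str(at[factor])
            if lv not in w:
                raise ValueError(f"unknown level {lv!r} of {factor!r}")
            w[lv] = 1.0
        weights[factor] = w
        for lv, col in meta.factor_cols[factor].items():
            L[col] = w[lv]

    if meta.year_kind is not None:
        t = meta.year_mean_c if year_value_c is None else float(year_value_c)
        basis = _year_basis(meta, [t])[0]
        for k, col in enumerate(meta.year_cols):
            L[col] = basis[k]
        if meta.inter_factor:
            w = weights[meta.inter_factor]
            for lv, idxs in meta.inter_cols.items():
                for k, col in enumerate(idxs):
                    L[col] = basis[k] * w[lv]
    return L


def global_probability(model: FlagModel) -> MarginalProbability:
    """Typical-country flag probability from an intercept-only model."""
    if model.meta.factors or model.meta.year_kind is not None:
        raise ValueError("global_probability requires an intercept-only model")
    model.fit.require_converged()
    eta = float(model.fit.coefficients.iloc[0])
    se = float(model.fit.se().iloc[0])
    p, lo, hi = _wald_interval_prob(eta, se)
    return MarginalProbability("global", p, lo, hi, None)


def group_probabilities(
    model: FlagModel, classification: str
) -> list[MarginalProbability]:
    """Per-level marginal flag probabilities with contrasts vs the mean.

    Each level's probability is the inverse-logit of its estimated
    marginal mean (other factors averaged, random effects zero); the
    p-value tests the level's deviation from the unweighted mean of all
    level means on the logit scale (sum-to-zero contrast, Wald).
    """
    model.fit.require_converged()
    if classification not in model.meta.factors:
        raise ValueError(f"{classification!r} is not a fixed factor of this model")
    beta = model.fit.coefficients.to_numpy()
    V = model.fit.vcov.to_numpy()
    levels = model.meta.factors[classification]
    Ls = [_emm_vector(model, {classification: lv}) for lv in levels]
    Lbar = np.mean(Ls, axis=0)
    out = []
    for lv, L in zip(levels, Ls):
        eta = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        p, lo, hi = _wald_interval_prob(eta, se)
        C = L - Lbar
        d = float(C @ beta)
        sd = float(np.sqrt(C @ V @ C))
        pval = float(2 * stats.norm.sf(abs(d) / sd)) if sd > 0 else 1.0
        out.append(MarginalProbability(str(lv), p, lo, hi, pval))
    return out


def trend_percent_change(
    model: FlagModel, group: Optional[str] = None
) -> TrendEstimate:
    """Yearly percent change in the odds of a flag: (exp(slope)-1) x 100.

    For a model with a year x classification interaction, ``group``
    selects the level whose slope is reported; without interaction the
    global slope is returned.  Negative values are declines.
    """
    model.fit.require_converged()
    meta = model.meta
    if meta.year_kind != "linear":
        raise ValueError("trend_percent_change requires a linear year term")
    p = len(meta.colnames)
    L = np.zeros(p)
    L[meta.year_cols[0]] = 1.0
    label = "global"
    if group is not None:
        if not meta.inter_factor:
            raise ValueError("model has no year interaction; cannot request a group trend")
        levels = meta.factors[meta.inter_factor]
        if str(group) not in levels:
            raise ValueError(f"unknown level {group!r} of {meta.inter_factor!r}")
        if str(group) in meta.inter_cols:  # non-reference level
            L[meta.inter_cols[str(group)][0]] = 1.0
        label = str(group)
    beta = model.fit.coefficients.to_numpy()
    V = model.fit.vcov.to_numpy()
    slope = float(L @ beta)
    se = float(np.sqrt(L @ V @ L))
    pct = (np.exp(slope) - 1.0) * 100.0
    lo = (np.exp(np.clip(slope - Z95 * se, -700, 700)) - 1.0) * 100.0
    hi = (np.exp(np.clip(slope + Z95 * se, -700, 700)) - 1.0) * 100.0
    pval = float(2 * stats.norm.sf(abs(slope) / se)) if se > 0 else 1.0
    return TrendEstimate(label, float(pct), float(lo), float(hi), pval)


def probability_scale_trend(model: FlagModel, group: Optional[str] = None) -> float:
    """Geometric yearly percent change of the predicted probability
    between the first and last observed year (probability-scale analogue
    of the odds-scale trend)."""
    meta = model.meta
    at = {meta.inter_factor: group} if group is not None else None
    t0, t1 = float(meta.years_c.min()), float(meta.years_c.max())
    b = model.fit.coefficients.to_numpy()
    eta0 = float(_emm_vector(model, at, t0) @ b)
    eta1 = float(_emm_vector(model, at, t1) @ b)
    p0 = 1.0 / (1.0 + np.exp(-eta0))
    p1 = 1.0 / (1.0 + np.exp(-eta1))
    return ((p1 / p0) ** (1.0 / (t1 - t0)) - 1.0) * 100.0


def spline_trend(
    model: FlagModel, classification: Optional[str] = None
) -> pd.DataFrame:
    """Predicted flag probability per year (and group level), with CIs.

    Requires a model whose year term is a natural cubic spline (or
    linear, which the basis degenerates to at df=1).  Random effects are
    at zero; other factors are averaged with equal weights.
    """
    model.fit.require_converged()
    meta = model.meta
    if meta.year_kind is None:
        raise ValueError("model has no year term")
    if len(meta.years_c) < 3:
        raise ValueError("too few distinct years for a trend curve")
    beta = model.fit.coefficients.to_numpy()
    V = model.fit.vcov.to_numpy()
    if classification is not None and classification not in meta.factors:
        raise ValueError(f"{classification!r} is not a fixed factor of this model")
    levels = meta.factors[classification] if classification else [None]
    rows = []
    for lv in levels:
        at = {classification: lv} if lv is not None else None
        for t in meta.years_c:
            L = _emm_vector(model, at, float(t))
            eta = float(L @ beta)
            se = float(np.sqrt(L @ V @ L))
            p, lo, hi = _wald_interval_prob(eta, se)
            rows.append(
                dict(
                    group="global" if lv is None else str(lv),
                    year=int(round(t + meta.year_center)),
                    probability=p,
                    ci_low=lo,
                    ci_high=hi,
                )
            )
    return pd.DataFrame(rows)
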