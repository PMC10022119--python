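"""Binomial logistic mixed-effects models via the Laplace approximation.

Fits models of the form

    y_i ~ Bernoulli(p_i),   logit p_i = x_i' beta + z_i' b_{g(i)},
    b_g ~ N(0, D),          D = diag(sigma_1^2, ..., sigma_q^2),

where ``g(i)`` indexes the level-two grouping factor (here: country) and
the random-effect design ``z_i`` holds an intercept plus optional slopes
(year, vaccine-dose indicators).  Variance components are independent
(diagonal D), which keeps the optimizer stable at moderate panel sizes.

Estimation maximizes the Laplace-approximated marginal likelihood (one
quadrature point): for each candidate D, the joint penalized likelihood
is maximized over (beta, b) by Newton iterations with the random-effect
block solved per group via a Schur complement, and the profiled Laplace
log-likelihood

    l(beta, b_hat) - 1/2 sum_g b_hat_g' D^-1 b_hat_g
                   - 1/2 sum_g log det(I + D Z_g' W_g Z_g)

is optimized over log-sigma.  With all variances fixed at zero the
procedure reduces exactly to ordinary logistic regression.

The fixed-effect covariance is the inverse Schur complement at the
optimum (conditional on the estimated variance components), giving Wald
inference on the logit scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

__all__ = ["MixedLogitFit", "fit_binomial_glmm", "ConvergenceError"]

_SIGMA_FLOOR = 1e-4


class ConvergenceError(RuntimeError):
    """Raised when inference is requested from a non-converged fit."""


@dataclass
class MixedLogitFit:
    """Fitted mixed logistic model: estimates, covariance, variances."""

    coefficients: pd.Series
    vcov: pd.DataFrame
    random_sd: dict[str, float]
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    random_modes: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def require_converged(self) -> None:
        if not self.converged:
            raise ConvergenceError("model did not converge; refusing inference")

    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.vcov.values)), index=self.coefficients.index
        )


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _pirls(y, X, Z, groups, n_groups, d_inv, beta0, b0, max_iter=200, tol=1e-10):
    """Maximize the penalized log-likelihood over (beta, b) for fixed D.

    Returns (beta, b, pll, S, zwz, w, converged) where S is the Schur
    complement (observed information for beta) and zwz the per-group
    Z'WZ blocks, both at the mode.
    """
    n, p = X.shape
    q = Z.shape[1]
    beta = beta0.copy()
    b = b0.copy()

    def penalized(beta, b):
        eta = X @ beta + np.einsum("nq,nq->n", Z, b[groups])
        return _bernoulli_loglik(y, eta) - 0.5 * float(np.sum(b * b * np.diag(d_inv))), eta

    pll, eta = penalized(beta, b)
    S = zwz = w = None
    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        r = y - mu
        grad_beta = X.T @ r
        # per-group gradient for b
        Zr = Z * r[:, None]
        grad_b = np.zeros((n_groups, q))
        np.add.at(grad_b, groups, Zr)
        grad_b -= b @ d_inv

        WX = X * w[:, None]
        WZ = Z * w[:, None]
        A = X.T @ WX
        zwz = np.zeros((n_groups, q, q))
        np.add.at(zwz, groups, np.einsum("ni,nj->nij", Z, WZ))
        xwz = np.zeros((n_groups, p, q))
        np.add.at(xwz, groups, np.einsum("ni,nj->nij", X, WZ))
        cmat = zwz + d_inv[None, :, :]
        cinv = np.linalg.inv(cmat)
        S = A - np.einsum("cpq,cqr,csr->ps", xwz, cinv, xwz)
        rbeta = grad_beta - np.einsum("cpq,cqr,cr->p", xwz, cinv, grad_b)
        try:
            dbeta = np.linalg.solve(S, rbeta)
        except np.linalg.LinAlgError:
            dbeta = np.linalg.lstsq(S, rbeta, rcond=None)[0]
        db = np.einsum("cqr,cr->cq", cinv, grad_b - np.einsum("cpq,p->cq", xwz, dbeta))

        # step-halving line search on the penalized log-likelihood
        step = 1.0
        for _half in range(30):
            beta_new = beta + step * dbeta
            b_new = b + step * db
            pll_new, eta_new = penalized(beta_new, b_new)
            if pll_new >= pll - 1e-12:
                break
            step *= 0.5
        improved = pll_new - pll
        beta, b, eta = beta_new, b_new, eta_new
        if abs(improved) < tol * (1.0 + abs(pll_new)):
            pll = pll_new
            converged = True
            break
        pll = pll_new
    # refresh curvature at the final mode
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    WZ = Z * w[:, None]
    zwz = np.zeros((n_groups, q, q))
    np.add.at(zwz, groups, np.einsum("ni,nj->nij", Z, WZ))
    xwz = np.zeros((n_groups, X.shape[1], q))
    np.add.at(xwz, groups, np.einsum("ni,nj->nij", X, WZ))
    cinv = np.linalg.inv(zwz + d_inv[None, :, :])
    S = X.T @ (X * w[:, None]) - np.einsum("cpq,cqr,csr->ps", xwz, cinv, xwz)
    return beta, b, pll, S, zwz, converged


def _plain_logistic(y, X, max_iter=100, tol=1e-12):
    """Newton fit of ordinary logistic regression (the sigma -> 0 limit)."""
    beta = np.zeros(X.shape[1])
    ll = _bernoulli_loglik(y, X @ beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        H = X.T @ (X * w[:, None])
        g = X.T @ (y - mu)
        try:
            step_dir = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step_dir = np.linalg.lstsq(H, g, rcond=None)[0]
        step = 1.0
        for _half in range(30):
            beta_new = beta + step * step_dir
            ll_new = _bernoulli_loglik(y, X @ beta_new)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        if abs(ll_new - ll) < tol * (1 + abs(ll_new)):
            beta, ll = beta_new, ll_new
            converged = True
            break
        beta, ll = beta_new, ll_new
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    H = X.T @ (X * w[:, None])
    return beta, ll, np.linalg.inv(H), converged


def fit_binomial_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    Z: Optional[np.ndarray] = None,
    fixed_names: Optional[Sequence[str]] = None,
    random_names: Optional[Sequence[str]] = None,
    start_sigma: float | Sequence[float] = 0.5,
    fix_sigma: Optional[Sequence[float]] = None,
    sigma_upper: float = 20.0,
) -> MixedLogitFit:
    """Fit the mixed logistic model by Laplace-approximated ML.

    Parameters
    ----------
    y, X, groups
        Binary outcome, fixed-effect design, and integer group codes.
    Z
        Per-observation random-effect design (default: intercept only).
    fix_sigma
        If given, the random-effect standard deviations are held fixed
        (zeros reduce the model to ordinary logistic regression).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    codes, groups = np.unique(groups, return_inverse=True)
    n_groups = len(codes)
    n, p = X.shape
    if fixed_names is None:
        fixed_names = [f"x{i}" for i in range(p)]
    if Z is None:
        Z = np.ones((n, 1))
    Z = np.asarray(Z, dtype=float)
    q = Z.shape[1]
    if random_names is None:
        random_names = ["intercept"] + [f"z{i}" for i in range(1, q)]
    if n_groups < 2:
        raise ValueError("need at least 2 groups to fit a mixed model")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")

    # sigma fixed at zero for every component: plain logistic regression
    if fix_sigma is not None and np.all(np.asarray(fix_sigma, dtype=float) == 0.0):
        beta, ll, vb, conv = _plain_logistic(y, X)
        return MixedLogitFit(
            coefficients=pd.Series(beta, index=list(fixed_names)),
            vcov=pd.DataFrame(vb, index=list(fixed_names), columns=list(fixed_names)),
            random_sd={nm: 0.0 for nm in random_names},
            loglik=ll,
            converged=conv,
            n_obs=n,
            n_groups=n_groups,
            random_modes=np.zeros((n_groups, q)),
        )

    state = {"beta": np.zeros(p), "b": np.zeros((n_groups, q))}
    eye_q = np.eye(q)

    def laplace_negloglik(log_sigma: np.ndarray) -> float:
        sigma = np.exp(log_sigma)
        d_inv = np.diag(1.0 / np.maximum(sigma, 1e-12) ** 2)
        beta, b, pll, S, zwz, conv = _pirls(
            y, X, Z, groups, n_groups, d_inv, state["beta"], state["b"]
        )
        state["beta"], state["b"] = beta, b
        D = np.diag(sigma**2)
        sign, logdet = np.linalg.slogdet(eye_q[None, :, :] + zwz @ D)
        ll = pll - 0.5 * float(np.sum(logdet))
        return -ll

    if fix_sigma is not None:
        log_sigma_hat = np.log(np.maximum(np.asarray(fix_sigma, dtype=float), _SIGMA_FLOOR))
        outer_ok = True
    else:
        s0 = np.asarray(start_sigma, dtype=float)
        if s0.ndim == 0:
            s0 = np.full(q, float(s0))
        x0 = np.log(np.clip(s0, _SIGMA_FLOOR, sigma_upper))
        bounds = [(np.log(_SIGMA_FLOOR), np.log(sigma_upper))] * q
        res = optimize.minimize(
            laplace_negloglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-9},
        )
        log_sigma_hat = res.x
        outer_ok = bool(res.success)
        if not outer_ok:
            # the profiled objective carries tiny warm-start noise that can
            # abort L-BFGS-B line searches; Nelder-Mead is robust to it
            res2 = optimize.minimize(
                laplace_negloglik,
                res.x,
                method="Nelder-Mead",
                options={"maxiter": 400, "fatol": 1e-7, "xatol": 1e-6},
            )
            if res2.fun <= res.fun + 1e-6:
                log_sigma_hat = np.clip(res2.x, np.log(_SIGMA_FLOOR), np.log(sigma_upper))
                outer_ok = bool(res2.success)

    sigma_hat = np.exp(log_sigma_hat)
    floored = sigma_hat <= _SIGMA_FLOOR * 1.5
    if np.any(floored) and fix_sigma is None:
        warnings.warn(
            "random-effect variance estimate at the boundary; floored at 0 for: "
            + ", ".join(np.asarray(random_names)[floored]),
            RuntimeWarning,
        )
    neg_ll = laplace_negloglik(log_sigma_hat)
    d_inv = np.diag(1.0 / np.maximum(sigma_hat, 1e-12) ** 2)
    beta, b, pll, S, zwz, inner_ok = _pirls(
        y, X, Z, groups, n_groups, d_inv, state["beta"], state["b"]
    )
    vcov = np.linalg.inv(S)
    sd_out = {
        nm: (0.0 if fl else float(s))
        for nm, s, fl in zip(random_names, sigma_hat, floored)
    }
    return MixedLogitFit(
        coefficients=pd.Series(beta, index=list(fixed_names)),
        vcov=pd.DataFrame(vcov, index=list(fixed_names), columns=list(fixed_names)),
        random_sd=sd_out,
        loglik=-neg_ll,
        converged=bool(outer_ok and inner_ok),
        n_obs=n,
        n_groups=n_groups,
        random_modes=b,
    )
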