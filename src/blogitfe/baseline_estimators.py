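"""Comparison estimators: dummy-variable binomial logit and pooled logit.

The dummy-variable (DV) estimator maximises the full binomial likelihood
jointly in the slopes and one intercept per unit.  With T fixed this is the
textbook incidental-parameters situation: the estimator is inconsistent,
with an upward bias that shrinks as T and K grow.  Units whose outcome sits
at the same boundary in every period are perfectly predicted (their
intercept diverges) and are dropped up front — the same rule that removes
non-informative units from the conditional ML fit, so all estimators can
share one estimation sample.

The pooled logit simply replaces every unit intercept with a common one,
ignoring unit heterogeneity altogether; it is inconsistent whenever the
effects are correlated with the covariates or heterogeneity is present.

The DV fit concentrates the intercepts out: for fixed slopes each unit's
intercept solves a one-dimensional monotone score equation (safeguarded
Newton, vectorised across units), and a quasi-Newton iteration updates the
slopes on the profile likelihood, whose gradient is the plain score by the
envelope theorem.  This scales to Monte Carlo use where a dense (N+p)
parameter solve would not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from .cml import EstimationError, informative_subset
from .panel_model import PanelDataset, log_binom_coeff

__all__ = ["DVFit", "EstimatorFit", "fit_blogit_dv", "fit_pooled_logit"]


@dataclass
class DVFit:
    """Binomial logit with unit dummies (joint MLE of slopes and intercepts)."""

    beta_hat: np.ndarray
    alpha_hat: dict
    vcov: np.ndarray
    n_units_dropped_perfect: int
    converged: bool
    loglik: float
    covariate_names: Sequence[str]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


@dataclass
class EstimatorFit:
    """Generic fit container (used by the pooled logit)."""

    beta_hat: np.ndarray
    vcov: np.ndarray
    converged: bool
    loglik: float
    covariate_names: Sequence[str]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


def _solve_alphas(Y_sum, KT_len, eta_sums_fn, alpha0, K, tol=1e-12, maxiter=200):
    """Per-unit intercepts given slopes: solve sum_t (Y - K*Lambda) = 0.

    ``eta_sums_fn(alpha)`` must return per-unit sums of Lambda and
    Lambda*(1-Lambda) at the current intercepts.  The score is strictly
    decreasing in alpha, so Newton with step clipping converges globally;
    ``tol`` is an absolute bound on the per-unit score.
    """
    alpha = alpha0.copy()
    for _ in range(maxiter):
        lam_sum, w_sum = eta_sums_fn(alpha)
        f = Y_sum - K * lam_sum
        if np.max(np.abs(f)) < tol:
            break
        step = f / np.maximum(K * w_sum, 1e-12)
        alpha += np.clip(step, -10.0, 10.0)
    return alpha


def fit_blogit_dv(
    data: PanelDataset,
    gtol: float = 1e-8,
    maxiter: int = 200,
    drop_perfect: bool = True,
    small_sample_correction: bool = True,
) -> DVFit:
    """Fit the binomial logit with one dummy per unit (profile likelihood).

    Perfectly predicted units (total 0 or ``K*T_i``) are dropped first.  The
    covariance is a cluster-robust sandwich in the slope block, with the
    intercepts concentrated out.
    """
    if drop_perfect:
        filtered, dropped = informative_subset(data)
    else:
        filtered, dropped = data, []
    ds = filtered.sorted_by_unit_time()
    K = ds.K
    codes = ds.unit_codes
    G = ds.n_units
    p = ds.n_covariates
    X, Y = ds.X, ds.Y
    Y_sum = np.bincount(codes, weights=Y, minlength=G)
    T_len = np.bincount(codes, minlength=G)

    # identification: every covariate must vary within at least one unit
    starts = np.concatenate([[0], np.cumsum(T_len)[:-1]])
    bad = [
        name
        for j, name in enumerate(ds.covariate_names)
        if np.all(
            np.maximum.reduceat(X[:, j], starts) - np.minimum.reduceat(X[:, j], starts)
            == 0
        )
    ]
    if bad:
        raise EstimationError(
            f"covariates {bad} are constant within every unit and are "
            "absorbed by the unit dummies; beta is not identified"
        )

    state = {"alpha": np.zeros(G)}

    def profile(beta):
        eta0 = X @ beta

        def sums(alpha):
            lam = expit(eta0 + alpha[codes])
            return (
                np.bincount(codes, weights=lam, minlength=G),
                np.bincount(codes, weights=lam * (1 - lam), minlength=G),
            )

        alpha = _solve_alphas(Y_sum, T_len, sums, state["alpha"], K)
        state["alpha"] = alpha
        lam = expit(eta0 + alpha[codes])
        ll = float(np.sum(Y * np.log(lam) + (K - Y) * np.log1p(-lam)))
        resid = Y - K * lam
        grad = X.T @ resid  # envelope theorem: alpha-derivatives vanish
        return -ll, -grad, resid

    res = minimize(
        lambda b: profile(b)[:2],
        np.zeros(p),
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    beta_hat = np.asarray(res.x, dtype=float)
    n_iter = int(res.nit)

    # polish with damped Newton on the profile score (BFGS line searches
    # stop on rounding noise before reaching tight gradient tolerances)
    nll, neg_grad, resid = profile(beta_hat)
    gnorm = float(np.max(np.abs(neg_grad)))
    hstep = 1e-6 * (1.0 + np.abs(beta_hat))
    polish = 0
    while gnorm > gtol and n_iter + polish < maxiter and polish < 25:
        Hp = np.empty((p, p))
        for j in range(p):
            bp, bm = beta_hat.copy(), beta_hat.copy()
            bp[j] += hstep[j]
            bm[j] -= hstep[j]
            Hp[:, j] = (profile(bp)[1] - profile(bm)[1]) / (2 * hstep[j])
        try:
            step = np.linalg.solve(0.5 * (Hp + Hp.T), -neg_grad)
        except np.linalg.LinAlgError:
            break
        scale, improved = 1.0, False
        for _ in range(8):
            cand = beta_hat + scale * step
            nll_c, g_c, resid_c = profile(cand)
            if float(np.max(np.abs(g_c))) < gnorm or nll_c < nll:
                beta_hat, nll, neg_grad, resid = cand, nll_c, g_c, resid_c
                gnorm = float(np.max(np.abs(neg_grad)))
                improved = True
                break
            scale *= 0.5
        polish += 1
        if not improved:
            break

    converged = bool(gnorm <= max(gtol, 1e-6 * (1.0 + abs(nll))))
    if not converged:
        warnings.warn(
            f"Blogit DV did not converge after {n_iter + polish} iterations",
            RuntimeWarning,
        )

    # clustered sandwich on the profile score
    h = 1e-5 * (1.0 + np.abs(beta_hat))
    H = np.empty((p, p))
    for j in range(p):
        bp, bm = beta_hat.copy(), beta_hat.copy()
        bp[j] += h[j]
        bm[j] -= h[j]
        H[:, j] = (-profile(bp)[1] - (-profile(bm)[1])) / (2 * h[j])
    H = 0.5 * (H + H.T)
    scores = np.zeros((G, p))
    np.add.at(scores, codes, X * resid[:, None])
    try:
        bread = np.linalg.inv(-H)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular profile Hessian in the DV fit") from exc
    factor = G / (G - 1) if (small_sample_correction and G > 1) else 1.0
    vcov = factor * bread @ (scores.T @ scores) @ bread
    vcov = 0.5 * (vcov + vcov.T)

    profile(beta_hat)  # restore the intercepts at the optimum (the Hessian
    # differencing above left state["alpha"] at a perturbed slope vector)
    units = ds.unique_units()
    alpha_hat = {u: float(a) for u, a in zip(units, state["alpha"])}
    ll_full = -nll + float(np.sum(log_binom_coeff(K, Y)))
    return DVFit(
        beta_hat=beta_hat,
        alpha_hat=alpha_hat,
        vcov=vcov,
        n_units_dropped_perfect=len(dropped),
        converged=converged,
        loglik=ll_full,
        covariate_names=list(ds.covariate_names),
    )


def fit_pooled_logit(
    data: PanelDataset,
    add_intercept: bool = True,
    cluster: bool = True,
) -> EstimatorFit:
    """Pooled binomial logit with a common intercept (no unit effects).

    Delegates to a binomial GLM with logit link; standard errors are
    clustered at the unit level by default.  Coefficient order is the
    covariates followed by ``const`` when an intercept is added.
    """
    exog = data.X
    names = list(data.covariate_names)
    if add_intercept:
        exog = np.column_stack([exog, np.ones(data.n_obs)])
        names = names + ["const"]
    endog = np.column_stack([data.Y, data.K - data.Y])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if cluster:
            res = model.fit(cov_type="cluster", cov_kwds={"groups": data.unit_codes})
        else:
            res = model.fit()
    converged = bool(res.converged) if hasattr(res, "converged") else True
    if not converged:
        warnings.warn("pooled logit did not converge (possible separation)",
                      RuntimeWarning)
    return EstimatorFit(
        beta_hat=np.asarray(res.params),
        vcov=np.asarray(res.cov_params()),
        converged=converged,
        loglik=float(res.llf),
        covariate_names=names,
    )
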