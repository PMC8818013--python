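"""Conditional maximum likelihood for the fixed-effects binomial logit.

Conditioning each unit's outcome sequence on its total ``S_i = sum_t Y_it``
eliminates the fixed effect: the conditional probability is

    f(Y_i1..Y_iT | S_i) = exp(sum_t Y_it eta_it) * prod_t C(K, Y_it) / D_i(S_i)

where ``eta_it = x_it' beta`` and ``D_i(S)`` is the coefficient of ``z^S`` in
the generating polynomial ``prod_t (1 + z e^{eta_it})^K``.  The coefficient is
computed by sequential polynomial multiplication carried out entirely in log
space with log-sum-exp accumulation, so the recursion is overflow-safe for
``K*T`` in the hundreds.  The same prefix/suffix products yield the
conditional expectations ``E(q_t | S)`` needed for the analytic score.

Units whose total is 0 or ``K*T_i`` have conditional probability one and are
dropped before estimation.  A clone-expansion route (each observation becomes
``K`` Bernoulli rows) reproduces the estimator through a conditional *binary*
logit and is kept as an equivalent implementation path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp
from scipy.optimize import minimize

from .panel_model import PanelDataset, log_binom_coeff

__all__ = [
    "EstimationError",
    "GroupConditioningState",
    "ExpandedBernoulliData",
    "CMLFit",
    "informative_subset",
    "group_cond_loglik",
    "brute_force_cond_loglik",
    "cond_loglik",
    "cond_score",
    "fit_blogit_cml",
    "expand_to_bernoulli",
    "fit_blogit_cml_via_expansion",
]

_NEG_INF = -np.inf


class EstimationError(RuntimeError):
    """Raised when a fit is structurally impossible (no informative units,
    collinear covariates, infeasible expansion, ...)."""


# ---------------------------------------------------------------------------
# log-space polynomial arithmetic (batched over groups)
# ---------------------------------------------------------------------------

def _lse_last(W: np.ndarray) -> np.ndarray:
    """log-sum-exp along the last axis; all ``-inf`` rows stay ``-inf``."""
    m = np.max(W, axis=-1)
    finite = m > _NEG_INF
    safe_m = np.where(finite, m, 0.0)
    s = np.einsum("...q->...", np.exp(W - safe_m[..., None]))
    with np.errstate(divide="ignore"):
        out = safe_m + np.log(s)
    return np.where(finite, out, _NEG_INF)


def _logconv(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Log-space product of batched polynomials.

    ``A`` has shape ``(G, m)`` and ``B`` shape ``(G, n)`` holding log
    coefficients; returns ``(G, m+n-1)`` with
    ``out[g, d] = logsumexp_a A[g, a] + B[g, d-a]``.
    """
    if A.shape[1] > B.shape[1]:  # slide the shorter operand
        A, B = B, A
    G, m = A.shape
    n = B.shape[1]
    Bp = np.full((G, n + 2 * (m - 1)), _NEG_INF)
    if m > 1:
        Bp[:, m - 1 : m - 1 + n] = B
    else:
        Bp = B
    # window j at degree d pairs A[m-1-j] with B[d-m+1+j]
    W = sliding_window_view(Bp, m, axis=1)  # (G, m+n-1, m)
    return _lse_last(W + A[:, None, ::-1])


def _factor_logcoeffs(eta: np.ndarray, K: int) -> np.ndarray:
    """Log coefficients of ``(1 + z e^eta)^K`` per period.

    ``eta`` has shape ``(G, T)``; returns ``(G, T, K+1)`` with entry
    ``log C(K, q) + q * eta``.
    """
    q = np.arange(K + 1)
    logc = log_binom_coeff(K, q)
    return logc[None, None, :] + q[None, None, :] * eta[:, :, None]


def _bucket_logdenom(eta: np.ndarray, S: np.ndarray, K: int,
                     expectations: bool = False):
    """Log-denominators (and conditional expectations) for a balanced bucket.

    Parameters
    ----------
    eta : (G, T) linear indices, S : (G,) group totals, K : trials.

    Returns ``logdenom`` of shape ``(G,)`` and, when ``expectations`` is set,
    ``Eq`` of shape ``(G, T)`` with ``Eq[g, t] = E(q_t | S_g)``.
    """
    G, T = eta.shape
    S = np.asarray(S, dtype=np.int64)
    F = _factor_logcoeffs(eta, K)
    rows = np.arange(G)

    prefix = [np.zeros((G, 1))]
    for t in range(T):
        prefix.append(_logconv(prefix[-1], F[:, t, :]))
    logdenom = prefix[T][rows, S]
    if not expectations:
        return logdenom, None

    suffix = [None] * (T + 1)
    suffix[T] = np.zeros((G, 1))
    for t in range(T - 1, -1, -1):
        suffix[t] = _logconv(suffix[t + 1], F[:, t, :])

    q = np.arange(K + 1)
    Eq = np.empty((G, T))
    for t in range(T):
        # leave-one-out coefficient at degree S - q only (a band of K+1
        # degrees per group), not the full product polynomial:
        # L[g, q] = lse_a prefix[t][g, a] + suffix[t+1][g, S_g - q - a]
        A, B = prefix[t], suffix[t + 1]
        m, n = A.shape[1], B.shape[1]
        idx = S[:, None, None] - q[None, :, None] - np.arange(m)[None, None, :]
        valid = (idx >= 0) & (idx < n)
        Bv = np.where(valid, B[rows[:, None, None], np.clip(idx, 0, n - 1)], _NEG_INF)
        L = _lse_last(A[:, None, :] + Bv)  # (G, K+1)
        p = np.exp(F[:, t, :] + L - logdenom[:, None])
        Eq[:, t] = p @ q
    return logdenom, Eq


# ---------------------------------------------------------------------------
# grouped view of a dataset, bucketed by panel length
# ---------------------------------------------------------------------------

class _GroupedPanel:
    """Reshape a (unit, time)-sorted panel into per-``T`` batched arrays."""

    def __init__(self, data: PanelDataset):
        ds = data.sorted_by_unit_time()
        self.K = ds.K
        self.p = ds.n_covariates
        lengths = ds.unit_lengths()
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        self.n_units = len(lengths)
        self.buckets = []
        self._unit_order = []  # unit codes per bucket, to reassemble scores
        for T in np.unique(lengths):
            codes = np.flatnonzero(lengths == T)
            rows = starts[codes][:, None] + np.arange(T)[None, :]
            Y = ds.Y[rows]                       # (G, T)
            X = ds.X[rows.ravel()].reshape(len(codes), T, self.p)
            self.buckets.append((int(T), codes, Y, X))
            self._unit_order.append(codes)
        self._const = sum(
            float(np.sum(log_binom_coeff(self.K, Y))) for _, _, Y, _ in self.buckets
        )

    def loglik(self, beta: np.ndarray) -> float:
        total = self._const
        for T, _, Y, X in self.buckets:
            eta = X @ beta
            S = Y.sum(axis=1)
            logdenom, _ = _bucket_logdenom(eta, S, self.K)
            total += float(np.sum(Y * eta) - np.sum(logdenom))
        return total

    def loglik_and_unit_scores(self, beta: np.ndarray):
        """One pass over the buckets giving the value and per-unit scores."""
        total = self._const
        out = np.empty((self.n_units, self.p))
        for (T, codes, Y, X) in self.buckets:
            eta = X @ beta
            S = Y.sum(axis=1)
            logdenom, Eq = _bucket_logdenom(eta, S, self.K, expectations=True)
            total += float(np.sum(Y * eta) - np.sum(logdenom))
            out[codes] = np.einsum("gt,gtp->gp", Y - Eq, X)
        return total, out

    def unit_scores(self, beta: np.ndarray) -> np.ndarray:
        """Per-unit score contributions, stacked in unit-code order."""
        return self.loglik_and_unit_scores(beta)[1]

    def score(self, beta: np.ndarray) -> np.ndarray:
        return self.unit_scores(beta).sum(axis=0)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def informative_subset(data: PanelDataset):
    """Drop units whose total is 0 or ``K*T_i`` (conditional probability 1).

    Returns the remaining dataset and the list of dropped unit identifiers.
    """
    totals = data.unit_totals()
    lengths = data.unit_lengths()
    keep = (totals > 0) & (totals < data.K * lengths)
    units = data.unique_units()
    dropped = list(units[~keep])
    if not keep.any():
        raise EstimationError(
            "no informative units: every unit's total is 0 or K*T_i, "
            "so all conditional probabilities are one"
        )
    return data.select_units(keep), dropped


@dataclass
class GroupConditioningState:
    """Per-unit conditioning state: linear indices, total, and the log-scale
    coefficients of ``prod_t (1 + z e^{eta_t})^K``."""

    eta: np.ndarray
    K: int
    S: int
    unit_id: object = None
    log_coeffs: np.ndarray = field(default=None)

    def __post_init__(self):
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        if self.log_coeffs is None:
            F = _factor_logcoeffs(self.eta[None, :], self.K)
            poly = np.zeros((1, 1))
            for t in range(self.eta.size):
                poly = _logconv(poly, F[:, t, :])
            self.log_coeffs = poly[0]

    @property
    def T(self) -> int:
        return self.eta.size

    @classmethod
    def from_counts(cls, eta, Y, K, unit_id=None) -> "GroupConditioningState":
        return cls(eta=np.asarray(eta, float), K=K, S=int(np.sum(Y)), unit_id=unit_id)


def group_cond_loglik(group: GroupConditioningState, Y_t) -> float:
    """Conditional log-likelihood of one unit's sequence given its total.

    ``sum_t [Y_t eta_t + log C(K, Y_t)] - log D(S)`` where ``log D(S)`` is the
    degree-``S`` log coefficient of the group's generating polynomial.
    """
    Y = np.atleast_1d(np.asarray(Y_t, dtype=np.int64))
    S = int(Y.sum())
    if S != group.S:
        raise ValueError(f"sum of counts ({S}) does not match group total ({group.S})")
    if not (0 < S < group.K * group.T):
        raise ValueError(
            f"group total {S} is at the boundary of [0, {group.K * group.T}]; "
            "such units are non-informative and should have been filtered"
        )
    num = float(np.sum(Y * group.eta) + np.sum(log_binom_coeff(group.K, Y)))
    return num - float(group.log_coeffs[S])


def _compositions(S: int, T: int, K: int):
    """Yield all ``(q_1..q_T)`` with ``0 <= q_t <= K`` and ``sum q_t = S``."""
    if T == 1:
        if 0 <= S <= K:
            yield (S,)
        return
    lo = max(0, S - K * (T - 1))
    hi = min(K, S)
    for q in range(lo, hi + 1):
        for rest in _compositions(S - q, T - 1, K):
            yield (q,) + rest


def _n_compositions(S: int, T: int, K: int) -> int:
    # integer DP on the counting polynomial (1 + z + ... + z^K)^T
    coeffs = np.zeros(K * T + 1, dtype=object)
    coeffs[0] = 1
    row = np.ones(K + 1, dtype=object)
    poly = np.array([1], dtype=object)
    for _ in range(T):
        poly = np.convolve(poly, row)
    return int(poly[S])


def brute_force_cond_loglik(group: GroupConditioningState, Y_t,
                            max_terms: int = 1_000_000) -> float:
    """Reference implementation: explicit enumeration of the composition set.

    Sums ``prod_t C(K, q_t) exp(q_t eta_t)`` over all compositions of the
    group total; intended for testing on small instances only.
    """
    Y = np.atleast_1d(np.asarray(Y_t, dtype=np.int64))
    S = int(Y.sum())
    K, T = group.K, group.T
    if _n_compositions(S, T, K) > max_terms:
        raise EstimationError(
            f"composition set too large to enumerate (> {max_terms} terms)"
        )
    terms = []
    for qs in _compositions(S, T, K):
        q = np.asarray(qs, dtype=float)
        terms.append(float(np.sum(log_binom_coeff(K, q) + q * group.eta)))
    num = float(np.sum(Y * group.eta) + np.sum(log_binom_coeff(K, Y)))
    return num - float(logsumexp(np.asarray(terms)))


def cond_loglik(data: PanelDataset, beta) -> float:
    """Total conditional log-likelihood over all informative units."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    return _GroupedPanel(data).loglik(beta)


def cond_score(data: PanelDataset, beta) -> np.ndarray:
    """Analytic score ``sum_i [sum_t Y_t x_t - E(sum_t q_t x_t | S_i)]``.

    ``data`` must already be filtered to informative units.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    return _GroupedPanel(data).score(beta)


@dataclass
class CMLFit:
    """Result of a conditional ML fit."""

    beta_hat: np.ndarray
    vcov: np.ndarray
    cond_loglik: float
    n_units_used: int
    n_units_dropped_noninformative: int
    converged: bool
    n_iterations: int
    gradient_norm_at_optimum: float
    covariate_names: Sequence[str]
    method: str = "direct"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def summary(self) -> str:
        lines = [
            f"Blogit CML fit ({self.method}); "
            f"{self.n_units_used} units used, "
            f"{self.n_units_dropped_noninformative} dropped (boundary totals)",
            f"conditional log-likelihood: {self.cond_loglik:.4f}",
            f"{'covariate':<16}{'coef':>12}{'cluster se':>12}",
        ]
        for name, b, s in zip(self.covariate_names, self.beta_hat, self.se):
            lines.append(f"{name:<16}{b:>12.4f}{s:>12.4f}")
        return "\n".join(lines)


def _check_time_varying(data: PanelDataset) -> None:
    ds = data.sorted_by_unit_time()
    lengths = ds.unit_lengths()
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    bad = []
    for j, name in enumerate(ds.covariate_names):
        col = ds.X[:, j]
        mx = np.maximum.reduceat(col, starts)
        mn = np.minimum.reduceat(col, starts)
        if np.all(mx - mn == 0):
            bad.append(name)
    if bad:
        raise EstimationError(
            f"covariates {bad} are time-invariant within every unit; they are "
            "absorbed by the fixed effects and cannot be identified — exclude "
            "them or interact them with time-varying variables"
        )


def _sandwich_vcov(grouped: _GroupedPanel, beta: np.ndarray,
                   small_sample: bool = True) -> np.ndarray:
    p = beta.size
    H = np.empty((p, p))
    h = 1e-5 * (1.0 + np.abs(beta))
    for j in range(p):
        bp, bm = beta.copy(), beta.copy()
        bp[j] += h[j]
        bm[j] -= h[j]
        H[:, j] = (grouped.score(bp) - grouped.score(bm)) / (2 * h[j])
    H = 0.5 * (H + H.T)  # Hessian of the conditional log-likelihood (negative definite)
    scores = grouped.unit_scores(beta)
    meat = scores.T @ scores
    try:
        bread = np.linalg.inv(-H)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "singular Hessian at the optimum; covariates are collinear within "
            "the conditional likelihood"
        ) from exc
    G = grouped.n_units
    factor = G / (G - 1) if (small_sample and G > 1) else 1.0
    V = factor * bread @ meat @ bread
    return 0.5 * (V + V.T)


def fit_blogit_cml(
    data: PanelDataset,
    start: Optional[np.ndarray] = None,
    gtol: float = 1e-8,
    maxiter: int = 200,
    small_sample_correction: bool = True,
) -> CMLFit:
    """Fit the fixed-effects binomial logit by conditional ML.

    Quasi-Newton (BFGS) maximisation of the conditional log-likelihood with
    the analytic score, started at ``beta = 0``.  The covariance is a
    cluster-robust sandwich over per-unit score contributions with a
    ``G/(G-1)`` small-sample factor.
    """
    filtered, dropped = informative_subset(data)
    _check_time_varying(filtered)
    grouped = _GroupedPanel(filtered)
    p = filtered.n_covariates
    x0 = np.zeros(p) if start is None else np.asarray(start, dtype=float)

    def fused(b):
        ll, scores = grouped.loglik_and_unit_scores(b)
        return -ll, -scores.sum(axis=0)

    res = minimize(fused, x0, jac=True, method="BFGS",
                   options={"gtol": gtol, "maxiter": maxiter})
    beta_hat = np.asarray(res.x, dtype=float)
    n_iter = int(res.nit)

    # BFGS line searches stall on rounding noise well before |score| ~ 1e-8;
    # finish with damped Newton steps on the analytic score.
    ll, g = grouped.loglik(beta_hat), grouped.score(beta_hat)
    gnorm = float(np.max(np.abs(g)))
    h = 1e-6 * (1.0 + np.abs(beta_hat))
    polish = 0
    while gnorm > gtol and n_iter + polish < maxiter and polish < 25:
        H = np.empty((p, p))
        for j in range(p):
            bp, bm = beta_hat.copy(), beta_hat.copy()
            bp[j] += h[j]
            bm[j] -= h[j]
            H[:, j] = (grouped.score(bp) - grouped.score(bm)) / (2 * h[j])
        try:
            step = np.linalg.solve(-0.5 * (H + H.T), g)
        except np.linalg.LinAlgError:
            break
        scale, improved = 1.0, False
        for _ in range(8):
            cand = beta_hat + scale * step
            ll_c, g_c = grouped.loglik(cand), grouped.score(cand)
            if float(np.max(np.abs(g_c))) < gnorm or ll_c > ll:
                beta_hat, ll, g = cand, ll_c, g_c
                gnorm = float(np.max(np.abs(g)))
                improved = True
                break
            scale *= 0.5
        polish += 1
        if not improved:
            break

    converged = bool(gnorm <= max(gtol, 1e-6 * (1.0 + abs(ll))))
    if not converged:
        import warnings

        warnings.warn(
            f"Blogit CML did not converge after {n_iter + polish} iterations "
            f"(|score| = {gnorm:.2e})",
            RuntimeWarning,
        )
    vcov = _sandwich_vcov(grouped, beta_hat, small_sample_correction)
    return CMLFit(
        beta_hat=beta_hat,
        vcov=vcov,
        cond_loglik=float(ll),
        n_units_used=grouped.n_units,
        n_units_dropped_noninformative=len(dropped),
        converged=converged,
        n_iterations=n_iter + polish,
        gradient_norm_at_optimum=gnorm,
        covariate_names=list(filtered.covariate_names),
    )


@dataclass
class ExpandedBernoulliData:
    """Clone expansion of a binomial panel into ``K`` Bernoulli rows per
    observation (successes first), preserving unit and time labels."""

    data: PanelDataset        # K=1 panel with K rows per original observation
    original_row: np.ndarray  # index of the source row for each clone
    clone_index: np.ndarray   # j = 0..K-1 within each source row
    K_original: int = 0


def expand_to_bernoulli(data: PanelDataset) -> ExpandedBernoulliData:
    """Expand each observation into ``K`` binary indicator rows.

    Row with count ``Y`` becomes ``Y`` ones followed by ``K - Y`` zeros with
    unchanged covariates; the conditional likelihood of the expansion differs
    from the direct binomial one only by the constant ``sum log C(K, Y)``.
    """
    K = data.K
    n = data.n_obs
    orig = np.repeat(np.arange(n), K)
    j = np.tile(np.arange(K), n)
    d = (j < data.Y[orig]).astype(np.int64)
    # encode (time, clone) as a compound label to keep (unit, time) pairs unique
    time_clone = np.char.add(
        np.char.add(data.time_ids[orig].astype(str), "#"), j.astype(str)
    )
    expanded = PanelDataset(
        unit_ids=data.unit_ids[orig],
        time_ids=time_clone,
        K=1,
        Y=d,
        X=data.X[orig],
        covariate_names=data.covariate_names,
    )
    return ExpandedBernoulliData(
        data=expanded, original_row=orig, clone_index=j, K_original=K
    )


def fit_blogit_cml_via_expansion(
    data: PanelDataset,
    max_rows: int = 2_000_000,
    **fit_kwargs,
) -> CMLFit:
    """Fit via the clone expansion: conditional *binary* logit on ``K``
    replicated rows per observation, conditioning each unit on its grand
    total.  Produces the same coefficient estimates as the direct path; the
    reported conditional log-likelihood omits the ``sum log C(K, Y)``
    constant, as the Bernoulli form does.
    """
    if data.K * data.n_obs > max_rows:
        raise EstimationError(
            f"expansion would create {data.K * data.n_obs} rows "
            f"(> {max_rows}); use the direct path fit_blogit_cml instead"
        )
    expanded = expand_to_bernoulli(data)
    fit = fit_blogit_cml(expanded.data, **fit_kwargs)
    fit.method = "expansion"
    return fit
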