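"""Tests of the binomial (no-overdispersion) null for panel proportions.

The conditional ML estimator never estimates the unit effects, so classical
dispersion tests that need fitted conditional variances are unavailable.
The test implemented here works on within-unit differences instead.  For a
pair of periods with equal success probabilities, the squared difference of
counts ``(Y_1 - Y_2)^2`` has binomial-implied expectation that can be
estimated without the fixed effect by comparing it against auxiliary
Bernoulli draws ``M_t ~ Bernoulli(y_t)``:

    z = [ (Y_1 - Y_2)^2 - K (M_1 - M_2)^2 ] / [ K (K-1) ]

has expectation ``(Lambda_1 - Lambda_2)^2`` under the binomial null — zero
whenever the two periods share the same mean — and a positive expectation
under overdispersion.

Variants:

* discrete two-period: average ``z`` over the matched set
  ``A = {i : x_i1 = x_i2}`` and use a normal t-ratio;
* kernel two-period: Gaussian-kernel weighting in the estimated index
  difference ``Delta_i = (x_i1 - x_i2)' beta_hat`` with plug-in bias and
  variance corrections (rule-of-thumb bandwidth ``0.9 n^{-1/5}`` on the
  standardised differences);
* multi-period: one moment per consecutive period pair, combined into a
  chi-square statistic ``J = (sqrt(n) o gbar)' S^-1 (sqrt(n) o gbar)`` with
  ``T - 1`` degrees of freedom.  For the discrete variant the off-diagonal
  elements of ``S`` are poorly estimated in small samples (they rest on
  units matched in overlapping pairs), so the default uses the diagonal.

The auxiliary draws make the statistic itself stochastic; by default a
single seeded draw is used.  Passing ``m_draws > 1`` averages ``z`` over
independent draws, an extension that only reduces auxiliary noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .panel_model import PanelDataset

__all__ = [
    "DispersionTestResult",
    "KernelConfig",
    "draw_success_indicators",
    "z_statistic",
    "discrete_two_period_test",
    "kernel_two_period_test",
    "multi_period_test",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class KernelConfig:
    """Gaussian kernel settings for the continuous-covariate variant."""

    bandwidth_scale: float = 0.9   # h = scale * n^(-1/5) on standardised Delta
    mu2: float = 1.0               # second moment of the standard Gaussian

    def bandwidth(self, n: int) -> float:
        h = self.bandwidth_scale * n ** (-0.2)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
        return h


@dataclass
class DispersionTestResult:
    """Outcome of an overdispersion test."""

    variant: str
    statistic: float                 # tau_A, tau-hat, or J
    standardized: float              # t ratio, or J itself for chi-square tests
    p_value: float
    df: int                          # 0 for normal-based two-period tests
    n_effective: object              # |A|, kernel n, or per-moment counts
    variance_estimate: float = np.nan
    bias_estimate: float = np.nan    # kernel variants only
    s_matrix_mode: str = ""
    notes: Sequence[str] = field(default_factory=list)

    def reject(self, alpha: float = 0.05) -> bool:
        return bool(self.p_value <= alpha)


def draw_success_indicators(y, seed=None, rng: Optional[np.random.Generator] = None):
    """Independent auxiliary draws ``M ~ Bernoulli(y)`` (one per observation)."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.binomial(1, y)


def z_statistic(Y_t, Y_s, M_t, M_s, K: int):
    """Dispersion contrast ``[(Y_t-Y_s)^2 - K (M_t-M_s)^2] / (K (K-1))``."""
    if K < 2:
        raise ValueError(
            "the z statistic requires K >= 2: for K = 1 the binomial variance "
            "carries no information beyond the mean and the denominator K(K-1) "
            "vanishes"
        )
    Y_t = np.asarray(Y_t, dtype=float)
    Y_s = np.asarray(Y_s, dtype=float)
    M_t = np.asarray(M_t, dtype=float)
    M_s = np.asarray(M_s, dtype=float)
    for M in (M_t, M_s):
        if np.any((M != 0) & (M != 1)):
            raise ValueError("M draws must be binary")
    if np.any(Y_t < 0) or np.any(Y_t > K) or np.any(Y_s < 0) or np.any(Y_s > K):
        raise ValueError("counts must lie in [0, K]")
    out = ((Y_t - Y_s) ** 2 - K * (M_t - M_s) ** 2) / (K * (K - 1))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# pair extraction
# ---------------------------------------------------------------------------

class _PairSet:
    """All within-unit consecutive-period pairs of a panel.

    Periods are ranked by the global sorted order of time labels; a pair is
    formed whenever a unit observes two adjacent ranks (t, t+1).  ``moment``
    is the rank of the earlier period, indexing the pair's moment condition.
    """

    def __init__(self, data: PanelDataset, rng: np.random.Generator, m_draws: int = 1):
        ds = data.sorted_by_unit_time()
        if ds.K < 2:
            raise ValueError("dispersion tests require K >= 2")
        unique_times = np.unique(ds.time_ids)
        rank = np.searchsorted(unique_times, ds.time_ids)
        codes = ds.unit_codes
        adj = (codes[1:] == codes[:-1]) & (rank[1:] == rank[:-1] + 1)
        i1 = np.flatnonzero(adj)
        i2 = i1 + 1
        self.n_moments_max = len(unique_times) - 1
        self.unit = codes[i1]
        self.moment = rank[i1]
        self.Y1, self.Y2 = ds.Y[i1], ds.Y[i2]
        self.y2 = ds.Y[i2] / ds.K
        self.X1, self.X2 = ds.X[i1], ds.X[i2]
        self.K = ds.K
        # one M draw per observation per replication of the auxiliary draws
        M = rng.binomial(1, np.broadcast_to(ds.y, (m_draws, ds.n_obs)))
        zs = ((self.Y1 - self.Y2) ** 2 - ds.K * (M[:, i1] - M[:, i2]) ** 2) / (
            ds.K * (ds.K - 1)
        )
        self.z = zs.mean(axis=0)

    @property
    def n_pairs(self) -> int:
        return self.z.size


def _first_pairs(ps: _PairSet) -> np.ndarray:
    """Indices of each unit's first consecutive pair (two-period tests)."""
    _, first = np.unique(ps.unit, return_index=True)
    return first


def _norm_p(t: float) -> float:
    return float(2.0 * stats.norm.sf(abs(t)))


# ---------------------------------------------------------------------------
# two-period tests
# ---------------------------------------------------------------------------

def discrete_two_period_test(
    data: PanelDataset,
    beta_hat: Optional[np.ndarray] = None,
    match: str = "x",
    min_matched: int = 10,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    m_draws: int = 1,
) -> DispersionTestResult:
    """Matched-pair dispersion test for discrete covariates.

    Averages ``z`` over the set ``A`` of units whose covariates (or, with
    ``match='index'`` and an estimate ``beta_hat``, whose linear indices) are
    identical in the two periods, and refers the t-ratio
    ``tau_A / (sigma_A / sqrt(|A|))`` to the standard normal (two-sided).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ps = _PairSet(data, rng, m_draws=m_draws)
    idx = _first_pairs(ps)
    if match == "x":
        matched = np.all(ps.X1[idx] == ps.X2[idx], axis=1)
    elif match == "index":
        if beta_hat is None:
            raise ValueError("match='index' requires beta_hat")
        b = np.atleast_1d(np.asarray(beta_hat, float))
        matched = np.isclose(ps.X1[idx] @ b, ps.X2[idx] @ b, atol=1e-12)
    else:
        raise ValueError("match must be 'x' or 'index'")
    z = ps.z[idx][matched]
    nA = z.size
    notes = []
    if nA <= 1:
        raise ValueError(
            f"matched set has {nA} unit(s); the variance of the test "
            "statistic is undefined"
        )
    if nA < min_matched:
        msg = f"matched set is small (|A| = {nA} < {min_matched}); test unreliable"
        warnings.warn(msg, RuntimeWarning)
        notes.append(msg)
    tau = float(z.mean())
    var_z = float(z.var(ddof=1))
    if var_z == 0:
        t = 0.0 if tau == 0 else np.inf * np.sign(tau)
    else:
        t = tau / np.sqrt(var_z / nA)
    return DispersionTestResult(
        variant="discrete-two-period",
        statistic=tau,
        standardized=float(t),
        p_value=_norm_p(t),
        df=0,
        n_effective=nA,
        variance_estimate=var_z / nA,
        notes=notes,
    )


def kernel_two_period_test(
    data: PanelDataset,
    beta_hat,
    config: Optional[KernelConfig] = None,
    min_n: int = 30,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    m_draws: int = 1,
) -> DispersionTestResult:
    """Kernel-weighted dispersion test for continuous covariates.

    Weights each unit's ``z`` by a Gaussian kernel in the standardised index
    difference ``Delta_i = (x_i1 - x_i2)' beta_hat`` and corrects the local
    average for its smoothing bias ``sum w (y_2 (1-y_2) Delta)^2`` before
    standardising.  ``beta_hat`` should come from the conditional ML fit,
    which is consistent under the binomial null.
    """
    if config is None:
        config = KernelConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    b = np.atleast_1d(np.asarray(beta_hat, float))
    ps = _PairSet(data, rng, m_draws=m_draws)
    idx = _first_pairs(ps)
    z = ps.z[idx]
    n = z.size
    if n < min_n:
        raise ValueError(f"kernel test needs at least {min_n} pairs, got {n}")
    delta = (ps.X1[idx] - ps.X2[idx]) @ b
    sd = float(np.std(delta, ddof=1))
    h = config.bandwidth(n)
    if sd > 0:
        kv = np.exp(-0.5 * (delta / sd / h) ** 2) / _SQRT2PI
    else:
        # all index differences equal (e.g. zero): every unit gets full weight
        kv = np.full(n, 1.0 / _SQRT2PI)
    w = kv / kv.sum()
    tau_hat = float(w @ z)
    tau_of_delta = (ps.y2[idx] * (1.0 - ps.y2[idx]) * delta) ** 2
    bias = float(w @ tau_of_delta)
    sigma2 = float(w @ (z - tau_of_delta) ** 2)
    var_tau = sigma2 * float(np.sum(w**2))
    if var_tau <= 0:
        t = 0.0
    else:
        t = (tau_hat - bias) / np.sqrt(var_tau)
    return DispersionTestResult(
        variant="kernel-two-period",
        statistic=tau_hat,
        standardized=float(t),
        p_value=_norm_p(t),
        df=0,
        n_effective=n,
        variance_estimate=var_tau,
        bias_estimate=bias,
    )


# ---------------------------------------------------------------------------
# multi-period combination
# ---------------------------------------------------------------------------

def multi_period_test(
    data: PanelDataset,
    variant: str = "discrete",
    s_mode: Optional[str] = None,
    beta_hat=None,
    config: Optional[KernelConfig] = None,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    m_draws: int = 1,
    min_moment_n: int = 2,
) -> DispersionTestResult:
    """Chi-square combination of the ``T - 1`` consecutive-pair moments.

    Builds one moment condition per adjacent period pair — matched-set means
    of ``z`` (discrete) or kernel-weighted, bias-centred contributions
    (kernel) — and forms ``J = (sqrt(n) o gbar)' S^-1 (sqrt(n) o gbar)``,
    referred to chi-square with one degree of freedom per usable moment.

    ``s_mode='diagonal'`` (the discrete default) keeps only the moment
    variances in ``S``; the off-diagonal covariances rest on the few units
    matched in overlapping pairs and their noise badly distorts the size of
    the full-matrix test in small samples.  The kernel variant defaults to
    the full matrix.  A singular full matrix falls back to the diagonal with
    a warning.  Moments with fewer than ``min_moment_n`` contributing units
    are dropped (noted in the result).
    """
    if variant not in ("discrete", "kernel"):
        raise ValueError("variant must be 'discrete' or 'kernel'")
    if s_mode is None:
        s_mode = "diagonal" if variant == "discrete" else "full"
    if s_mode not in ("diagonal", "full"):
        raise ValueError("s_mode must be 'diagonal' or 'full'")
    if config is None:
        config = KernelConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    ps = _PairSet(data, rng, m_draws=m_draws)
    if ps.n_moments_max < 1:
        raise ValueError("multi-period test needs at least two periods")

    if variant == "kernel":
        if beta_hat is None:
            raise ValueError("kernel variant requires beta_hat")
        b = np.atleast_1d(np.asarray(beta_hat, float))

    notes = []
    g_vals, g_units, g_ns = [], [], []
    for t in range(ps.n_moments_max):
        sel = ps.moment == t
        if variant == "discrete":
            sel = sel & np.all(ps.X1 == ps.X2, axis=1)
        idx = np.flatnonzero(sel)
        n_t = idx.size
        if n_t < min_moment_n:
            notes.append(f"moment {t} dropped ({n_t} contributing units)")
            continue
        z = ps.z[idx]
        if variant == "discrete":
            g = z
        else:
            delta = (ps.X1[idx] - ps.X2[idx]) @ b
            sd = float(np.std(delta, ddof=1))
            h = config.bandwidth(n_t)
            if sd > 0:
                kv = np.exp(-0.5 * (delta / sd / h) ** 2) / _SQRT2PI
            else:
                kv = np.full(n_t, 1.0 / _SQRT2PI)
            tau_of_delta = (ps.y2[idx] * (1.0 - ps.y2[idx]) * delta) ** 2
            g = kv * (z - tau_of_delta) / kv.mean()
        g_vals.append(g)
        g_units.append(ps.unit[idx])
        g_ns.append(n_t)

    R = len(g_vals)
    if R == 0:
        raise ValueError("no usable moment conditions")
    if notes:
        warnings.warn("; ".join(notes), RuntimeWarning)

    n_vec = np.asarray(g_ns, dtype=float)
    gbar = np.array([g.mean() for g in g_vals])
    S = np.zeros((R, R))
    for r in range(R):
        S[r, r] = g_vals[r].var(ddof=1)
    if s_mode == "full":
        for r in range(R):
            for s in range(r + 1, R):
                common, ir, is_ = np.intersect1d(
                    g_units[r], g_units[s], return_indices=True
                )
                if common.size >= 2:
                    c = np.cov(g_vals[r][ir], g_vals[s][is_], ddof=1)[0, 1]
                    S[r, s] = S[s, r] = c

    v = np.sqrt(n_vec) * gbar
    used_mode = s_mode
    try:
        J = float(v @ np.linalg.solve(S, v))
        if J < 0:
            raise np.linalg.LinAlgError("indefinite S")
    except np.linalg.LinAlgError:
        msg = "covariance matrix singular or indefinite; falling back to diagonal"
        warnings.warn(msg, RuntimeWarning)
        notes.append(msg)
        used_mode = "diagonal"
        J = float(np.sum(v**2 / np.diag(S)))
    p = float(stats.chi2.sf(J, df=R))
    return DispersionTestResult(
        variant=f"{variant}-multi",
        statistic=J,
        standardized=J,
        p_value=p,
        df=R,
        n_effective=g_ns,
        s_matrix_mode=used_mode,
        notes=notes,
    )
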