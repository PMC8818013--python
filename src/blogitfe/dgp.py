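"""Synthetic panel generators: binomial and beta-binomial proportion data.

Both designs share a logistic mean with one regressor and a correlated
unit effect:

    p_it = Lambda(beta0 + beta1 * x_it + alpha_i),
    alpha_i = sqrt(T) * xbar_i + eps_i,   eps_i ~ N(0, 1),

so that corr(alpha_i, xbar_i) = 0.5 when ``x`` is uniform on [-1, 1]
(variance 1/3).  The regressor is drawn i.i.d. across units and periods,
either uniform on [-1, 1] or Bernoulli(1/2) on {0, 1}.

The binomial branch draws ``Y ~ binomial(K, p_it)``.  The overdispersed
branch first draws ``p~_it ~ beta(phi * p_it, phi * (1 - p_it))`` — a beta
with mean ``p_it`` and precision ``phi`` — and then ``Y ~ binomial(K, p~)``,
giving conditional variance ``K p (1-p) (1 + (K-1)/(phi+1))``.  The variance
inflation factor is ``1 + eta`` with ``eta = (K-1)/(phi+1)``, so a target
dispersion degree ``eta`` implies ``phi = (K-1)/eta - 1`` (which must be
positive: ``eta < K - 1``).

Common beta random number generators refuse very small shape parameters;
mirroring that behaviour, observations whose (u, v) fall below configurable
lower bounds (defaults 0.05 and 0.15) are dropped before drawing, and the
number of dropped observations is reported — this only shrinks the
effective sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .panel_model import PanelDataset

__all__ = [
    "DGPConfig",
    "SimulatedPanel",
    "phi_from_overdispersion",
    "draw_betabinomial_counts",
    "simulate_binomial_panel",
    "simulate_betabinomial_panel",
    "simulate_panel",
]


def phi_from_overdispersion(K: int, eta: float) -> float:
    """Beta precision ``phi`` implied by variance inflation ``1 + eta``.

    Inverts ``1 + (K-1)/(phi+1) = 1 + eta``:  ``phi = (K-1)/eta - 1``.
    Requires ``K >= 2`` and ``0 < eta < K - 1`` (otherwise ``phi <= 0`` and
    no beta-binomial with that inflation exists — e.g. at K=2 the inflation
    factor cannot reach 2).
    """
    if K < 2:
        raise ValueError("K must be at least 2 for a beta-binomial mixture")
    if not (0 < eta):
        raise ValueError(f"eta must be positive, got {eta}")
    if eta >= K - 1:
        raise ValueError(
            f"eta={eta} is infeasible for K={K}: the variance inflation of a "
            f"beta-binomial is bounded by K, so eta must be < K-1 = {K - 1}"
        )
    return (K - 1) / eta - 1.0


@dataclass
class DGPConfig:
    """Full specification of a simulated panel.

    ``eta`` is the dispersion degree (variance inflation minus one); 0 means
    the exact binomial branch.  ``beta_lower_bounds`` are the minimum beta
    shape parameters (u, v) below which an observation is discarded.
    """

    N: int = 100
    T: int = 2
    K: int = 2
    beta0: float = 0.0
    beta1: float = 2.0
    covariate: str = "uniform"  # "uniform" on [-1,1] or "binary" on {0,1}
    correlated_effects: bool = True  # alpha_i loads on the unit's mean x
    eta: float = 0.0
    beta_lower_bounds: tuple = (0.05, 0.15)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.covariate not in ("uniform", "binary"):
            raise ValueError("covariate must be 'uniform' or 'binary'")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")

    @property
    def phi(self) -> float:
        if self.eta == 0:
            return np.inf
        return phi_from_overdispersion(self.K, self.eta)


@dataclass
class SimulatedPanel:
    """A simulated dataset together with its ground truth."""

    data: PanelDataset
    alpha: np.ndarray          # (N,) unit effects
    p: np.ndarray              # success probabilities of the kept rows
    x: np.ndarray              # (N, T) regressor draws before any dropping
    config: DGPConfig
    n_dropped_obs: int = 0     # beta draws refused by the lower bounds


def _draw_design(config: DGPConfig, rng: np.random.Generator):
    N, T = config.N, config.T
    if config.covariate == "uniform":
        x = rng.uniform(-1.0, 1.0, size=(N, T))
    else:
        x = rng.integers(0, 2, size=(N, T)).astype(float)
    eps = rng.standard_normal(N)
    loading = np.sqrt(T) if config.correlated_effects else 0.0
    alpha = loading * x.mean(axis=1) + eps
    p = expit(config.beta0 + config.beta1 * x + alpha[:, None])
    return x, alpha, p


def _assemble(config, x, Y, keep_mask):
    N, T = config.N, config.T
    unit = np.repeat(np.arange(N), T)
    time = np.tile(np.arange(T), N)
    flat = keep_mask.ravel()
    return PanelDataset(
        unit_ids=unit[flat],
        time_ids=time[flat],
        K=config.K,
        Y=Y.ravel()[flat],
        X=x.ravel()[flat],
        covariate_names=["x"],
    )


def simulate_binomial_panel(config: DGPConfig, seed=None) -> SimulatedPanel:
    """Draw a correctly specified binomial panel (``eta`` ignored as 0)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    x, alpha, p = _draw_design(config, rng)
    Y = rng.binomial(config.K, p)
    keep = np.ones_like(Y, dtype=bool)
    return SimulatedPanel(
        data=_assemble(config, x, Y, keep),
        alpha=alpha,
        p=p.ravel(),
        x=x,
        config=config,
    )


def draw_betabinomial_counts(
    K: int,
    lam: np.ndarray,
    phi: float,
    rng: np.random.Generator,
    lower_bounds: tuple = (0.05, 0.15),
):
    """Beta-binomial counts with mean ``K*lam`` and precision ``phi``.

    Draws ``p~ ~ beta(phi*lam, phi*(1-lam))`` then ``Y ~ binomial(K, p~)``.
    Entries whose beta shape parameters fall below ``lower_bounds`` are not
    drawn; returns ``(Y, keep)`` where ``Y`` is defined (0) only off the
    kept mask.  The conditional variance of the kept draws is
    ``K lam (1-lam) (1 + (K-1)/(phi+1))``.
    """
    lam = np.asarray(lam, dtype=float)
    u = phi * lam
    v = phi * (1.0 - lam)
    b_u, b_v = lower_bounds
    keep = (u >= b_u) & (v >= b_v)
    Y = np.zeros(lam.shape, dtype=np.int64)
    if keep.any():
        p_tilde = rng.beta(u[keep], v[keep])
        Y[keep] = rng.binomial(K, p_tilde)
    return Y, keep


def simulate_betabinomial_panel(config: DGPConfig, seed=None) -> SimulatedPanel:
    """Draw an overdispersed panel via the beta-binomial mixture.

    Observations whose beta shape parameters violate the configured lower
    bounds are dropped (counted in ``n_dropped_obs``); the panel may
    therefore be unbalanced.  Draw order is fixed (x, then eps, then the
    beta variates, then Y) so results are bit-reproducible under a seed.
    """
    if config.eta <= 0:
        raise ValueError("beta-binomial branch requires eta > 0; "
                         "use simulate_binomial_panel for eta = 0")
    phi = config.phi
    rng = np.random.default_rng(config.seed if seed is None else seed)
    x, alpha, p = _draw_design(config, rng)
    Y, keep = draw_betabinomial_counts(
        config.K, p, phi, rng, config.beta_lower_bounds
    )
    if not keep.any():
        raise RuntimeError(
            "all observations violate the beta parameter lower bounds; "
            "the requested dispersion is too extreme for this design"
        )
    sim = SimulatedPanel(
        data=_assemble(config, x, Y, keep),
        alpha=alpha,
        p=p[keep],
        x=x,
        config=config,
        n_dropped_obs=int((~keep).sum()),
    )
    return sim


def simulate_panel(config: DGPConfig, seed=None) -> SimulatedPanel:
    """Dispatch on ``config.eta``: binomial when 0, beta-binomial otherwise."""
    if config.eta == 0:
        return simulate_binomial_panel(config, seed=seed)
    return simulate_betabinomial_panel(config, seed=seed)
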