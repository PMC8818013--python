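"""Monte Carlo harness for estimator-comparison and test size/power studies.

Cells are defined by a :class:`~blogitfe.dgp.DGPConfig`.  Every replication
draws its own random stream from ``SeedSequence((master_seed, cell_key,
rep))`` where ``cell_key`` is a stable hash of the cell configuration, so a
replication's data do not depend on how many other cells run, and rerunning
a cell with the same master seed is bit-reproducible.

Perfectly predicted / non-informative units (boundary totals) are removed
once per replication, before any estimator runs, so the conditional ML,
dummy-variable and pooled fits share a single estimation sample.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .baseline_estimators import fit_blogit_dv, fit_pooled_logit
from .cml import EstimationError, fit_blogit_cml, informative_subset
from .dgp import DGPConfig, simulate_panel
from .dispersion_test import (
    KernelConfig,
    discrete_two_period_test,
    kernel_two_period_test,
    multi_period_test,
)

__all__ = [
    "MonteCarloSummary",
    "run_estimator_cell",
    "run_test_cell",
    "relative_bias_curves",
    "plot_relative_bias",
]


def _cell_key(config: DGPConfig, tag: str = "") -> int:
    label = (
        f"{tag}|N={config.N}|T={config.T}|K={config.K}|b0={config.beta0}"
        f"|b1={config.beta1}|cov={config.covariate}|eta={config.eta}"
        f"|bounds={config.beta_lower_bounds}|corr={config.correlated_effects}"
    )
    return zlib.crc32(label.encode())


def _rep_rng_pair(master_seed: int, key: int, rep: int):
    ss = np.random.SeedSequence((master_seed, key, rep))
    data_ss, aux_ss = ss.spawn(2)
    return data_ss, np.random.default_rng(aux_ss)


@dataclass
class MonteCarloSummary:
    """Per-cell aggregate of a Monte Carlo experiment."""

    config: DGPConfig
    n_reps: int
    master_seed: int
    estimates: Dict[str, np.ndarray] = field(default_factory=dict)
    n_failed: Dict[str, int] = field(default_factory=dict)
    rejections: Optional[np.ndarray] = None
    alpha: Optional[float] = None
    variant: Optional[str] = None

    def mean(self, estimator: str) -> float:
        return float(np.mean(self.estimates[estimator]))

    def sd(self, estimator: str) -> float:
        return float(np.std(self.estimates[estimator], ddof=1))

    def mc_se(self, estimator: str) -> float:
        e = self.estimates[estimator]
        return float(np.std(e, ddof=1) / np.sqrt(e.size))

    @property
    def rejection_rate(self) -> float:
        if self.rejections is None:
            raise ValueError("this summary holds no test results")
        return float(np.mean(self.rejections))

    def rejection_se(self) -> float:
        r = self.rejection_rate
        return float(np.sqrt(r * (1 - r) / self.rejections.size))

    def to_frame(self) -> pd.DataFrame:
        c = self.config
        rows = []
        base = {
            "N": c.N, "T": c.T, "K": c.K, "eta": c.eta,
            "covariate": c.covariate, "n_reps": self.n_reps,
        }
        for name in self.estimates:
            rows.append({
                **base, "estimator": name, "mean": self.mean(name),
                "sd": self.sd(name), "mc_se": self.mc_se(name),
                "n_failed": self.n_failed.get(name, 0),
            })
        if self.rejections is not None:
            rows.append({
                **base, "estimator": f"test:{self.variant}",
                "mean": self.rejection_rate, "sd": np.nan,
                "mc_se": self.rejection_se(),
                "n_failed": self.n_failed.get("test", 0),
            })
        return pd.DataFrame(rows)


def run_estimator_cell(
    config: DGPConfig,
    n_reps: int = 1000,
    seed: int = 0,
    estimators: Sequence[str] = ("cml", "dv", "pooled"),
    coefficient: str = "x",
) -> MonteCarloSummary:
    """Simulate–fit cycle for one design cell.

    Each replication simulates a panel, drops boundary-total units once, and
    fits the requested estimators on the shared sample; the summary collects
    the coefficient estimates for ``coefficient``.  Replications where a fit
    raises or fails to converge are counted and excluded; the cell errors out
    if more than 10% of fits fail for any estimator.
    """
    key = _cell_key(config, tag="est")
    collected = {name: [] for name in estimators}
    n_failed = {name: 0 for name in estimators}
    for rep in range(n_reps):
        data_ss, _ = _rep_rng_pair(seed, key, rep)
        sim = simulate_panel(config, seed=data_ss)
        try:
            sample, _ = informative_subset(sim.data)
        except EstimationError:
            for name in estimators:
                n_failed[name] += 1
            continue
        j = sample.covariate_names.index(coefficient)
        for name in estimators:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if name == "cml":
                        fit = fit_blogit_cml(sample)
                    elif name == "dv":
                        fit = fit_blogit_dv(sample, drop_perfect=False)
                    elif name == "pooled":
                        # the pooled model never conditions on unit totals, so
                        # boundary-total units stay in its sample
                        fit = fit_pooled_logit(sim.data)
                    else:
                        raise ValueError(f"unknown estimator {name!r}")
                if not fit.converged or not np.isfinite(fit.beta_hat[j]):
                    raise EstimationError("non-convergence")
                collected[name].append(float(fit.beta_hat[j]))
            except (EstimationError, np.linalg.LinAlgError):
                n_failed[name] += 1
    for name in estimators:
        if n_failed[name] > 0.1 * n_reps:
            raise EstimationError(
                f"estimator {name!r} failed in {n_failed[name]}/{n_reps} "
                "replications"
            )
    return MonteCarloSummary(
        config=config,
        n_reps=n_reps,
        master_seed=seed,
        estimates={k: np.asarray(v) for k, v in collected.items()},
        n_failed=n_failed,
    )


def run_test_cell(
    config: DGPConfig,
    variant: str = "discrete",
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    s_mode: Optional[str] = None,
    m_draws: int = 1,
    kernel_config: Optional[KernelConfig] = None,
) -> MonteCarloSummary:
    """Monte Carlo rejection rate of an overdispersion test.

    With ``eta = 0`` in the config the rate estimates the size of the test;
    with ``eta > 0`` its power.  Two-period designs use the corresponding
    two-period statistic; longer panels use the multi-period chi-square
    combination.  The kernel variant fits the conditional ML estimator each
    replication to form the index differences; the discrete variant needs no
    fit.
    """
    if variant not in ("discrete", "kernel"):
        raise ValueError("variant must be 'discrete' or 'kernel'")
    key = _cell_key(config, tag=f"test-{variant}-{s_mode}-{alpha}")
    rejections = []
    n_failed = 0
    for rep in range(n_reps):
        data_ss, aux_rng = _rep_rng_pair(seed, key, rep)
        sim = simulate_panel(config, seed=data_ss)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                beta_hat = None
                if variant == "kernel":
                    sample, _ = informative_subset(sim.data)
                    beta_hat = fit_blogit_cml(sample).beta_hat
                if config.T == 2:
                    if variant == "discrete":
                        res = discrete_two_period_test(
                            sim.data, rng=aux_rng, m_draws=m_draws
                        )
                    else:
                        res = kernel_two_period_test(
                            sim.data, beta_hat, config=kernel_config,
                            rng=aux_rng, m_draws=m_draws,
                        )
                else:
                    res = multi_period_test(
                        sim.data, variant=variant, s_mode=s_mode,
                        beta_hat=beta_hat, config=kernel_config,
                        rng=aux_rng, m_draws=m_draws,
                    )
            rejections.append(res.reject(alpha))
        except (EstimationError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > 0.1 * n_reps:
        raise EstimationError(
            f"test computation failed in {n_failed}/{n_reps} replications"
        )
    return MonteCarloSummary(
        config=config,
        n_reps=n_reps,
        master_seed=seed,
        rejections=np.asarray(rejections, dtype=float),
        alpha=alpha,
        variant=variant,
        n_failed={"test": n_failed},
    )


def relative_bias_curves(
    etas: Sequence[float],
    Ts: Sequence[int],
    Ks: Sequence[int],
    N: int = 100,
    n_reps: int = 1000,
    seed: int = 0,
    estimators: Sequence[str] = ("cml", "dv"),
    beta1: float = 2.0,
    covariate: str = "uniform",
) -> pd.DataFrame:
    """Relative bias ``(mean beta1_hat - beta1)/beta1`` over a dispersion grid.

    Cells with ``eta >= K - 1`` are infeasible for the beta-binomial mixture
    and are skipped (flagged in the returned frame's absence).
    """
    rows = []
    for K in Ks:
        for T in Ts:
            for eta in etas:
                if eta > 0 and eta >= K - 1:
                    warnings.warn(
                        f"skipping infeasible cell (K={K}, eta={eta})",
                        RuntimeWarning,
                    )
                    continue
                config = DGPConfig(
                    N=N, T=T, K=K, eta=eta, beta1=beta1, covariate=covariate
                )
                cell = run_estimator_cell(
                    config, n_reps=n_reps, seed=seed, estimators=estimators
                )
                for name in estimators:
                    rows.append({
                        "eta": eta, "T": T, "K": K, "N": N,
                        "estimator": name,
                        "mean": cell.mean(name),
                        "sd": cell.sd(name),
                        "mc_se": cell.mc_se(name),
                        "relative_bias": (cell.mean(name) - beta1) / beta1,
                        "n_failed": cell.n_failed[name],
                        "n_reps": n_reps,
                    })
    return pd.DataFrame(rows)


def plot_relative_bias(df: pd.DataFrame, path) -> None:
    """Line plot of relative bias against the dispersion degree, one panel
    per (T, K) cell, one line per estimator."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = sorted({(t, k) for t, k in zip(df["T"], df["K"])})
    ncols = max(len({k for _, k in cells}), 1)
    nrows = max(len({t for t, _ in cells}), 1)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
        sharex=True, sharey=True, squeeze=False,
    )
    t_vals = sorted({t for t, _ in cells})
    k_vals = sorted({k for _, k in cells})
    for (t, k) in cells:
        ax = axes[t_vals.index(t)][k_vals.index(k)]
        sub = df[(df["T"] == t) & (df["K"] == k)]
        for name, grp in sub.groupby("estimator"):
            grp = grp.sort_values("eta")
            ax.plot(grp["eta"] * 100, grp["relative_bias"] * 100,
                    marker="o", label=name)
        ax.axhline(0.0, color="grey", lw=0.6)
        ax.set_title(f"T={t}, K={k}", fontsize=9)
    for ax in axes[-1]:
        ax.set_xlabel("overdispersion (%)")
    for row in axes:
        row[0].set_ylabel("relative bias (%)")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
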