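"""Panel data model for grouped binomial proportions.

An observation is a count ``Y`` of successes out of ``K`` trials (equivalently
a proportion ``y = Y/K`` on the grid ``{0, 1/K, ..., 1}``) for unit ``i`` in
period ``t``.  The conditional expectation of the proportion is logistic in
the covariates and a unit-specific intercept::

    E(y_it | x_it, a_i) = Lambda(x_it' beta + a_i)

with ``Lambda`` the standard logistic CDF.  The fixed effect ``a_i`` may be
arbitrarily correlated with the covariates; ``K`` is known and constant
across the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

__all__ = [
    "PanelDataset",
    "ModelParams",
    "logistic_cef",
    "binomial_loglik",
    "semi_elasticity",
    "read_panel_csv",
    "write_panel_csv",
]


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


@dataclass
class PanelDataset:
    """Long-format binomial proportion panel.

    Parameters
    ----------
    unit_ids, time_ids
        Row labels; every ``(unit, time)`` pair must be unique.  Periods are
        ordered by sorting ``time_ids`` within unit.
    K
        Number of trials per observation, constant across the dataset.
    Y
        Integer success counts, ``0 <= Y <= K``.
    X
        Covariate matrix (one row per observation).  No intercept column is
        needed for the fixed-effects estimators; pooled fits add their own.
    covariate_names
        Column labels for ``X``.
    """

    unit_ids: np.ndarray
    time_ids: np.ndarray
    K: int
    Y: np.ndarray
    X: np.ndarray
    covariate_names: Sequence[str] = field(default=None)

    def __post_init__(self):
        self.unit_ids = np.asarray(self.unit_ids)
        self.time_ids = np.asarray(self.time_ids)
        self.Y = np.asarray(self.Y)
        self.X = _as_2d(self.X)
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise ValueError(f"K must be a positive integer, got {self.K!r}")
        self.K = int(self.K)
        if not np.issubdtype(self.Y.dtype, np.integer):
            Yf = np.asarray(self.Y, dtype=float)
            Yr = np.rint(Yf)
            if np.max(np.abs(Yf - Yr), initial=0.0) > 1e-6:
                raise ValueError("Y must contain integer success counts")
            self.Y = Yr.astype(np.int64)
        else:
            self.Y = self.Y.astype(np.int64)
        n = len(self.Y)
        if not (len(self.unit_ids) == len(self.time_ids) == self.X.shape[0] == n):
            raise ValueError("unit_ids, time_ids, Y and X must have equal length")
        if np.any(self.Y < 0) or np.any(self.Y > self.K):
            raise ValueError("counts must satisfy 0 <= Y <= K")
        pairs = pd.MultiIndex.from_arrays([self.unit_ids, self.time_ids])
        if pairs.has_duplicates:
            raise ValueError("duplicated (unit, time) pairs are not allowed")
        if self.covariate_names is None:
            self.covariate_names = [f"x{j}" for j in range(self.X.shape[1])]
        self.covariate_names = list(self.covariate_names)
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names length must match X columns")
        # integer codes for fast grouping; rows of a unit sorted by time
        codes, _ = pd.factorize(self.unit_ids, sort=False)
        self._unit_codes = codes

    # -- basic accessors ---------------------------------------------------

    @property
    def n_obs(self) -> int:
        return len(self.Y)

    @property
    def n_units(self) -> int:
        return int(self._unit_codes.max()) + 1 if self.n_obs else 0

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Proportions ``Y/K``."""
        return self.Y / self.K

    @property
    def unit_codes(self) -> np.ndarray:
        return self._unit_codes

    def unit_totals(self) -> np.ndarray:
        """Per-unit sufficient statistics ``S_i = sum_t Y_it`` (by unit code)."""
        return np.bincount(self._unit_codes, weights=self.Y, minlength=self.n_units).astype(np.int64)

    def unit_lengths(self) -> np.ndarray:
        """Per-unit period counts ``T_i`` (by unit code)."""
        return np.bincount(self._unit_codes, minlength=self.n_units)

    def unique_units(self) -> np.ndarray:
        """Unit identifiers in code order."""
        _, idx = np.unique(self._unit_codes, return_index=True)
        return self.unit_ids[np.sort(idx)]

    def sorted_by_unit_time(self) -> "PanelDataset":
        """Return a copy with rows ordered by (unit code, time)."""
        order = np.lexsort((self.time_ids, self._unit_codes))
        return self.select_rows(order)

    def select_rows(self, idx) -> "PanelDataset":
        return PanelDataset(
            unit_ids=self.unit_ids[idx],
            time_ids=self.time_ids[idx],
            K=self.K,
            Y=self.Y[idx],
            X=self.X[idx],
            covariate_names=self.covariate_names,
        )

    def select_units(self, unit_mask_by_code: np.ndarray) -> "PanelDataset":
        """Keep rows belonging to units whose code is flagged True."""
        row_mask = unit_mask_by_code[self._unit_codes]
        return self.select_rows(np.flatnonzero(row_mask))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.unit_ids, "time": self.time_ids, "Y": self.Y})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.X[:, j]
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        K: int,
        covariates: Optional[Sequence[str]] = None,
        id_col: str = "id",
        time_col: str = "time",
    ) -> "PanelDataset":
        """Build a dataset from a long-format frame.

        The outcome is taken from a ``Y`` column (counts) or a ``y`` column
        (proportions, converted as ``round(K*y)``; off-grid values raise).
        ``covariates`` defaults to all remaining columns.
        """
        for col in (id_col, time_col):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if df[[id_col, time_col]].isna().any().any():
            raise ValueError("missing values in id/time columns")
        if "Y" in df.columns:
            Y = df["Y"].to_numpy()
            outcome_cols = ["Y"]
        elif "y" in df.columns:
            y = df["y"].to_numpy(dtype=float)
            Ky = K * y
            Y = np.rint(Ky)
            if np.max(np.abs(Ky - Y), initial=0.0) > 1e-6:
                bad = np.argmax(np.abs(Ky - Y))
                raise ValueError(
                    f"proportion {y[bad]} is not on the grid {{0, 1/{K}, ..., 1}}"
                )
            Y = Y.astype(np.int64)
            outcome_cols = ["y"]
        else:
            raise ValueError("need a 'Y' (counts) or 'y' (proportions) column")
        if covariates is None:
            covariates = [
                c for c in df.columns if c not in {id_col, time_col, "K", *outcome_cols}
            ]
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise ValueError(f"covariate columns not found: {missing}")
        sub = df[list(covariates)]
        if sub.isna().any().any() or pd.isna(Y).any():
            raise ValueError("missing values are not supported")
        return cls(
            unit_ids=df[id_col].to_numpy(),
            time_ids=df[time_col].to_numpy(),
            K=K,
            Y=Y,
            X=sub.to_numpy(dtype=float),
            covariate_names=list(covariates),
        )


def read_panel_csv(path, K: Optional[int] = None, covariates=None) -> PanelDataset:
    """Read a long-format panel CSV (columns ``id``, ``time``, ``Y`` or ``y``).

    ``K`` may be given explicitly or as a constant ``K`` column in the file.
    """
    df = pd.read_csv(path)
    if K is None:
        if "K" not in df.columns:
            raise ValueError("K must be supplied or present as a constant column")
        kvals = df["K"].unique()
        if len(kvals) != 1:
            raise ValueError("K column must be constant across the dataset")
        K = int(kvals[0])
    return PanelDataset.from_dataframe(df, K=K, covariates=covariates)


def write_panel_csv(data: PanelDataset, path) -> None:
    data.to_dataframe().to_csv(path, index=False)


@dataclass
class ModelParams:
    """Slope coefficients plus optional per-unit intercepts."""

    beta: np.ndarray
    alpha: Optional[Mapping] = None

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))


def logistic_cef(linear_index):
    """Logistic conditional expectation ``Lambda(eta) = exp(eta)/(1+exp(eta))``.

    Overflow-safe and strictly increasing; accepts scalars or arrays.
    """
    eta = np.asarray(linear_index, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("linear index must be finite")
    out = expit(eta)
    return float(out) if np.isscalar(linear_index) or out.ndim == 0 else out


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    # log(1 + e^eta), stable for large |eta|
    return np.logaddexp(0.0, eta)


def binomial_loglik(
    data: PanelDataset, params: ModelParams, include_constant: bool = False
) -> float:
    """Binomial log-likelihood ``sum_it [Y log L + (K-Y) log(1-L)]``.

    ``params.alpha`` maps unit identifier to its intercept; it may be omitted
    when an intercept is folded into a covariate.  The binomial coefficient
    ``log C(K, Y)`` is excluded unless ``include_constant``; without it the
    value equals the Bernoulli log-likelihood of the clone-expanded dataset
    exactly.  Boundary counts (``Y=0`` or ``Y=K``) never evaluate ``log 0``;
    a success probability pinned at 0 or 1 against a conflicting count gives
    ``-inf`` rather than an error.
    """
    eta = data.X @ params.beta
    if params.alpha is not None:
        missing = [u for u in data.unique_units() if u not in params.alpha]
        if missing:
            raise ValueError(f"alpha missing for units: {missing[:5]}")
        eta = eta + np.array([params.alpha[u] for u in data.unit_ids], dtype=float)
    Y = data.Y
    K = data.K
    finite = np.isfinite(eta)
    # Y*eta - K*log(1+e^eta) == Y log(L) + (K-Y) log(1-L)
    ll = np.where(finite, Y * np.where(finite, eta, 0.0) - K * _log1pexp(np.where(finite, eta, 0.0)), 0.0)
    if not np.all(finite):
        inf_pos = (eta == np.inf)
        inf_neg = (eta == -np.inf)
        ll = np.where(inf_pos, np.where(Y == K, 0.0, -np.inf), ll)
        ll = np.where(inf_neg, np.where(Y == 0, 0.0, -np.inf), ll)
    total = float(np.sum(ll))
    if include_constant:
        total += float(np.sum(log_binom_coeff(K, Y)))
    return total


def log_binom_coeff(K, q):
    """``log C(K, q)`` via log-gamma (vectorised)."""
    K = np.asarray(K, dtype=float)
    q = np.asarray(q, dtype=float)
    return gammaln(K + 1) - gammaln(q + 1) - gammaln(K - q + 1)


def binomial_null_sd(mean_level: float, K: int) -> float:
    """Standard deviation of a proportion under the binomial assumption.

    ``sqrt(mean*(1-mean)/K)`` — comparing it with the observed standard
    deviation of ``y`` is a quick marginal screen for overdispersion (an
    observed SD well above it suggests extra-binomial variation, though the
    formal test conditions on fixed effects and can disagree).
    """
    if not (0.0 <= mean_level <= 1.0):
        raise ValueError(f"mean_level must lie in [0, 1], got {mean_level}")
    if K < 1:
        raise ValueError("K must be a positive integer")
    return float(np.sqrt(mean_level * (1.0 - mean_level) / K))


def semi_elasticity(beta_j: float, mean_level: float) -> float:
    """Semi-elasticity ``d log E(y)/d x = beta * (1 - Lambda)`` at the mean.

    ``mean_level`` is an estimate of the average expected proportion; the
    sample mean of ``y`` is a natural plug-in.
    """
    if not (0.0 <= mean_level <= 1.0):
        raise ValueError(f"mean_level must lie in [0, 1], got {mean_level}")
    return float(beta_j) * (1.0 - float(mean_level))
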