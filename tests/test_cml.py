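import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import expit

from blogitfe import (
    DGPConfig,
    EstimationError,
    GroupConditioningState,
    PanelDataset,
    brute_force_cond_loglik,
    cond_loglik,
    cond_score,
    expand_to_bernoulli,
    fit_blogit_cml,
    fit_blogit_cml_via_expansion,
    group_cond_loglik,
    informative_subset,
    simulate_binomial_panel,
)
from blogitfe.panel_model import log_binom_coeff
from tests.conftest import random_informative_group


class TestInformativeSubset:
    def test_boundary_totals_dropped(self, tiny_panel):
        kept, dropped = informative_subset(tiny_panel)
        assert sorted(dropped) == ["a", "c"]  # totals 0 and K*T
        assert set(kept.unit_ids) == {"b"}

    def test_all_dropped_raises(self):
        ds = PanelDataset([1, 1], [1, 2], 2, [0, 0], [[0.0], [1.0]])
        with pytest.raises(EstimationError, match="no informative units"):
            informative_subset(ds)


class TestGroupConditional:
    def test_single_period_contributes_zero(self):
        st = GroupConditioningState.from_counts([0.8], [1], 2)
        assert group_cond_loglik(st, [1]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_beta_small_case(self):
        # K=2, T=2, Y=(1,1): weights C(2,0)C(2,2)=1, C(2,1)^2=4, 1 -> 4/6
        st = GroupConditioningState.from_counts([0.0, 0.0], [1, 1], 2)
        assert group_cond_loglik(st, [1, 1]) == pytest.approx(np.log(4 / 6), abs=1e-12)

    def test_boundary_total_rejected(self):
        st = GroupConditioningState.from_counts([0.1, 0.2], [0, 0], 2)
        with pytest.raises(ValueError, match="non-informative"):
            group_cond_loglik(st, [0, 0])

    def test_recursion_matches_enumeration(self, rng):
        """DP log-denominator vs explicit composition-set enumeration."""
        for _ in range(100):
            eta, Y, K = random_informative_group(rng)
            st = GroupConditioningState.from_counts(eta, Y, K)
            assert group_cond_loglik(st, Y) == pytest.approx(
                brute_force_cond_loglik(st, Y), abs=1e-10
            )

    def test_hypergeometric_limit_at_beta_zero(self, rng):
        # equal linear indices: conditional law is multivariate hypergeometric
        for _ in range(25):
            _, Y, K = random_informative_group(rng)
            T = len(Y)
            st = GroupConditioningState.from_counts(np.zeros(T), Y, K)
            S = int(Y.sum())
            closed = float(
                np.sum(log_binom_coeff(K, Y)) - log_binom_coeff(K * T, S)
            )
            assert group_cond_loglik(st, Y) == pytest.approx(closed, abs=1e-12)

    def test_fixed_effect_elimination(self, rng):
        # adding a unit-level constant to every eta leaves the value unchanged
        for _ in range(25):
            eta, Y, K = random_informative_group(rng)
            st0 = GroupConditioningState.from_counts(eta, Y, K)
            st1 = GroupConditioningState.from_counts(eta + 3.7, Y, K)
            assert group_cond_loglik(st0, Y) == pytest.approx(
                group_cond_loglik(st1, Y), abs=1e-10
            )

    def test_binary_reduction_is_conditional_logit(self):
        # K=1, T=2, S=1: P(Y=(1,0)) = e^eta1 / (e^eta1 + e^eta2)
        eta = np.array([0.4, -1.1])
        st = GroupConditioningState.from_counts(eta, [1, 0], 1)
        expected = eta[0] - np.logaddexp(eta[0], eta[1])
        assert group_cond_loglik(st, [1, 0]) == pytest.approx(expected, abs=1e-12)

    def test_enumeration_guard(self):
        st = GroupConditioningState.from_counts(np.zeros(14), [1] * 14, 3)
        with pytest.raises(EstimationError, match="too large"):
            brute_force_cond_loglik(st, [1] * 14, max_terms=1000)


class TestCondScore:
    def test_matches_finite_difference(self, rng):
        sim = simulate_binomial_panel(DGPConfig(N=25, T=3, K=3), seed=2)
        data, _ = informative_subset(sim.data)
        for beta in ([0.0], [1.5], [-0.8]):
            b = np.asarray(beta)
            g = cond_score(data, b)
            h = 1e-6
            fd = (cond_loglik(data, b + h) - cond_loglik(data, b - h)) / (2 * h)
            assert g[0] == pytest.approx(fd, abs=1e-5)

    def test_zero_at_beta_zero_for_antisymmetric_design(self):
        # unit 2 is unit 1 with periods swapped and covariate negated, so the
        # score contributions cancel exactly at beta = 0
        ds = PanelDataset(
            unit_ids=[1, 1, 2, 2],
            time_ids=[1, 2, 1, 2],
            K=3,
            Y=[1, 2, 2, 1],
            X=[[0.4], [-0.9], [0.9], [-0.4]],
        )
        g = cond_score(ds, [0.0])
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_score_dimension(self, small_sim):
        data, _ = informative_subset(small_sim.data)
        two_cov = PanelDataset(
            data.unit_ids, data.time_ids, data.K, data.Y,
            np.column_stack([data.X, data.X[:, 0] ** 2]),
            covariate_names=["x", "x2"],
        )
        assert cond_score(two_cov, [0.5, -0.2]).shape == (2,)

    def test_rejects_non_finite_beta(self, small_sim):
        data, _ = informative_subset(small_sim.data)
        with pytest.raises(ValueError):
            cond_score(data, [np.nan])


class TestFit:
    def test_recovers_truth_within_sampling_error(self):
        sim = simulate_binomial_panel(DGPConfig(N=300, T=5, K=5), seed=9)
        fit = fit_blogit_cml(sim.data)
        assert fit.converged
        assert fit.gradient_norm_at_optimum < 1e-7
        assert abs(fit.beta_hat[0] - 2.0) < 3 * fit.se[0]

    def test_binary_case_equals_conditional_logit_root(self):
        # K=1, T=2: the conditional MLE solves the Chamberlain two-period
        # score sum [d_i - sigma(dx_i b)] dx_i = 0, solvable by bisection
        sim = simulate_binomial_panel(DGPConfig(N=400, T=2, K=1), seed=4)
        data, _ = informative_subset(sim.data)
        ds = data.sorted_by_unit_time()
        Y = ds.Y.reshape(-1, 2)
        X = ds.X[:, 0].reshape(-1, 2)
        d = Y[:, 0]
        dx = X[:, 0] - X[:, 1]

        def score(b):
            return float(np.sum((d - expit(dx * b)) * dx))

        root = brentq(score, -10, 10, xtol=1e-12)
        fit = fit_blogit_cml(data)
        assert fit.beta_hat[0] == pytest.approx(root, abs=1e-8)

    def test_time_invariant_covariate_rejected(self, small_sim):
        data = small_sim.data
        bad = PanelDataset(
            data.unit_ids, data.time_ids, data.K, data.Y,
            np.column_stack([data.X, np.ones(data.n_obs)]),
            covariate_names=["x", "const"],
        )
        with pytest.raises(EstimationError, match="time-invariant"):
            fit_blogit_cml(bad)

    def test_bookkeeping_adds_up(self, small_sim):
        fit = fit_blogit_cml(small_sim.data)
        total = small_sim.data.n_units
        assert fit.n_units_used + fit.n_units_dropped_noninformative == total
        v = fit.vcov
        assert np.allclose(v, v.T)
        assert np.all(np.linalg.eigvalsh(v) >= -1e-12)


class TestExpansion:
    def test_indicator_layout(self):
        ds = PanelDataset([1], [1], 5, [3], [[0.7]])
        exp = expand_to_bernoulli(ds)
        assert list(exp.data.Y) == [1, 1, 1, 0, 0]
        assert np.allclose(exp.data.X[:, 0], 0.7)

    def test_sums_preserved(self, small_sim):
        data = small_sim.data
        exp = expand_to_bernoulli(data)
        sums = np.bincount(exp.original_row, weights=exp.data.Y)
        assert np.array_equal(sums.astype(int), data.Y)
        assert exp.data.n_obs == data.K * data.n_obs

    def test_identity_for_binary_data(self):
        sim = simulate_binomial_panel(DGPConfig(N=10, T=2, K=1), seed=0)
        exp = expand_to_bernoulli(sim.data)
        assert np.array_equal(exp.data.Y, sim.data.Y)
        assert exp.data.n_obs == sim.data.n_obs

    def test_clone_order_irrelevant(self, rng):
        sim = simulate_binomial_panel(DGPConfig(N=40, T=2, K=3), seed=6)
        data, _ = informative_subset(sim.data)
        exp = expand_to_bernoulli(data)
        # scramble the indicators within each original row's clone block
        Y_perm = exp.data.Y.copy()
        for r in range(data.n_obs):
            block = slice(r * data.K, (r + 1) * data.K)
            Y_perm[block] = rng.permutation(Y_perm[block])
        permuted = PanelDataset(
            exp.data.unit_ids, exp.data.time_ids, 1, Y_perm, exp.data.X,
            covariate_names=exp.data.covariate_names,
        )
        f1 = fit_blogit_cml(exp.data)
        f2 = fit_blogit_cml(permuted)
        assert f1.beta_hat[0] == pytest.approx(f2.beta_hat[0], abs=1e-10)

    def test_direct_and_expansion_fits_agree(self):
        """Equivalence of the two implementation paths on random datasets."""
        for seed in range(20):
            K = 2 + seed % 2
            sim = simulate_binomial_panel(DGPConfig(N=25, T=2, K=K), seed=seed)
            data, _ = informative_subset(sim.data)
            f_direct = fit_blogit_cml(data)
            f_exp = fit_blogit_cml_via_expansion(data)
            assert f_direct.beta_hat[0] == pytest.approx(
                f_exp.beta_hat[0], abs=1e-6
            )

    def test_loglik_paths_differ_by_binomial_constant(self, small_sim):
        data, _ = informative_subset(small_sim.data)
        f_direct = fit_blogit_cml(data)
        f_exp = fit_blogit_cml_via_expansion(data)
        const = float(np.sum(log_binom_coeff(data.K, data.Y)))
        assert f_direct.cond_loglik - f_exp.cond_loglik == pytest.approx(
            const, abs=1e-6
        )

    def test_expansion_size_guard(self, small_sim):
        with pytest.raises(EstimationError, match="expansion"):
            fit_blogit_cml_via_expansion(small_sim.data, max_rows=10)
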