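# blogitfe

Fixed-effects **b**inomial **logit** estimation for panel *proportion*
outcomes, with a test of the binomial assumption.

Many panel outcomes are bounded fractions on a discrete grid: days absent
out of a working week, patents granted out of applications filed,
contracted work-time as a percentage of full time.  Writing the outcome as
`Y_it = K y_it` successes out of `K` trials, the model is

    Y_it | x_it, a_i  ~  binomial(K, Λ(x_it'β + a_i)),
    Λ(η) = exp(η) / (1 + exp(η)),

where `a_i` is a unit-specific intercept that may be freely correlated with
the covariates.  Joint maximum likelihood in `(β, {a_i})` (the
"dummy-variable" estimator) is inconsistent for fixed `T` — the incidental
parameters problem — but conditioning each unit's sequence on its total
`S_i = Σ_t Y_it` eliminates `a_i` and yields a consistent conditional
maximum likelihood (CML) estimator, the binomial analogue of the
conditional logit.  The package implements:

* **`fit_blogit_cml`** — the conditional ML estimator.  The conditioning
  denominator `Σ_{q∈Q_i} Π_t C(K, q_t) exp(q_t x_it'β)` is the degree-`S_i`
  coefficient of the generating polynomial `Π_t (1 + z e^{x_it'β})^K`,
  evaluated by log-space polynomial multiplication, so no composition set is
  ever enumerated.  Cluster-robust (sandwich) standard errors.
* **`fit_blogit_cml_via_expansion`** — the same estimator through clone
  expansion: each observation becomes `K` Bernoulli rows and a conditional
  *binary* logit is fit, the route available in any software with a
  conditional logit command.  Agrees with the direct path to optimizer
  precision (property-tested).
* **`fit_blogit_dv`**, **`fit_pooled_logit`** — the comparison estimators:
  binomial logit with unit dummies (profile-likelihood implementation) and
  pooled binomial logit.
* **Overdispersion tests** (`discrete_two_period_test`,
  `kernel_two_period_test`, `multi_period_test`) — the CML fit never
  produces `a_i`-hat, so classical dispersion tests are unavailable.  The
  test implemented here compares, for pairs of periods with (nearly) equal
  expected proportions, the squared count difference `(Y_1 − Y_2)²` against
  auxiliary Bernoulli draws `M_t ~ Bernoulli(y_t)` through

      z = [(Y_1 − Y_2)² − K (M_1 − M_2)²] / (K (K − 1)),

  which has mean zero under the binomial null and positive mean under
  overdispersion.  Variants: exact covariate matching (discrete regressors),
  Gaussian-kernel weighting in the estimated index difference
  `(x_1 − x_2)'β̂` with plug-in bias/variance corrections (continuous
  regressors), and a chi-square combination of the `T − 1` consecutive-pair
  moments for longer panels.
* **Simulators and a Monte Carlo harness** (`simulate_panel`,
  `run_estimator_cell`, `run_test_cell`, `relative_bias_curves`) — binomial
  and beta-binomial panels with effects correlated with the covariates, for
  size/power and robustness studies.  The beta-binomial mixture inflates the
  binomial variance by `1 + (K−1)/(φ+1)`; `phi_from_overdispersion` maps a
  target inflation to the beta precision `φ`.

## Worked example

Simulate an overdispersed panel (200 units, 5 periods, `K = 10`, variance
inflation 2.0, true slope 2), fit the conditional ML estimator, and test the
binomial assumption:

```python
from blogitfe import (DGPConfig, simulate_panel, informative_subset,
                      fit_blogit_cml, multi_period_test, semi_elasticity)

sim = simulate_panel(DGPConfig(N=200, T=5, K=10, eta=1.0), seed=7)
sample, dropped = informative_subset(sim.data)
fit = fit_blogit_cml(sample)
print(fit.summary())

ybar = float(sample.y.mean())
print(f"semi-elasticity of x: {semi_elasticity(fit.beta_hat[0], ybar):.3f}")

res = multi_period_test(sim.data, variant="kernel",
                        beta_hat=fit.beta_hat, seed=7)
print(f"overdispersion J = {res.statistic:.1f} on {res.df} df, "
      f"p = {res.p_value:.2e}")
```

```
Blogit CML fit (direct); 196 units used, 0 dropped (boundary totals)
conditional log-likelihood: -1225.6305
covariate               coef  cluster se
x                     2.0964      0.0872
semi-elasticity of x: 1.105
overdispersion J = 19.6 on 4 df, p = 5.96e-04
```

The slope estimate 2.10 recovers the true value 2 up to the small upward
bias that moderate overdispersion induces in the conditional ML estimator;
the semi-elasticity `β̂(1 − ȳ)` says a unit increase in `x` raises the
expected proportion by about 110 percent.  The chi-square statistic (19.6 on
4 degrees of freedom) correctly rejects the binomial null for this
overdispersed design.

The same workflow is available from the shell:

```sh
blogitfe simulate --dgp betabinom --n 200 --t 5 --k 10 --eta 1.0 --seed 7 --out panel.csv
blogitfe fit  --input panel.csv --k 10 --estimator cml --out fit.json
blogitfe test --input panel.csv --k 10 --variant kernel --seed 7 --out test.json
blogitfe replicate --table 1 --reps 1000 --seed 1 --out-dir results/
```

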