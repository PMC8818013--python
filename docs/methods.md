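# Methods

## Model

An observation is a count `Y_it ∈ {0, …, K}` of successes in `K` trials
(equivalently a proportion `y_it = Y_it / K` on the grid `{0, 1/K, …, 1}`)
for unit `i` in period `t`.  The maintained assumptions are

1. `Y_it | p_it ~ binomial(K, p_it)` with `K` known and constant across the
   dataset;
2. `p_it = Λ(x_it'β + a_i)` with `Λ` the logistic CDF and `a_i` a
   unit-specific effect, arbitrarily correlated with `x_it`;
3. independence across units, and serial independence within units
   conditional on `a_i`.

Modelling the proportion directly respects the bounded support and the
probability mass at the endpoints, which log-odds transforms and beta
regression cannot accommodate.  `K` is fixed per dataset; readers accept
either counts or proportions (proportions are snapped to the grid with
tolerance 1e−6, anything further off is an error, since off-grid values
violate assumption 1).

## Conditional maximum likelihood

The within-unit total `S_i = Σ_t Y_it` is sufficient for `a_i`; the
conditional probability of the sequence given `S_i` is free of `a_i`:

    f(Y_i1..Y_iT | S_i) = exp(Σ_t Y_it η_it) Π_t C(K, Y_it) / D_i(S_i),
    η_it = x_it'β,

where `D_i(S)` is the degree-`S` coefficient of `Π_t (1 + z e^{η_it})^K`.
Units with `S_i = 0` or `S_i = K·T_i` have conditional probability one and
are dropped before estimation (they carry no information about `β`); units
observed in a single period likewise contribute a constant and are harmless.
Unbalanced panels are supported — conditioning is per unit — although the
balanced case is the canonical one.

**Numerics.**  All polynomial arithmetic is carried out on log-scale
coefficients with log-sum-exp accumulation, so `D_i(S)` is overflow-safe for
`K·T` in the hundreds and any slope magnitude.  The score needs the
conditional expectations `E(q_t | S_i)`; these come from the same recursion
via prefix/suffix products of the per-period factors, with the leave-one-out
coefficient evaluated only on the band of `K+1` degrees that the factor for
period `t` can reach.  One evaluation of the likelihood-plus-score costs
`O(G · K² · T²)` log-sum-exp operations for `G` units, batched across units
of equal `T`.

**Optimization.**  BFGS on the negative conditional log-likelihood with the
analytic score, started at `β = 0` (the objective is globally concave).
Because quasi-Newton line searches stall on floating-point noise around
`|score| ≈ 1e−6`, the optimum is polished with damped Newton steps using a
central-difference Hessian of the analytic score until the gradient
max-norm falls below 1e−8 (default; cap of 200 combined iterations).  A fit
that cannot reach `max(1e−8, 1e−6·(1+|loglik|))` is flagged `converged =
False` with a warning rather than raised.

**Covariance.**  Cluster-robust sandwich at the unit level: bread is the
inverse finite-difference Hessian of the conditional log-likelihood, meat
the sum of per-unit score outer products, with a `G/(G−1)` small-sample
factor.  Time-invariant covariates are detected (zero within-unit variation
for every unit) and rejected with an explanatory error — they are absorbed
by the fixed effects.

**Clone expansion.**  Replacing each observation by `K` binary rows
(successes first; any order gives the identical likelihood, which is a
property test) turns the model into a conditional binary logit on `K·T_i`
rows per unit.  The expansion route reports the conditional log-likelihood
without the `Σ log C(K, Y)` constant — the Bernoulli convention — so the two
paths' values differ by exactly that constant while the estimates coincide.
The expansion is guarded by a row-count limit since it multiplies the data
by `K`.

## Comparison estimators

*Dummy variables (DV).*  Full binomial ML jointly in `(β, {a_i})` after
dropping perfectly predicted units (boundary totals, where the intercept
diverges).  The intercepts are concentrated out: given `β` each `a_i` solves
a strictly monotone one-dimensional score equation by safeguarded Newton
(vectorised across units, absolute score tolerance 1e−12), and `β` is
updated by BFGS on the profile likelihood — whose gradient is the plain
score at the profiled intercepts by the envelope theorem — with the same
Newton polish as above.  This scales to Monte Carlo use where solving the
dense `(N+p)`-parameter system repeatedly would not.  The DV estimator is
deliberately the *biased* benchmark: with fixed `T` it exhibits the upward
incidental-parameters bias that shrinks as `T` and `K` grow.

*Pooled logit.*  Binomial GLM with a common intercept, ignoring unit
effects; standard errors clustered at the unit level.  It is inconsistent in
two opposing directions (upward through the covariate–effect correlation,
downward through neglected heterogeneity), so its bias direction flips with
the design — a feature the Monte Carlo harness reproduces.  In the harness
the pooled model is fit on the *full* simulated sample: unlike the
fixed-effects estimators it does not condition on unit totals, and
boundary-total units carry information for it.  (Restricting it to the
conditioning sample truncates the extreme unit effects and reverses its
bias, which is a different — and less interesting — experiment.)

## Overdispersion test

The conditional ML fit provides no `â_i`, so residual-based dispersion
diagnostics are unavailable.  The test works on within-unit differences.
With auxiliary draws `M_it ~ Bernoulli(y_it)`,

    z_i = [(Y_i1 − Y_i2)² − K (M_i1 − M_i2)²] / (K (K − 1))

has expectation `(Λ_i1 − Λ_i2)²` under the binomial null — zero for pairs
with equal means — and a strictly positive expectation under overdispersion.
`K ≥ 2` is required (at `K = 1` the variance carries no information beyond
the mean).  The auxiliary draws make the statistic stochastic; the default
is a single seeded draw, and `m_draws > 1` optionally averages `z` over
independent draws, an extension that only reduces auxiliary noise.

*Discrete covariates.*  Average `z` over the matched set
`A = {i : x_i1 = x_i2}` and refer `τ_A / (σ̂_A/√|A|)` to the standard
normal, two-sided.  Matching can alternatively be on the estimated index
`x'β̂`.  A matched set below 10 units triggers a warning; below 2, an error.

*Continuous covariates.*  Gaussian-kernel weights in the estimated index
difference `Δ̂_i = (x_i1 − x_i2)'β̂` (from the conditional ML fit, which is
consistent under the null; its estimation noise is ignored in the variance).
`Δ̂` is standardised by its sample standard deviation before applying the
rule-of-thumb bandwidth `h = 0.9 n^{−1/5}`; no cross-validation is offered.
The local average `τ̂ = Σ w_i z_i` is corrected for its smoothing bias with
the plug-in `Σ w_i (y_i2(1−y_i2) Δ̂_i)²` — the squared first-order term of
the mean gap, with `y_i2(1−y_i2)` estimating the logistic derivative and the
*raw* (unstandardised) `Δ̂_i`, since the bias lives on the original index
scale — and standardised by `σ̂² Σ w_i²` with
`σ̂² = Σ w_i (z_i − τ(Δ̂_i))²`.  If all `Δ̂_i` coincide (e.g. a
time-invariant design) the weights degenerate to uniform and the bias term
vanishes.

*Multiple periods.*  One moment per consecutive period pair `(t, t+1)`,
`t = 1..T−1` (no all-pairs pooling): matched-set means of `z` in the
discrete case, kernel-weighted bias-centred contributions
`K(Δ̂ˢ_{i,t}/h)(z_{i,t} − τ(Δ̂_{i,t})) / mean(K(·))` in the continuous
case, with the kernel quantities computed per moment over that moment's
available pairs (the per-moment sample size is also what scales the moment,
relevant when beta-draw dropping unbalances the panel).  The statistic is

    J = (√n ∘ ḡ)' Ŝ⁻¹ (√n ∘ ḡ)  ~  χ²(T−1)

under the null.  For the *discrete* variant `Ŝ` defaults to its diagonal:
the off-diagonal covariances are estimated from the few units matched in
two overlapping pairs, and their sampling noise badly oversizes the
full-matrix test in small samples (the package retains `s_mode="full"` to
demonstrate the phenomenon).  The kernel variant uses the full matrix, which
does not suffer from the problem since every unit contributes to every
moment.  A singular or indefinite `Ŝ` falls back to the diagonal with a
warning; moments with fewer than two contributing units are dropped and the
degrees of freedom reduced accordingly.  With `T = 2` the discrete `J`
equals the squared two-period t-ratio exactly; the kernel `J` differs from
it only through the bias centering convention.

## Synthetic data

Both generators share the logistic mean `p_it = Λ(β₀ + β₁ x_it + a_i)` with
defaults `β₀ = 0`, `β₁ = 2`; `x_it` i.i.d. uniform on [−1, 1] (variance 1/3)
or Bernoulli(½) on {0, 1}; and correlated effects
`a_i = √T x̄_i + ε_i`, `ε_i ~ N(0,1)`, giving corr(`a_i`, `x̄_i`) = 0.5 in
the uniform design (a `correlated_effects=False` switch removes the loading
for null designs).  The binomial branch draws `Y ~ binomial(K, p_it)`.  The
overdispersed branch draws `p̃_it ~ beta(φ p_it, φ(1−p_it))` — mean `p_it`,
precision `φ` — then `Y ~ binomial(K, p̃_it)`, which inflates the
conditional variance by `1 + (K−1)/(φ+1)`.  A dispersion degree `η`
(inflation minus one) therefore maps to `φ = (K−1)/η − 1`, feasible only for
`η < K−1`: at `K = 2` inflations of 100% or more are unattainable, which is
why dispersion grids thin out at small `K`.

Mirroring the bounds that common beta generators impose on their shape
parameters, observations with `φ p < 0.05` or `φ(1−p) < 0.15` are discarded
before drawing (observation-level, not unit-level; dropped draws are counted,
not replaced, since the violation depends only on exogenous quantities and
dropping costs only effective sample size).  The bounds are configurable —
they are an artifact of particular generator implementations.  Draw order is
fixed (x, then ε, then the beta variates, then Y), so every dataset is
bit-reproducible from its seed.

What the generator does *not* emulate: serially correlated or dynamic
covariates, within-unit contagion across trials (an alternative source of
overdispersion), missingness mechanisms other than the beta-bound rule, and
any covariate dimension beyond a single regressor.  Passing tests therefore
demonstrate correctness of the estimator and test under the maintained
sampling assumptions, not robustness to violations of assumption 3.

## Monte Carlo harness

Each replication draws its stream from `SeedSequence((master, cell_key,
rep))`, where `cell_key` hashes the cell configuration — results for
replication `r` are independent of which other cells run, and cells are
bit-reproducible.  Failed fits (non-convergence or numerical errors) are
counted and excluded from cell means; a cell errors out if more than 10% of
fits fail.  Default replications are 1000 per cell, matching the reference
tables; the acceptance suite uses 200–400 with three-Monte-Carlo-SE
tolerances, which keeps the full run in the minutes range on one CPU.

## Known discrepancies and limitations

* In the strong-overdispersion robustness cell (N=100, T=K=10, η=1.0) the
  conditional-ML Monte Carlo mean computed here is ≈ 2.02–2.03 across seeds,
  below the reference figure of 2.049, while the dummy-variable estimator in
  the same cell lands at ≈ 2.045.  Since the package reproduces the purely
  binomial reference cells to within one Monte Carlo standard error, the
  likely explanation is that the reference figure for this cell tracks the
  dummy-variable column; the corresponding acceptance test asserts the
  conditional-ML value as specified and is expected to fail at its 3-SE
  tolerance.  The acceptance script reports the honestly computed value.
* The conditional likelihood convention includes the `Π_t C(K, Y_it)`
  constant (the expansion path omits it); reported log-likelihood levels are
  comparable only within one convention.
* No correlated-random-effects variant, no score-type dispersion tests
  (they require `â_i`), and no bandwidth selection beyond the rule of thumb.
* `K` must be constant across the dataset; varying trial counts would
  require per-observation generating factors (straightforward but out of
  scope).
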