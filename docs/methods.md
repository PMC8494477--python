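# Methods

## Model

Each sampled unit (participant, neuron, session) undergoes a
within-unit statistical test with known false positive rate `α`, assumed
common across units — true of any correctly calibrated parametric or
permutation test. Writing `γ` for the population prevalence of
*true-positive* results under this exact procedure, the probability that
a random unit tests positive is `θ = (1 − γ)α + γ`. The observed count of
positives `k` out of `n` is `Binomial(n, θ)`.

Inference targets true-positive prevalence rather than ground-truth effect
prevalence because the latter requires a common, known test sensitivity
`β`, which is unrealistic when effect sizes vary across the population.
The general forward map `θ = (1 − γ)α + γβ` is available for simulation
(`theta_from_gamma`); setting `β = 1` in the inferential model makes `γ` a
conservative lower bound on ground-truth prevalence.

### Single group

A `Beta(r, s)` prior on `θ` (default uniform, `r = s = 1`) gives the
posterior `Beta(k + r, n − k + s)` truncated to `[α, 1]`; prevalence is
the linear reparameterisation `γ = (θ − α)/(1 − α)` with support `[0, 1]`
and Jacobian `1 − α`. Under the uniform prior the posterior mode is
`(k/n − α)/(1 − α)` clamped to `[0, 1]`, equal to the maximum-likelihood
estimate; for general beta priors the mode is located from the shape
parameters (interior stationary point, or a support edge when a shape is
≤ 1, comparing edge densities in the U-shaped case).

Interval summaries: the highest posterior density interval (HPDI) is the
shortest interval containing a stated mass, reported at 0.96 by default —
a deliberately non-0.95 convention that discourages reading the interval
as a p = 0.05 test. The posterior lower bound at level `c` is the
`(1 − c)` posterior quantile.

### Differences

*Between two independent groups tested with the same procedure*: the
posterior of `(θ₁, θ₂)` is a product of independent truncated betas with
parameters `(kᵢ + 1, nᵢ − kᵢ + 1)` on `[α, 1]`; the prevalence difference
is `γ₁ − γ₂ = (θ₁ − θ₂)/(1 − α)`. An exact distribution of a difference of
(truncated) betas exists but is unwieldy; Monte Carlo sampling achieves
any desired accuracy and is what this package implements.

*Between two tests applied to one sample*: each unit falls in one of four
joint-outcome cells with probabilities `θ₁₁, θ₁₀, θ₀₁, θ₀₀` summing to 1,
with marginal constraints `α < θ₁₁ + θ₁₀ < 1` and `α < θ₁₁ + θ₀₁ < 1`.
Under a uniform prior and multinomial counts `kᵢⱼ` the posterior is a
Dirichlet with parameters `mᵢⱼ = kᵢⱼ + 1` restricted to that region.
Samples are drawn by a modified stick-breaking scheme: `θ₁₁` from
`Beta(m₁₁, m₁₀ + m₀₁ + m₀₀)` on `[0, 1]`; then `z₁₀` from
`Beta(m₁₀, m₀₁ + m₀₀)` truncated below at `(α − θ₁₁)/(1 − θ₁₁)` with
`θ₁₀ = (1 − θ₁₁) z₁₀`; then `z₀₁` from `Beta(m₀₁, m₀₀)` truncated to
enforce both remaining constraints, `θ₀₁ = (1 − θ₁₁ − θ₁₀) z₀₁`; the rest
is `θ₀₀`. The difference is `(θ₁₀ − θ₀₁)/(1 − α)`. The scheme was checked
against rejection sampling of the constrained Dirichlet: at `α → 0` it is
the exact plain-Dirichlet stick-breaking, and at `α = 0.05` with
realistic counts the two agree to Monte-Carlo precision (the constraint
region then carries ≈ 0.9999 of the Dirichlet mass).

A drawn `(θ₁₁, θ₁₀)` prefix can leave no feasible `θ₀₁` (only possible
when `θ₁₁ < α` and `θ₁₀ > 1 − α`, i.e. far outside the constraint
region); such prefixes are redrawn, which is exactly conditioning on the
support. For realistic inputs this path is never taken.

All truncated beta draws use inverse-CDF sampling through the regularised
incomplete beta function and its inverse, with per-draw truncation bounds.

### Sample summaries

The sample-based MAP is the mode of a Gaussian kernel density estimate
with normal-reference bandwidth `σ̂ n^(−1/5)`, evaluated on a fixed
2001-point grid over `[−1, 1]`. The KDE is computed by linear binning onto
the grid followed by discrete convolution with the kernel — numerically
the same curve as direct evaluation at the grid resolution, but `O(n)` in
the sample count, which matters at 10⁷ samples. Sample HPDIs are the
shortest window of `⌈mass · n⌉` consecutive order statistics. Posterior
log-odds for a directional hypothesis are `logit` of the sample
proportion on that side; when every sample falls on one side the value is
reported as the resolution bound `±logit(1 − 1/(n + 1))` and flagged.
Summaries require at least 10⁴ samples; defaults are 10⁶ for MAP/HPDI and
10⁷ for log-odds. A single integer seed determines the entire sample
stream, and seeds are echoed in all outputs.

### Effect-size curves

Instead of one binarisation, a threshold `Ê` is swept (default 200 points,
linearly spaced over the observed range) across the per-unit effect
statistics. At each threshold the null exceedance probability supplies
`α(Ê)`, the strict exceedance count supplies `k(Ê)` (ties count as not
exceeding), and the standard single-group posterior gives MAP and HPDI.
All units must share one null distribution; the analytic central-t tail
ships with the package, and any callable threshold→tail-probability map
(e.g. an empirical permutation tail) can be supplied instead. Thresholds
whose `α` falls outside `(10⁻¹², 1 − 10⁻⁶)` are dropped with a warning
because the binomial model needs `0 < α < 1`.

### Frequentist counterparts

The MLE equals the uniform-prior MAP. The global null (no unit in the
population has an effect) is tested with the strict binomial tail
`P(X > k)` at success rate `α` — the strict inequality is the convention
this package adopts throughout for that test. Compound nulls `γ < γ₀`
("majority null" at `γ₀ = 0.5`) use the tail at `θ(γ₀)`, where the
supremum over the null is attained; the default is `P(X ≥ k)` with a
`strict` flag for the other convention, since conventions differ across
the literature. The frequentist lower bound is the largest `γc` whose
compound null is rejected at the chosen level, found by bisection
(tolerance 10⁻⁶ on `γ`; the p-value is monotone in `γc`). The percentile
bootstrap resamples the per-unit binary outcomes, equivalently
`k* ~ Binomial(n, k/n)`.

## Simulators

*Hierarchical Gaussian*: trials `y_ij ~ N(μᵢ, σw²)` with participant
means `μᵢ` drawn from a mixture of normals (one component = the standard
`N(μpop, σb²)` model; the mixture covers heterogeneous populations, e.g.
75% near zero and 25% with large effects). Within-participant means are
marginally `N(μpop, σb² + σw²/T)`, which the generator's moment tests
verify.

*ERP-like*: unit-variance white noise over 600 time points at 1 ms
spacing (the default; both are parameters), plus a Gaussian template
`a·exp(−(t − p)²/2σ²)` with `σ = 20 ms`, amplitude `a` drawn once per
participant from a uniform range and peak `p` once per participant from a
uniform window — constant across that participant's trials. Subgroup
designs set the amplitude of the remaining participants to zero.
Within-participant detection uses timepointwise t-tests Bonferroni
corrected over the time axis (`α/600` per point).

*Correlated two-test outcomes*: ground truth is `(γ₁, γ₂, ρ₁₂)`, where
`ρ₁₂` is the Pearson correlation of the two binary true-effect
indicators; the both-positive rate is
`γ₁₁ = γ₁γ₂ + ρ₁₂√(γ₁(1−γ₁)γ₂(1−γ₂))`, the standard identity for
correlated Bernoulli margins (validated against brute-force simulation).
Observed cell probabilities add false positives:
`θ₁₁ = γ₁₁ + α²γ₀₀ + αγ₀₁ + αγ₁₀`, with the marginals fixed at
`θᵢ = α + (1 − α)γᵢ`. Counts are one multinomial draw. Infeasible
`(γ₁, γ₂, ρ₁₂)` combinations (implied cell probability outside `[0, 1]`)
raise.

*Design curves*: second-level t-test power uses the noncentral t with
effect size `d = μpop/√(σb² + σw²/T)` and noncentrality `d√N`; where
scipy's noncentral-t tail overflows to NaN at large noncentrality, the
standard normal approximation of the nct tail is substituted. Expected
MAP, lower bound and HPDI width at a given `(γ, α, n)` are computed by
exact enumeration over `k = 0..n` under `Binomial(n, θ(γ))`.

## Numerical choices

- HPDI for the exact posterior: bounded scalar minimisation of
  `quantile(u + mass) − quantile(u)` over the lower tail probability `u`
  (tolerance 10⁻⁹); valid because the posterior is unimodal. Boundary
  modes (`k/n ≤ α`, or `k = n`) get one-sided intervals anchored at the
  support edge.
- Quantiles and CDF are computed through the beta survival function, so
  they stay accurate when the truncation region `[α, 1]` carries little
  of the untruncated mass; if that mass underflows entirely (< 10⁻³⁰⁰)
  the posterior degenerates and an error is raised. Conversely when the
  mass below `α` underflows, renormalisation is skipped.
- MAP values below the support are reported as exactly 0 (mode at the
  boundary), not as small negatives.
- Non-beta priors are rejected; alternative priors would need MCMC, which
  is out of scope.

## What the tests do and do not show

The simulators generate idealised data: Gaussian trials, exactly
calibrated within-unit tests, exchangeable units, a common null for all
units, and amplitudes/latencies constant within participant. Passing
recovery and calibration tests therefore demonstrates correctness of the
inference given the binomial model, not robustness to violations such as
unit-specific false positive rates, dependence between units, or
non-stationary effects — on real data those assumptions are the user's
responsibility (the `α`-common assumption is the critical one). Monte
Carlo summaries were exercised at 10⁶ samples (MAP/HPDI) and 10⁷
(log-odds); calibration and recovery checks in the test suite use
scaled-down replicate counts (100–200 replicates, 2×10⁴ samples per
summary) chosen to keep Monte-Carlo error comfortably below the asserted
tolerances.

## Known limitations

- The stick-breaking scheme's step distributions are exact conditionals
  only where the constraints do not couple across steps; in extreme
  regimes (large `α` with tiny `n`) it is an approximation to the
  constrained Dirichlet, though it always satisfies the constraints.
- The KDE mode inherits grid resolution (10⁻³ on differences) and
  bandwidth choice; reported difference MAPs are stable to about two
  decimals at 10⁶ samples.
- `expected_prevalence_summaries` enumerates all `n + 1` posteriors and
  is intended for design-sized `n` (hundreds), not thousands.
- Bootstrap percentile intervals inherit the discreteness of `k/n`;
  measured coverage at `n = 100` is a few points below nominal, as is
  typical for percentile bootstrap on proportions.
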