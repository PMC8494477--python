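# prevalence

Bayesian (and frequentist) inference of the **population prevalence of
true-positive test results** from a count of significant units.

## The problem

In psychology, neuroimaging and electrophysiology it is common to run a
statistical test *within* each experimental unit — a participant, a
recording session, a single neuron — and to ask what the resulting counts
say about the population. If `k` of `n` sampled units show a significant
effect, each tested with false positive rate `α`, the number of positive
results is binomial with success probability

```
θ = (1 − γ) α + γ
```

where `γ` is the prevalence of true positives: the proportion of the
population that would yield a genuine positive result under the same test
procedure. Because a test with imperfect sensitivity only misses real
effects, `γ` is a conservative lower bound on the prevalence of the
underlying effect itself.

With a uniform prior, the posterior of `θ` is `Beta(k+1, n−k+1)` truncated
to `[α, 1]`, and `γ = (θ − α)/(1 − α)` has an exact posterior on `[0, 1]`.
The package computes its density, CDF and quantiles, the analytic MAP
`(k/n − α)/(1 − α)`, highest posterior density intervals (96% by
convention here), and posterior lower bounds. It also provides:

- **between-group differences** `γ₁ − γ₂` for two independent samples
  given the same test (product of truncated betas, Monte Carlo);
- **within-group differences** between two tests on one sample, via a
  stick-breaking sampler for the constrained (truncated) Dirichlet
  posterior of the four joint-outcome probabilities;
- **prevalence as a function of effect-size threshold**, converting each
  threshold to its null exceedance rate `α(Ê)`;
- frequentist counterparts: maximum likelihood, percentile bootstrap,
  global-null and compound-null (e.g. "majority null" `γ < 0.5`) p-values,
  and a frequentist prevalence lower bound;
- the simulators used to validate all of the above (hierarchical Gaussian
  trial data, ERP-like time series, correlated two-test outcomes) plus
  exact power/expectation curves for design planning.

## Worked example

```python
from prevalence import TestResultCounts, summarize

summary = summarize(TestResultCounts(k=32, n=50, alpha=0.05), mass=0.96)
print(round(summary.map, 2), round(summary.hpdi_lo, 2), round(summary.hpdi_hi, 2))
# 0.62 0.47 0.76
```

32 of 50 participants significant at `α = 0.05` gives a MAP prevalence of
0.62 with a 96% HPDI of [0.47, 0.76]: given the data, more than 47% of the
population would most likely show a true positive under this experiment.
The `examples/` directory contains one short script per capability
(`single_group.py`, `difference_between_groups.py`,
`difference_within_group.py`, `effect_size_curve.py`,
`participants_vs_trials.py`); each prints the numbers it computes along
with what they mean.

A thin CLI mirrors the library for shell use:

```sh
prevalence count --k 32 --n 50 --alpha 0.05
prevalence diff-within --k11 8 --k10 19 --k01 5 --n 50 --alpha 0.05 --seed 1
```

Both emit JSON including the inputs and seed, so any run can be reproduced
from its own output.

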