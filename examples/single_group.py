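"""Single-group prevalence inference from a count of significant units.

Suppose 32 of 50 participants showed a significant within-participant
effect, each tested at a false positive rate of 0.05.  What proportion of
the population would show a true positive result under this procedure?
"""

from prevalence import PrevalencePosterior, TestResultCounts, summarize

counts = TestResultCounts(k=32, n=50, alpha=0.05)
summary = summarize(counts, mass=0.96, lower_bound_levels=(0.5, 0.95))

print(f"observed: {counts.k}/{counts.n} significant at alpha={counts.alpha}")
print(f"MAP prevalence estimate : {summary.map:.2f}")
print(f"96% HPDI                : [{summary.hpdi_lo:.2f}, {summary.hpdi_hi:.2f}]")
print(f"95% posterior lower bound: {summary.lower_bounds[0.95]:.2f}")

# The MAP is the single most probable population prevalence of true
# positives; the HPDI is the shortest interval holding 96% of the
# posterior; the lower bound says prevalence exceeds it with probability
# 0.95 given the data.

post = PrevalencePosterior(counts)
print("\nposterior density on a coarse grid:")
for g in (0.3, 0.5, 0.62, 0.8, 0.95):
    print(f"  gamma={g:.2f}  density={post.density(g):6.3f}")
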