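"""Prevalence as a function of effect-size threshold.

Rather than one fixed significance cut-off, sweep a threshold over the
observed per-participant t statistics and estimate, at each threshold,
the prevalence of participants whose true effect exceeds it.
"""

import numpy as np

from prevalence import (
    EffectSizeInputs,
    HierarchicalModelParams,
    prevalence_curve,
    simulate_hierarchical,
    t_null_tail,
    within_participant_ttest,
)

# simulate 30 participants x 50 trials with a positive population mean
params = HierarchicalModelParams.single(
    n_participants=30, n_trials=50, mu_pop=1.0, sigma_b=2.0, sigma_w=10.0, seed=7
)
tvals, _ = within_participant_ttest(simulate_hierarchical(params))

inputs = EffectSizeInputs(tvals, t_null_tail(df=49), tail="right")
curve = prevalence_curve(inputs, n_thresholds=9, mass=0.96)

print("threshold  alpha    k   MAP   96% HPDI")
for i in range(len(curve.thresholds)):
    print(
        f"{curve.thresholds[i]:8.2f}  {curve.alpha_at[i]:6.4f}  {curve.k_at[i]:3d}"
        f"  {curve.map[i]:.2f}  [{curve.hpdi_lo[i]:.2f}, {curve.hpdi_hi[i]:.2f}]"
    )

# Each row is a full prevalence analysis at one threshold: alpha is the
# null probability of a t statistic exceeding it, k the number of
# participants that do, and MAP/HPDI the posterior prevalence of true
# positives at that threshold.  Low thresholds give high alpha and low
# information; high thresholds isolate the participants with big effects.
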