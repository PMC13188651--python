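"""Upper confidence limits on the probability of exceeding a tolerance limit.

Reconstructs the log-scale summary from a published-style result (median
2.18 min, CV 19.7%, n = 46) and computes the 95% upper limit on
P(time > 5 min) three ways: generalized-pivotal Monte Carlo, the exact
noncentral-t construction, and the exact binomial bound from a 0/46
exceedance count.
"""

import math

from proctol import (
    ExceedanceQuery,
    LogSampleSummary,
    clopper_pearson_upper,
    exceedance_upper_noncentral_t,
    gpq_exceedance_upper,
    sigma_from_cv,
)

summary = LogSampleSummary(xbar=math.log(2.18), s=sigma_from_cv(0.197), n=46)

for L in (5.0, 4.0):
    gpq = gpq_exceedance_upper(
        summary, ExceedanceQuery(tolerance_L=L, replications_R=2_999_999, seed=0)
    )
    nct = exceedance_upper_noncentral_t(summary, L, 0.95)
    print(f"L = {L:.1f} min: plug-in P(time > L) = {gpq.point_estimate * 100:.4f}%")
    print(f"  GPQ 95% upper limit          = {gpq.upper_limit * 100:.4f}%"
          f"  (MC SE {gpq.mc_se * 100:.5f}%)")
    print(f"  noncentral-t 95% upper limit = {nct.upper_limit * 100:.4f}%")

binomial = clopper_pearson_upper(0, 46, 0.05)
print(f"\nBinomial (0/46 events) 95% upper limit = {binomial * 100:.1f}%")
print("\nKnowing the distribution is log-normal turns a 6.3% count-based bound")
print("into a ~0.03% parametric bound at the same confidence level.")
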