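"""Bayes shape estimates: four priors, each combined with squared-error,
LINEX, and composite-LINEX loss, all via one Gamma posterior."""

import numpy as np

from lomaxshape import (
    LomaxParams,
    Loss,
    LossSpec,
    PriorFamily,
    PriorSpec,
    bayes_estimate,
    posterior,
    sample,
    sufficient_stat,
)

params = LomaxParams(shape=2.0, scale=2.0)
s = sample(params, 20, np.random.default_rng(42))
stat = sufficient_stat(s, params.scale)
print(f"sufficient statistic: n = {stat.n}, T = {stat.T:.4f}  (true shape 2)\n")

header = f"{'prior':18s} {'posterior (A, B)':>18s} {'SELF':>8s} {'LINEX a=1':>10s} {'CLLF a=1':>10s}"
print(header)
for family in PriorFamily:
    spec = PriorSpec(family=family)  # c=0.5, (k, d) = (0.6, 0.2)
    post = posterior(spec, stat)
    row = [
        bayes_estimate(spec, LossSpec(Loss.SELF), stat),
        bayes_estimate(spec, LossSpec(Loss.LINEX, a=1.0), stat),
        bayes_estimate(spec, LossSpec(Loss.COMPOSITE_LINEX, a=1.0), stat),
    ]
    print(f"{family.value:18s} ({post.shape_A:7.2f},{post.rate_B:8.4f}) "
          f"{row[0]:8.4f} {row[1]:10.4f} {row[2]:10.4f}")

print("\nLINEX guards against over-estimation so it sits below the posterior mean;")
print("composite LINEX symmetrises the penalty and sits above it.  With c = 0.5 the")
print("extended-Jeffreys SELF estimate is exactly the MLE n/T.")
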