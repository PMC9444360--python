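"""Lomax distribution basics: density, survival, sampling, and the
sufficient statistic T that drives every estimator downstream."""

import numpy as np

from lomaxshape import LomaxParams, cdf, pdf, sample, sufficient_stat, survival

params = LomaxParams(shape=2.0, scale=2.0)
print(f"Lomax(shape={params.shape}, scale={params.scale})")
print(f"  f(0)  = {pdf(0.0, params):.4f}   (density at zero is shape/scale)")
print(f"  F(2)  = {cdf(2.0, params):.4f}   (probability of failing by t=2)")
print(f"  R(2)  = {survival(2.0, params):.4f}   (probability of surviving past t=2)")

rng = np.random.default_rng(1)
s = sample(params, 1000, rng)
stat = sufficient_stat(s, params.scale)
print(f"\n1000 simulated failure times: mean {s.values.mean():.3f} "
      f"(population mean scale/(shape-1) = {params.scale/(params.shape-1):.3f})")
print(f"T = sum ln(1 + x/scale) = {stat.T:.2f}; since T ~ Gamma(n, rate=shape), "
      f"E[T] = n/shape = {s.n/params.shape:.1f}")
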