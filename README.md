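# lomaxshape

Shape-parameter estimation for the Lomax (Pareto type II) distribution with
known scale, aimed at failure-time and biomedical-duration modelling where
the tail index is the quantity of interest.

The Lomax law on [0, ∞) has density and survival function

    f(x) = (ϑ/δ) (1 + x/δ)^-(ϑ+1),        R(t) = (1 + t/δ)^-ϑ,

with shape ϑ > 0 and scale δ > 0.  With δ known, the data enter every
estimator through the complete sufficient statistic

    T = Σᵢ ln(1 + xᵢ/δ)  ~  Gamma(n, rate = ϑ).

The package implements, compares, and exactly risk-evaluates seventeen
estimators of ϑ:

- **Classical** — maximum likelihood `n/T`; the unbiased estimator
  `(n−1)/T`; probability-plot least squares (slope of `ln(1−F̂ᵢ)` on
  `ln(δ+x₍ᵢ₎)` with median-rank, mean-rank or Blom plotting positions); a
  ridge-penalised variant of that regression (penalty λ added to n in the
  normal equations, λ = 0 recovering OLS exactly); and the median method
  `−ln 0.5 / ln(1 + x_med/δ)`.
- **Bayes** — four priors (extended Jeffreys ∝ ϑ^(−2c), chi-square,
  inverted Levy, gamma), all conjugate here, so every posterior is
  Gamma(A, B); three losses per prior: squared error (posterior mean
  `A/B`), LINEX (`(A/a) ln(1 + a/B)`), and composite LINEX
  (`(A/(2a)) ln((B+a)/(B−a))`).
- **Analytic risk oracle** — the MSE of any estimator that is a function of
  (n, T) as a one-dimensional integral against the Gamma law of T, with
  closed forms `ϑ²(n+2)/((n−1)(n−2))` for the MLE and `ϑ²/(n−2)` for the
  unbiased estimator.
- **Monte Carlo study** — a vectorised simulation engine that draws paired
  replicates, evaluates all estimators, and tabulates MSEs with standard
  errors across a grid of true shapes and sample sizes.

## Worked example

```python
import numpy as np
from lomaxshape import (LomaxParams, sample, sufficient_stat,
                        mle, umvue, ridge_estimate, RidgeOptions,
                        PriorSpec, PriorFamily, LossSpec, Loss, bayes_estimate)

params = LomaxParams(shape=2.0, scale=2.0)        # true shape 2, scale known
s = sample(params, 20, np.random.default_rng(42))
stat = sufficient_stat(s, params.scale)

print(round(mle(stat), 4))                         # 1.735
print(round(umvue(stat), 4))                       # 1.6483
print(round(ridge_estimate(s, 2.0, opts=RidgeOptions(lam=0.75)), 4))  # 1.6396

gamma_prior = PriorSpec(PriorFamily.GAMMA, k=0.6, d=0.2)
print(round(bayes_estimate(gamma_prior, LossSpec(Loss.LINEX, a=1.0), stat), 4))
# 1.6857
```

All four numbers estimate the true shape 2 from the same 20 failure times;
the LINEX estimate sits below the others because the loss penalises
over-estimation more heavily.

The `examples/` directory has one short script per capability, and a thin
CLI mirrors the library:

```sh
lomaxshape estimate --scale 2 --input sample.csv --all
lomaxshape estimate-bayes --prior gamma --loss clinex --a 1 --scale 2 --input sample.csv
lomaxshape oracle --estimator umvue --n 20 --shape 1.5     # 0.1250000
lomaxshape study run --out results/
```

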