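# Methods

## Model and sufficiency

Failure times follow the Lomax (Pareto II) law with density
f(x) = (ϑ/δ)(1 + x/δ)^−(ϑ+1) on [0, ∞).  The scale δ is treated as known
throughout; estimating it is out of scope.  The transform
Y = ln(1 + X/δ) is exponential with rate ϑ, so T = Σ ln(1 + xᵢ/δ) is a
complete sufficient statistic with T ~ Gamma(n, rate ϑ).  This single fact
drives three layers of the package: the closed-form estimators, the
conjugate Bayes analysis, and the analytic risk oracle.

Samples of exactly zero are legal at the distribution layer (the density
is positive at 0); estimators that divide by T or by ln(1 + x_med/δ)
reject the degenerate all-zero sample with an explicit error rather than
returning infinity.

## Classical estimators

* **MLE** n/T and **unbiased estimator** (n−1)/T (Lehmann–Scheffé applied
  to T).  Their exact risks are ϑ²(n+2)/((n−1)(n−2)) and ϑ²/(n−2), from
  E[1/T] = ϑ/(n−1) and E[1/T²] = ϑ²/((n−1)(n−2)).
* **Probability-plot least squares.**  ln(1 − F(x)) = −ϑ ln(δ+x) + ϑ ln δ,
  so regressing yᵢ = ln(1 − F̂ᵢ) on x*ᵢ = ln(δ + x₍ᵢ₎) gives slope −ϑ.
  The rank-based CDF estimate F̂ᵢ is a configurable plotting position:
  median rank (i−0.3)/(n+0.4), mean rank i/(n+1), or Blom
  (i−3/8)/(n+0.25).  Median rank is the default; the simulated OLS and
  ridge MSE cells are sensitive to this choice at the second decimal, and
  the study engine records the position used in its design metadata.
* **Ridge regression.**  The penalised normal equations replace n by
  (n + λ) in both the numerator and denominator of the slope:
  β̂ = [(n+λ)Σx*y − Σx*Σy]/[(n+λ)Σx*² − (Σx*)²], with intercept
  (Σy − β̂Σx*)/(n+λ).  At λ = 0 this is bit-for-bit the OLS fit (both go
  through the same code path).  The default penalty is fixed at λ = 0.75,
  matching the simulation design.  A data-driven option sets
  λ = ρσ̂²/(β̂′β̂) with ρ = 2 (the number of distribution parameters),
  σ̂² the OLS residual mean square on n−2 degrees of freedom, and β̂′β̂ the
  squared norm (slope² + intercept²) of the OLS coefficient vector; the
  result is clamped into (0, 1].  The literature leaves σ² and β′β
  operationally underspecified here, so these are this package's
  concrete choices.
* **Median method** solves F(x_med) = 0.5 for ϑ.  For even n the sample
  median is the mean of the two central order statistics — the
  conventional definition, adopted here because the method itself does
  not prescribe one.

## Priors, posteriors, losses

All four priors combine with the likelihood ϑⁿ e^(−Tϑ) into a
Gamma(A, B) posterior; per-prior code exists only in the mapping table

| prior | A | B |
|---|---|---|
| extended Jeffreys (exponent c) | n − 2c + 1 | T |
| chi-square(k, d) | n + k/2 | T + d/2 |
| inverted Levy(d) | n + 1/2 | T + d/2 |
| gamma(k, d) | n + k | T + d |

since the twelve prior-loss estimators are three functionals of (A, B):
posterior mean A/B (squared-error loss), (A/a) ln(1 + a/B) (LINEX), and
(A/(2a)) ln((B+a)/(B−a)) (composite LINEX).  The composite form is
computed as (A/a)·artanh(a/B) — algebraically identical but accurate as
a → 0, where the log-ratio form loses seven digits to cancellation.
The inverted-Levy prior is parameterised by d alone; its conventional
normalising constant involves a second symbol that cancels from every
posterior quantity, so it is not represented.

Existence conditions are hard preconditions, not NaNs: LINEX requires
a > −B, composite LINEX 0 < a < B.  In the simulation these never bind,
since B ≥ T which concentrates near n/ϑ ≫ 1.5.  Extended Jeffreys
requires n > 2c − 1 for a proper posterior.  Defaults c = 0.5,
(k, d) = (0.6, 0.2), a ∈ {0.5, 1, 1.5} are the study constants.  At
c = 0.5 the extended-Jeffreys posterior mean is exactly the MLE, an
identity the tests assert column-for-column on study output.

## Analytic risk oracle

For any estimator g(n, T), MSE = ∫ (g(n,t) − ϑ)² Gamma(t; n, rate ϑ) dt.
The quadrature splits the half-line at Gamma quantiles (10⁻¹² through
1 − 10⁻¹²) so the adaptive rule resolves the sharp mode at large n, then
integrates each segment with relative tolerance 1e−10.  Composite-LINEX
estimators do not exist where the posterior rate is ≤ a; the integral is
restricted to the existence region and the excluded probability mass
Gamma-CDF(t_lower) is reported alongside the value.  For the study's
designs this mass is below 10⁻¹¹; it becomes material only for n ≲ 5.
The oracle is the authority when a Monte Carlo cell and the integral
disagree beyond sampling noise: tabulated simulation values carry
single-run noise of a few units in the third decimal at 10,000
replicates.

## Simulation design

The study engine emulates i.i.d. failure-time sampling by the exact
inverse-CDF transform x = δ[(1 − U)^(−1/ϑ) − 1], keeping the (1 − U)
orientation so a recorded uniform stream reproduces draws bitwise.  The
generator produces exactly the assumed model — no censoring, rounding,
contamination, or scale misspecification — so passing tests demonstrate
correctness of the estimators and of the risk accounting under the model,
not robustness to real-data departures from it.

Default grid: cases I–III = shapes (1.5, 2.0, 2.5) at scale 2 (scale
greater than, equal to, below the shape), n ∈ {20, 40, 60, 80, 100},
10,000 replicates.  Design choices made where the protocol is open:

* **Paired replicates** — every estimator sees the same samples within a
  replicate.  This cannot change any expected MSE; it only correlates
  columns, sharpening cross-column comparisons.
* **Seeding** — one root `SeedSequence` spawns an independent substream
  per (case, n) cell, so any cell is recomputable in isolation.
* **Error policy** — an estimator failing on any replicate (e.g. a
  degenerate sample) aborts the cell with the replicate index; nothing is
  silently skipped, which would bias the MSE.
* **Standard errors** — each MSE cell carries its Monte Carlo SE, the
  standard deviation of the replicate squared errors over √reps.  The
  acceptance comparisons use max(4 SE, 5% relative); smoke tests run at a
  few hundred replicates, where 4 SE is wide but the exact identities
  (ridge(0) = OLS, Jeffreys-SELF = MLE) still hold bitwise.

The full 3 × 5 × 33-column grid at 10,000 replicates is vectorised over
replicates and completes in a few seconds on one core, so tests and the
reproduction script run it outright.

## Known limitations

* The scale must be known; no joint or profile estimation.
* No censoring schemes and no interval estimates — point estimation and
  MSE comparison only, plus exact risks for T-based estimators.
* OLS, ridge, and median estimators are order-statistic functionals with
  no analytic risk here; they are assessed by Monte Carlo only.
* The data-driven ridge penalty is one defensible operationalisation of
  λ = ρσ̂²/(β̂′β̂); alternatives (e.g. using the slope norm alone) shift λ
  and hence the estimate slightly.
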