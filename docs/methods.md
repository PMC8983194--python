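# Methods

## Model

Lifetimes follow the generalized exponential (exponentiated exponential)
distribution with shape α > 0 and rate λ > 0 (units 1/time):

    F(x) = ψ(x)^α,   ψ(x) = 1 − e^{−λx},
    S(x) = 1 − ψ(x)^α,
    f(x) = α λ e^{−λx} ψ(x)^{α−1},
    H(x) = f(x) / S(x).

α = 1 recovers the exponential law; α > 1 gives a hazard that rises from 0,
α < 1 one that falls.  All internal evaluation goes through log ψ and
log(1 − ψ^α), computed with `expm1`/`log1p` branches so that both x → 0
(where ψ^α underflows) and large λx (where 1 − ψ^α cancels) stay accurate.

## Censoring mechanism

A Type I generalized progressive hybrid censored (GPHC) experiment places n
units on test with a progressive plan (m planned failures, removals
R_1..R_m summing to n − m), a guaranteed minimum failure count k < m, and a
threshold time T.  The test stops at T* = max{Y_k, min{Y_m, T}}.  Writing d
for the failure count by T, the observed count is D* = max(k, min(m, d))
and three cases arise: termination at Y_k (T < Y_k), at T (Y_k ≤ T < Y_m,
with R_τ survivors withdrawn at T), or at Y_m (plan completes).  Unit
conservation D* + Σ R*_i + R_τ = n holds in every case and is enforced on
every constructed sample.

Two bookkeeping details are fixed by the worked ball-bearing example rather
than by the general formulas, which are printed inconsistently in the
source material:

* in the early-termination case, every unit still on test at Y_k is
  withdrawn there, so the terminal removal R*_k = n − k − Σ_{i<k} R_i
  exceeds the planned R_k;
* R_τ is the count of survivors at T, n − d − Σ_{j≤d} R_j, not the sum of
  planned removals.

Simulation uses the exact uniform-spacings construction for progressive
Type II samples (independent uniforms raised to 1/γ_i with γ_i the number
of units still on test counted from the tail, cumulative suffix products,
then the GE quantile), O(m) per sample; it is validated in the test suite
against a brute-force mechanism that removes random survivors at each
failure.  A tie Y_i = T counts as observed.

## Likelihood inference

The log-likelihood (up to an additive combinatorial constant) is

    ℓ(α, λ) = D* ln α + D* ln λ − λ Σ y_i + (α−1) Σ ln ψ(y_i)
              + Σ R*_i ln(1 − ψ(y_i)^α) + R_τ ln(1 − ψ(T)^α).

Score and observed information are fully analytic (the λλ-entry's leading
term is −D*/λ², which is what differentiating the likelihood gives; a
printed variant with m in its place does not match the numerical Hessian).
Both are cross-checked against central finite differences on randomized
samples at every test run.

The MLE maximizes in (ln α, ln λ) — positivity without constraints — by
L-BFGS from four starts (a closed-form no-censoring α at λ = 1/ȳ, and
(1, 1/ȳ), (0.5, 1/ȳ), (2, 2/ȳ)), then polishes with Newton root-finding on
the score.  Convergence requires the sup-norm of the scale-free score
(α ∂ℓ/∂α, λ ∂ℓ/∂λ) below 1e−8 and a positive-definite observed
information; failures raise an error carrying the best point found.  The
fit is equivariant under rescaling the time axis (α̂ invariant, λ̂ ∝ 1/c),
which the suite asserts to 1e−6.

Wald intervals θ̂ ± z_{γ/2} √V̂ use the inverse observed information;
delta-method intervals for S(t) and H(t) use analytic gradients of the
plug-in transforms (validated against finite differences to 1e−5).
Intervals are deliberately not clipped to the parameter space or to [0, 1]:
the asymptotic pivot defines a symmetric interval and clipping would break
that symmetry.  A `clip=True` flag truncates for presentation.

## Bayesian inference

Independent gamma priors Gamma(a₁, b₁) on α and Gamma(a₂, b₂) on λ (rate
parameterization; all-zero hyperparameters give the improper 1/(αλ) limit).
The α-conditional includes the −b₁α prior factor — it must be proportional
to the joint posterior at fixed λ, and the suite checks that
proportionality on grids for both conditionals.

Sampling is Metropolis-Hastings within a sequential Gibbs scan: normal
random-walk proposals with scales defaulting to the asymptotic standard
errors at the MLE (user-overridable); nonpositive proposals are rejected
outright, preserving detailed balance on the positive support; the λ-update
conditions on the already-updated α.  Chains start at the MLE, default
length N = 11 000 with B = 1 000 burn-in for one-off analyses.  Point
estimates are posterior means (squared error loss) with S(t), H(t)
transformed per draw before averaging; credible intervals are
symmetric-tail empirical quantiles, carrying the posterior median as their
bracketed point (the mean can escape a quantile interval for strongly
skewed posteriors).  Propriety of the posterior under the improper prior is
not verified analytically; acceptance rates are reported and a chain that
never moves warns.

## Monte-Carlo study

The study grid mirrors the benchmark design: n = 60, truth GE(α=2, λ=1.2),
(k, m) ∈ {(15,30), (20,40), (25,50)}, T ∈ {0.5, 1.0, 1.5}, removal schemes
placing mass 2(n−m)/5, 2(n−m)/5, (n−m)/5 on failures {1, k, m} in the three
rotations, 1000 replications, estimands evaluated at t = 0.6, 95% intervals.
Metrics are the Monte-Carlo mean, estimate bias, MSE, average interval
length and coverage probability.  Replication seeds come from a
counter-based stream keyed by (root seed, cell, replication), so any cell
reruns identically in isolation.  Non-converged fits are excluded and
counted, never imputed (none occur at the benchmark settings in practice).
Bayesian study arms default to N = 3000 / B = 500 chains — posterior means
stabilize well before that at these sample sizes, and the study multiplies
the sampler by the replication count; one-off analyses keep 11 000 / 1 000.

## Benchmark values that are not reproduced

The package's estimates disagree with several published benchmark numbers,
and the disagreement is in the benchmark, not the optimizer; these values
are not reproduced by design:

* **Real-data ML point estimates.** On the printed ball-bearing datasets
  the published estimates ((4.6436, 0.0295) for T=50, (4.4185, 0.0290) for
  T=80, (4.4080, 0.0283) for T=110) have strictly *lower* log-likelihood
  than this package's fits ((6.6142, 0.0379), (5.0462, 0.0314),
  (4.5575, 0.0291)) under the same likelihood on the same data — verified
  independently by grid search plus simplex polish and by a term-by-term
  symbolic likelihood oracle.  No correct maximizer can return the
  published values; they appear to come from an unconverged optimizer (the
  three published shape estimates are nearly identical across materially
  different censored samples).
* **Published asymptotic CI endpoints** are not symmetric about the
  published point estimates, contradicting the Wald construction they are
  said to use; the package reports symmetric Wald intervals.
* **Published simulation summaries for S(0.6) and H(0.6)** (≈0.85 and
  ≈0.46) are inconsistent with the stated truth GE(2, 1.2), at which
  S(0.6) = 0.7366 and H(0.6) = 0.8140; they match a scale-parameterized
  ψ(x) = 1 − e^{−x/λ} instead.  The package follows the rate convention
  its formulas state, and validates the S/H machinery through delta-method
  and credible coverage properties instead of those summary tables.
* **Simulation-table means/MSEs** (e.g. mean α̂ = 1.9933 and MSE(λ̂) =
  0.0519 in the (25,50,60) cells) differ from this package's converged-MLE
  results (2.16, 0.14) by many Monte-Carlo standard errors under either
  parameterization convention.  The published coverage probabilities are
  all multiples of 0.02, suggesting far fewer effective replications than
  stated; the package's Wald and credible coverages sit within binomial
  error of the nominal 95%, which the acceptance suite asserts.
* The goodness-of-fit test on the full uncensored 23-point dataset is out
  of scope (the complete data are not part of the censored fixtures).

## Synthetic data: what it does and does not emulate

The generator draws exact progressive GPHC samples from a GE law — the
assumed model is exactly true, removals are exactly as planned, and times
carry no measurement error, rounding or ties.  Passing tests therefore
demonstrate correctness of the estimators under the model, not robustness
to misspecification, grouped inspection times, or informative withdrawal,
none of which the mechanism represents.

## Numerical choices and limitations

* Derivative checks: central differences, step 1e−5·max(1, |θ|); gradients
  to rel. 1e−5, Hessians to rel. 1e−4.
* Log-domain guard: any censored survival factor that underflows to zero
  makes ℓ = −∞ rather than NaN.
* Degenerate inputs: fits require D* ≥ 2; credible intervals require enough
  retained draws for the requested tail (N−B ≥ 40 at 95%); zero proposal
  variance degenerates to a constant chain with a warning.
* Quantile evaluation switches between `expm1` and `log1p` branches at
  u^{1/α} = e^{−1/2} to stay accurate at both tails.
* The test suite's stochastic checks use fixed seeds; coverage assertions
  use 3σ binomial bands at 200–500 replications, and the two Monte-Carlo
  study cells in the acceptance suite run the full 1000 replications.
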