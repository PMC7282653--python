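# Methods

## Model and hypotheses

All four tests address the fraction-retention non-inferiority hypothesis
H₀: δ ≤ δ₀ vs H₁: δ > δ₀ with δ = θ₁/θ₂, under (i) the constancy
assumption, so the historical control-vs-placebo difference stands in for
the concurrent one, and (ii) normality of the two difference estimates,

    m̂ ~ N(μ_NI, σ_NI²),   ĥ ~ N(μ_H, σ_H²),   independent.

Since θ₁ = θ₂ − μ_NI and θ₂ = μ_H, the hypothesis is equivalent to
H₀: μ_NI/μ_H ≥ 1 − δ₀. Heteroscedasticity (σ_NI ≠ σ_H, both unknown in the
raw-data setting) is the crux: no exact pivot exists for the ratio of
means, which motivates the generalized-inference construction.

δ₀ is conventionally in (0, 1) — retain at least a fraction of the control
effect — but nothing in the construction needs that, and the simulation
grids deliberately include δ₀ = 1.1 and 1.2 (super-retention nulls), so the
package does not restrict δ₀.

## The Cauchy-like null distribution (`ratio_normal`)

The observed retention fraction ẑ = 1 − m̂/ĥ is distributed as
r(a+X)/(b+Y) + 1 with a = −μ_NI/σ_NI, b = μ_H/σ_H, r = σ_NI/σ_H, X, Y iid
standard normal. Its CDF is computed by conditioning on the denominator:

    P((a+X)/(b+y) ≤ t) = Φ(t(b+y) − a)      on b+y > 0,
                         1 − Φ(t(b+y) − a)  on b+y < 0,

integrated against φ(y) with adaptive quadrature (`scipy.integrate.quad`,
`epsabs = 1e-11`) separately over the two sign regions, truncating to
|y| ≤ 12 (normal mass beyond is ~1.8e-33). The contract is absolute
accuracy 1e-8; tests verify it against a brute-force sampling oracle and
the closed Cauchy form at a = b = 0. The distribution has Cauchy-type
tails whenever P(b+Y ≈ 0) is non-negligible, so no fixed quantile bracket
is safe: the quantile function brackets geometrically outward from
1 ± 50r(1+|a|)/(1+|b|) and refines with Brent's method. p-values are taken
from the CDF directly (p = 1 − G(ẑ)) rather than by comparing ẑ with a
computed critical value, avoiding a second layer of root-finding error.
The sampler leaves ±inf from a zero denominator in place — a
probability-zero event that the empirical CDF handles naturally.

Null-boundary parameterization: on δ = δ₀ the constraint
μ_NI = μ_H(1 − δ₀) pins a = −(1−δ₀)b/r, so the null law G_{b,r,δ₀} is a
two-parameter family indexed by (b, r) once δ₀ is fixed.

## Summary-statistics tests (`ni_tests`)

The rejection-region formulations of Rothmann's and Wang's tests carry a
critical-value sign ambiguity (an "upper α point" compared with a `<`
region). The package works in p-value space instead — Rothmann: lower
normal tail of Z_R; Wang: upper normal tail of W — which is unambiguous,
reproduces the published worked example to 4 d.p., and makes
reject ⇔ p < α a type invariant of `TestResult`. For ĥ > 0, W = −Z_R
exactly, so the two tests coincide; for ĥ < 0 they diverge (Rothmann's
positivity assumption failing), and ĥ = 0 is a hard error. σ_NI and σ_H
are treated as known SDs of the difference estimates, with no
degrees-of-freedom correction — the normal-theory setting in which these
tests are defined. The ratio test plugs in b̂ = ĥ/σ_H and r̂ = σ_NI/σ_H
per dataset.

## The GPV test (`gpq`)

The GPQ for a normal mean, R_μ = x̄ − Z·√((n−1)s²/(nU)) with Z ~ N(0,1) and
U ~ χ²(n−1), has a parameter-free distribution given the data and observed
value μ; the ratio GPQ R_{μNI}/R_{μH} inherits both properties. The
generalized p-value is estimated by Monte Carlo with M draws (default
M = 10 000, MC standard error ≤ 0.5/√M): p̂ = #{R_ratio ≥ 1 − δ₀}/M,
rejecting when p̂ < α.

Design choices that were genuinely open:

* **Tail direction.** A mechanical reading of the GPV estimator as a
  lower-tail frequency conflicts with the decision rule it accompanies
  (small p must mean evidence *against* μ_NI/μ_H ≥ 1 − δ₀, i.e. the ratio
  GPQ massed *below* the boundary). The upper-tail frequency at 1 − δ₀ is
  the direction consistent with the stochastic ordering of the generalized
  test variable, with the worked example (tiny GPV p-values when δ̂ ≫ δ₀)
  and with type-I error calibration at the null boundary; it is what the
  package implements.
* **Ties** at the boundary count toward the tail (≥): conservative for
  rejection.
* **Infinite draws.** When the historical effect is weak the denominator
  GPQ crosses zero and ratio draws can be ±inf. They are kept — +inf in
  the tail, −inf out of it; trimming would bias p toward rejection exactly
  in the regime where the method should be cautious.
* **Randomness.** The four streams (Z_H, Z_NI, U_H, U_NI) are spawned as
  independent `SeedSequence` children of one user seed, so Step-1 mutual
  independence and single-seed reproducibility hold simultaneously.

## Simulation design (`simulation`)

A cell is specified by (δ₀, true δ, μ_H, b, b/r, n_H, n_NI, α, seed). The
defaults are the study conditions: μ_H = 0.24, α = 0.025, n = 30, 10 000
replicates, M = 10 000; the type-I-error grid crosses
δ₀ ∈ {0.5, 0.7, 0.9, 1.1, 1.2} × b ∈ {2,3,4} × b/r ∈ {2,4,8}, the
equal-sample-size grid fixes b = 2 with n ∈ {30, 40, 50} and
δ₁ = 0.625, and the power-curve grid sweeps the true retention level.
Derived parameters: σ_H = μ_H/b, σ_NI = μ_H/(b/r), μ_NI = μ_H(1 − δ_true).

Two engines:

* Summary tests are simulated at the estimator level — one
  (m̂, ĥ) pair per replicate, σ's known (these tests are defined for known
  variances); the ratio test re-estimates b from ĥ each replicate with r
  known. Under the null boundary Rothmann's statistic is exactly standard
  normal, which gives a free exactness check on the engine.
* The GPV engine draws n_H and n_NI raw observations per replicate with
  σ_H and σ_NI as **per-observation** standard deviations. Whether the
  design SDs apply per observation or to the estimator is not decidable
  from the grid definition alone; the per-observation reading is the one
  consistent with the reported power levels — a closed-form Wald check,
  power ≈ Φ̄(z_{1−α} − (μ_H(1−δ₀) − μ_NI)/√(σ_NI²/n + (1−δ₀)²σ_H²/n)),
  gives ≈ 0.23/0.49/0.69 at n = 30 for b/r = 2/4/8 and ≈ 0.35 at n = 50,
  b/r = 2, matching the simulated 0.21–0.66 and 0.34 levels, while the
  estimator-level reading predicts power ≈ 0.04 — an order of magnitude
  off.

Seeds: a master `SeedSequence` spawns per-cell seeds, each cell spawns
per-replicate children, and each replicate splits into a data stream and a
GPQ stream — any cell or replicate is reproducible in isolation and cells
can run in parallel.

Test-suite problem sizes: the suite runs its calibration checks at reduced
scale (e.g. 2 000 replicates × M = 2 000 for the headline type-I-error
cell, a few hundred replicates for monotonicity checks) with tolerance
bands widened to ±3 binomial standard errors at that scale;
`scripts/acceptance.py` reruns the headline cells at the full
10 000 × 10 000 scale.

## What the synthetic generator does and does not emulate

Simulated data are exactly normal, independent, with constant variance
within arm — the model under which all four tests are derived. Passing
tests therefore demonstrate correctness of the procedures *under the
model*, not robustness to skewness, overdispersion, dependence between the
historical meta-analysis and the NI trial, or violation of constancy. The
Xeloda inputs are consumed as printed summary statistics (log hazard-ratio
differences); no survival model is fitted, and the raw per-arm data behind
the published GPV p-values are not public, so that column is not
reproduced — the GPV path requires raw observations by construction.

## Numerical notes and limitations

* CDF accuracy 1e-8 absolute; quantile round-trip verified to 1e-6.
  The large-b normal approximation converges like 1/b (≈2e-3 deviation at
  b = 50, ≈5e-4 at b = 200).
* Wang's and Rothmann's p-values can differ in their 4th decimal in
  published tables due to rounding in the source computations; the
  algebraic identity holds to 1e-12 here, and comparisons use a ±0.0002
  tolerance.
* The GPV p-value is a Monte Carlo estimate: at M = 10 000 its standard
  error is ≤ 0.005, so decisions with p within ~0.01 of α are
  seed-sensitive; raise M for borderline data.
* Quantile-based sample-size planning is out of scope: GPQ percentiles
  have no closed form, making power inversion expensive and fragile.
* Only the normal model is supported; the GPQ construction used here does
  not transfer to other distributions unchanged.
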