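# Methods

`healthspan` derives the full distribution of healthy longevity after age
60 from two age-indexed inputs — the annual probability of death `q_x`
and the cross-sectional probability of being healthy `h_x` — and compares
such distributions between populations. This note documents the model,
its assumptions, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## The healthy-years model (Markov chain with rewards)

An individual healthy at exact age 60 moves through a pure age ladder.
During each year of age `[x, x+1)`, two independent Bernoulli events
occur: survival of the year with probability `s_x = 1 − q_x`, and a
"healthy-year reward" with probability `h_x`, the prevalence of the
healthy state at age `x`. Healthy years accumulate until death or until
the cap at age 90, where anyone still alive is treated as exiting; total
healthy years `HY` therefore lie in `{0, …, 30}` on the full 60–89 grid,
and the *exit age* is `60 + HY`.

The first three raw moments of `HY` obey a scalar backward recursion
with boundary `m_k(90) = 0`. Under **occupancy** timing (reward for year
`[x, x+1)` earned by anyone alive at exact age `x`):

```
m1(x) = h_x + s_x m1(x+1)
m2(x) = h_x + 2 h_x s_x m1(x+1) + s_x m2(x+1)
m3(x) = h_x + 3 h_x s_x m1(x+1) + 3 h_x s_x m2(x+1) + s_x m3(x+1)
```

Under **survived-year** timing the reward is earned only if the year is
survived: each right-hand side is multiplied by `s_x` with the lone
`h_x` moved inside. The scalar recursion is exactly equivalent, for this
chain structure, to the absorbing-Markov-chain matrix formulation with
`(I − U′)⁻¹`; the scalar form was chosen because it is easier to verify
line by line. Both timings are implemented because the literature's
reward convention is not uniquely determined by prevalence data alone;
the package default is occupancy timing with conditioning on being
healthy at 60 (`h_60` replaced by 1), so reported distributions apply to
people who reach 60 in a healthy state. A Monte-Carlo simulator of the
identical stochastic process (`simulate_healthy_years`) serves as the
internal arbiter: the analytic moments must sit within 4 Monte-Carlo
standard errors of the simulated ones for either convention, and do.

Assumptions inherited by anything built on this model: health and
mortality are independent given age (the same `q_x` applies to healthy
and unhealthy individuals); the healthy state is effectively absorbing
in the prevalence sense (no explicit recovery process — `h_x` is a
cross-sectional probability, not an incidence survival curve); and
nothing is observed past age 90.

Key identities used for validation: the occupancy mean equals the
Sullivan-type sum `Σ_x l_x h_x` with `l_60 = 1`, `l_{x+1} = l_x s_x`
(agreement to 1e-12); pointwise increases of `h_x` can never decrease
the mean; survived-year means never exceed occupancy means.

## Maximum-entropy exit-age distribution

Among all distributions on the 31 integer ages `{60, …, 90}` with the
given mean, variance and third central moment, the package returns the
one maximizing Shannon entropy:

```
p_x(λ) ∝ exp(λ1 z_x + λ2 z_x² + λ3 z_x³),   z_x = (x − μ)/σ,
```

an exponential family in the age basis standardized to the target mean
`μ` and SD `σ` — a raw-age polynomial basis (entries up to 90³) is
numerically hazardous, while standardized targets are simply `(0, 1,
skewness)`. The multipliers solve the strictly convex dual
(log-partition minus `λ·targets`) by Newton's method: the gradient is
the moment residual, the Hessian the covariance of the basis under the
current distribution. Numerical choices:

* initialization `λ = 0` (the uniform distribution, which is the exact
  solution for uniform targets);
* backtracking Armijo line search with an absolute slack of 1e-12 — the
  slack matters: near the optimum, rounding noise in the dual value
  otherwise rejects the last Newton steps and stalls the residual near
  1e-9;
* convergence at max standardized residual < 1e-9 (default), cap 200
  iterations; non-convergence raises with full diagnostics, never a
  silent fallback;
* the log-partition is evaluated with the usual max-shift guard.

Feasibility is checked up front: the mean exit age must lie in
[60, 90] and the variance cannot exceed `(μ−60)(90−μ)`, the sharp bound
for a distribution on a bounded interval. A variance below 1e-12 is
treated as degenerate and returns a point mass at the rounded mean exit
age (skewness is reported as undefined in that case). Uniqueness of the
optimum follows from strict convexity of the dual on a full-rank basis;
restarting from arbitrary multipliers reproduces the same distribution
to 1e-8, and an independent constrained optimizer (SLSQP maximizing
entropy over the raw simplex) finds no feasible distribution of higher
entropy.

The support is kept discrete (integer exit ages matching integer reward
totals; no continuity correction). Fitting on a continuous support and
discretizing afterwards would be an alternative reading; discrete was
chosen because every downstream statistic is defined on the discrete
support. Three moments cannot represent every shape: the fit is
unimodal-leaning and tends to understate probabilities in the old-age
tail relative to a Monte-Carlo reference; `tail_diagnostic` reports
per-age signed differences and the total-variation distance against any
reference pmf for exactly this reason, with no pass/fail attached.

## Comparison statistics

With `phloss_x` the per-age health-loss probabilities and `lhealth_x`
the tail survival (`lhealth_60 = 1`, `lhealth_91 = 0`), the
outsurvival statistic of population 1 over population 2 is

```
φ = Σ_x phloss²_x · lhealth¹_{x+1} + ½ Σ_x phloss¹_x · phloss²_x
```

i.e. `P(X1 > X2) + ½ P(X1 = X2)` under independence, ties split evenly.
It satisfies `φ(A,B) + φ(B,A) = 1` and equals an exhaustive O(n²)
enumeration to 1e-12 (the enumeration is kept in the package as
`phi_hl_bruteforce`, a test oracle only).

The Hellinger distance is computed in the discrete formulation scaled to
[0, 2]: `HD = √(2 Σ (√p1 − √p2)²) = 2√(1 − BC)` with the Bhattacharyya
coefficient `BC = Σ √(p1 p2)`. Both routes are evaluated and must agree;
the agreement is asserted on the *squared* distance, where the identity
holds to machine precision. The square-root-of-`1 − BC` form amplifies
rounding in `BC` near 1 (reporting ~1e-8 for identical inputs), so the
root-difference evaluation is the returned value: exactly 0 for
identical distributions and exactly 2 for disjoint supports. Inputs are
renormalized to sum exactly to 1 before either statistic is computed.

## Survey preparation

Health measures follow three modes: *all-free* (healthy iff free of
every listed condition), *at-most-one* (multimorbidity), and
*cognitive-threshold* (healthy iff each test score exceeds the reference
mean − 1.5 reference SD and there is no dementia diagnosis). Reference
statistics pool all person-wave observations and both sexes by default
(a per-wave option exists), and are computed within education strata for
the education-adjusted variant. The rule is applied per test — any
failing test marks the record unhealthy — because no composite score is
defined. Two edge rules are the package's own: a reference cell with
zero or undefined score variance cannot discriminate and is skipped
rather than failing everyone at its mean; records missing *all* scores
are dropped (and counted), while individually missing scores are simply
not evaluated. Records with missing condition indicators are dropped by
default; an explicit flag treats missing as absent.

Weighted prevalence is the Hájek ratio `Σ w·healthy / Σ w` per
(wave, sex, age) stratum, invariant to rescaling of the weights, with
weighted and unweighted stratum sizes carried along. Mortality can be
parsed from the standard HMD 1×1 period life-table text layout (the
open-age `110+` row parses but lies outside the grid) or a simplified
tidy CSV, which round-trips byte-exactly through the package's writer
(`float_precision="round_trip"` matters here: the default pandas float
parser is off by one ulp). Cross-country pooling is the
respondent-count-weighted average of `q_x`.

## Weighted bootstrap

Sampling uncertainty is attached to the prevalence inputs only;
mortality is held fixed. For each stratum, records are resampled with
replacement `n_reps` times (default 5000; pipelines under test scale
down to 200), each replicate is pushed through moments → maxent →
comparison, and 95% intervals are the 2.5th/97.5th percentiles of the
replicates (linear interpolation between order statistics; inherently
integer quantities such as the modal age snap to the nearest attained
replicate value). Replicate `r` draws from a generator seeded
`base_seed + r`, so any prefix of replicates is reproducible regardless
of `n_reps`. Replicates whose maxent fit fails are dropped and counted;
more than 1% dropped fails the run.

"Weighted sampling with replacement" admits two readings and both are
implemented: `selection` (default) draws records with probability
proportional to weight and recomputes an unweighted mean; `reweight`
draws uniformly and recomputes the weighted estimator. The selection
variant mirrors the verbal description most literally, but its replicate
variance omits the weight design effect `1 + CV²_w` and therefore
understates the sampling variance of the weighted point estimator under
heterogeneous weights; the reweight variant is the variance-consistent
bootstrap of that estimator, and it is the one used for the nominal-
coverage diagnostic in the test suite (measured ~92–95% coverage for
the healthy-life-expectancy interval over 200 synthetic worlds at 100
records per age-stratum, versus ~87% for the selection variant).

## Synthetic data

The generator fabricates the statistical structure the pipeline assumes,
not any particular survey: Gompertz mortality `q_x = 1 − exp(−a e^{b(x−60)})`
(guaranteed < 1 for all parameters), logistic age-declining healthy
prevalence `h_x = floor + (1−floor)/(1 + e^{k(x−x0)})`, and person-wave
microdata with exactly `n_per_stratum` records per (wave, sex, age).
Weights are lognormal (σ = 0.5 by default) and deliberately *not*
normalized per stratum — calibrated weights need not sum to the sample
size. Condition indicators are independent Bernoulli draws from the
per-condition curves; an optional shared-frailty switch (off by default,
since no dependence structure is asserted by the data model) correlates
them through a latent per-person normal. Cognitive scores share a latent
ability factor across the three tests (correlation 0.6) with
education-specific means (±0.3) declining 0.012 SD per year of age, and
dementia follows a logistic in age (midpoint 100, slope 0.18) — together
these defaults put roughly 5–15% of records aged 80+ below the −1.5 SD
rule, in line with the intended old-age failure band; without the
shared factor, three independent tests would compound to an
implausible ~30%.

What the generator does *not* emulate: calibration to any real survey's
margins, country heterogeneity, non-response and attrition, correlated
survey design effects, or any health–mortality dependence. Passing
tests therefore demonstrate internal consistency of the estimators under
the assumed data model, not agreement with any particular survey.

## Problem sizes and determinism

Default analyses run on the 60–89 grid (31-atom exit-age support).
Monte-Carlo validation uses 10⁶ paths per schedule across 20 randomized
schedule pairs; the coverage study uses 200 synthetic worlds × 200
bootstrap replicates at 100 records per stratum. All randomness flows
through `numpy.random.default_rng` seeds recorded in the run manifest;
identical configuration and seed reproduce output files byte for byte.

## Known limitations

* A single average `q_x` applies to healthy and unhealthy individuals;
  if the unhealthy die faster, healthy-year moments are conservative.
* No transitions back to health: `h_x` is cross-sectional prevalence,
  so recovery is only reflected implicitly through the age profile.
* The age-90 cap truncates late health loss and pulls skewness negative
  for measures with substantial mass near the cap.
* Three-moment maximum entropy cannot represent multimodal shapes and
  systematically trades tail mass for mid-age mass; use
  `tail_diagnostic` against a simulation reference when tail
  probabilities matter.
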