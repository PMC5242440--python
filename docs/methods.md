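# Methods

This note documents the statistical procedures implemented in `catfda`, the
defaults and their rationale, what the synthetic cohort generator does and
does not emulate, and the numerical choices that matter for reproducing
results.

## Data model and preprocessing

The unit of observation is a subject-day of 1440 per-minute activity counts
from a collar-mounted accelerometer. Counts are non-negative integers and
strongly right-skewed, so all analysis happens on the `ln(1 + x)` scale; the
transformed minutes are then averaged within each of the 288 left-closed
5-minute intervals. The order matters — transform first, bin second — and a
property test guards it: by Jensen's inequality, `bin(ln(1+x)) ≤
ln(1+bin(x))` with equality only for constant input.

Curves live on the bin midpoints `t_j = (5j + 2.5)/60` hours with quadrature
weight `w = 1/12` hour per point; midpoint labels avoid a half-bin phase bias
in statements about peak locations. Days run midnight-to-midnight on the
local clock, with no circular wrap of the evening peak into the next day.

For wear records longer than 7 days, baseline selection deletes the first
and last recorded days (partial collar wear) and keeps the chronologically
last 7 complete days; at least 9 recorded days are required. Incomplete days
(fewer than 1440 distinct minutes) are dropped entirely and logged — never
imputed. A subject's profile needs exactly 5 weekday (Mon–Fri) and 2 weekend
(Sat–Sun) days; day-typing is real calendar logic on ISO dates.

Per subject, the activity profiles `Y_weekday(t)`, `Y_weekend(t)` are
pointwise means within day type, and intensity is `I(t) = Y(t) − ave`, where
`ave` is the unweighted grand mean over all 7×288 daily-curve values. With
complete 5+2 data, `(5·mean_t I_weekday + 2·mean_t I_weekend)/7 = 0` holds
exactly, and the tests assert it at 1e-12. Pre-transformation per-subject
mean counts are summarized per group with type-7 (linear-interpolation)
quantiles; the convention is recorded in the output because no single
quartile definition is universal.

## FPCA

Curves are dense and complete, so the estimator is the empirical one: the
pointwise mean, the eigendecomposition of the weighted sample covariance
`C·w`, and quadrature projection scores. No covariance smoothing (PACE-style
or otherwise) is applied; a smoothing hook exists but is off by default.
Eigenvalues carry curve-variance × hours units and scale linearly with the
quadrature weight (asserted numerically). Variance-explained fractions use
the total trace of the empirical covariance as the denominator, which
includes any measurement-error variance — relevant when comparing to
published figures computed after smoothing.

Sign convention: each eigenfunction is oriented so that its integral over
the morning window [5 h, 9 h] is non-negative, tie-broken by the sign at the
first grid point. This makes "positively loaded" subjects reproducible
across runs and platforms. Numerically negative eigenvalues are clipped to
zero when `|λ| < 1e-10·λ_1`; anything larger raises an error. FPCA is fit
separately for weekend and weekday curves; cross-day-type score
correlations pair subjects across the two fits.

## Function-on-scalar regression

Each coefficient curve is `β_p(t) = B(t)θ_p` with 15 cubic B-spline basis
functions on [0, 24] hours and a second-order difference penalty — the
standard penalized-spline default, exposed for sensitivity analysis.
Coefficients minimize the penalized least-squares criterion over all n×288
observations under working independence; per-term smoothing parameters are
selected by coordinate-descent GCV over a log-spaced grid (REML is not
implemented; GCV was chosen for speed and determinism). `σ²` is the residual
sum of squares over the residual degrees of freedom `nT − edf`, with `edf`
the trace of the hat operator.

Covariates are standardized to unit sample SD per model (not pooled across
models), and the age×BCS interaction is the product of the standardized main
effects, so all coefficient curves are per-SD effects.

The working-independence Gaussian likelihood deliberately ignores
within-curve residual correlation; dependence is instead respected by the
subject-level bootstrap: whole curves with their covariate rows are
resampled with replacement and the model is refit at the original fit's
smoothing parameters (re-running GCV inside each of 2000 resamples adds cost
without changing the bands appreciably). Confidence bands are pointwise
2.5%/97.5% percentiles. Resampled designs can be rank-deficient when a
covariate has few levels; the penalty regularizes those refits, truly
singular systems fail at the Cholesky factorization, and a failure rate
above 5% of draws aborts with an error. Across 200 simulated datasets with a
planted sinusoidal age effect (n=150, noise SD 0.5, 200 bootstrap draws) the
mean pointwise coverage of the nominal 95% band is computed by the
acceptance suite and required to lie in [0.90, 0.985].

Significance regions are maximal runs of grid points where the band
excludes zero, reported as `[start_hour, end_hour)` on bin edges.

## Mean-curve likelihood-ratio tests

Null and alternative are nested function-on-scalar models under the working
Gaussian likelihood; the statistic is the profiled deviance
`Λ = nT·log(RSS_null/RSS_alt) ≥ 0`. Two designs:

- **Two-group** (optionally covariate-adjusted, in four settings: none;
  age + BCS + interaction; + TDJD; + TPain): the alternative adds a
  standardized group-indicator coefficient curve. The null distribution is
  built by adding whole residual curves, resampled with replacement across
  subjects, to the null fitted values — preserving within-curve dependence
  that the likelihood ignores.
- **Paired weekend-vs-weekday**: per-subject difference curves
  `D_i = weekend − weekday`; null RSS is the raw sum of squares, the
  alternative fits a free penalized-spline mean, and the null distribution
  sign-flips whole difference curves.

One selection subtlety dominates calibration: the tested term's smoothing
parameter must be re-selected by GCV *inside every dataset*, observed and
resampled alike, so that the statistic is the same function of the data
everywhere. Reusing the observed data's selected smoothing in the null
draws is anti-conservative (measured rejection 0.125 instead of ~0.05 at
n=30/group). Shared-term smoothing stays fixed at the null model's GCV
choice, which keeps the models nested at fixed bases; `Λ` is clipped at zero
against roundoff. p-values are `(1 + #{Λ* ≥ Λ})/(n_sim + 1)`, so `n_sim ≥
99` is enforced. Defaults: 10,000 simulations for headline runs, 200–500
for the test suite. When a family of k tests is run on one data subset, the
Bonferroni-adjusted level `α/k` is recorded alongside each decision.

## Distribution test

To test whether two groups' curve *distributions* coincide, FPCA is fit to
the pooled sample (common mean removed), K is the smallest component count
explaining ≥ 95% of variance, and each component's scores get a rank-based
two-sample Anderson–Darling test with a random-permutation p-value; the
family is Bonferroni-controlled at `α/K` and the reported overall p is the
min-p combination `min(K·min_k p_k, 1)`. The AD statistic depends only on
ranks (invariant to monotone transforms, asserted by property test); exact
ties — which arise only from degenerate inputs, since scores are continuous
in theory — are broken by seeded uniform jitter of 1e-9 times the data
range.

Two practical consequences of the 95% rule deserve note. First, with
measurement-level noise in the curves the rule can select K in the tens
(each noise direction contributes a small eigenvalue), diluting power —
which is why power fixtures use smooth low-rank curves. Second, a
Bonferroni rejection needs permutation resolution finer than `α/K`, so
`n_perm` is automatically raised to `ceil(2K/α) − 1` whenever the requested
value is too coarse; the value actually used is recorded in the result.
This test is sensitive to second-moment differences that mean tests cannot
see: with equal means and a 4-fold score-variance ratio at n=100/group it
rejects in most replicates while the mean LRT stays at its nominal level.

## Synthetic cohort generator

The generator produces the data structure the analysis assumes, with known
ground truth for recovery tests. On the `ln(1+x)` scale, each subject's
latent day-type curve is

    template(group, daytype) + Σ_k ξ_ik φ_k(t) + Σ_p x_ip β_p(t)

- **Templates** are a constant baseline (3.6 log-counts ≈ 36 counts/min)
  plus a sharp morning Gaussian peak (07:00, SD 0.9 h, amplitude 1.1), a
  broad evening peak (20:00, SD 2.2 h, amplitude 0.8) and a negative
  overnight trough (03:30, SD 1.1 h, depth 0.9) — the bimodal crepuscular
  pattern of indoor cats, with count levels in the range reported for real
  collar data. Weekend templates delay the morning peak by 1.5 h, flatten it
  to 65% and widen it by 30% (owners rise later and less uniformly), and
  flatten the evening peak slightly. DJD templates multiply all three
  excursions by an attenuation factor (default 0.6): muted peaks *and*
  shallower troughs, not a uniform downward shift.
- **Inter-cat variability** uses a low-rank orthonormal Fourier basis
  (orthonormalized on the grid to 1e-10) with eigenvalues (1.0, 0.5, 0.25);
  weekday and weekend scores per component are bivariate Gaussian with a
  planted correlation of 0.6.
- **Covariates** are group-dependent: Normal cats are younger (age ≈
  N(6, 2)) with negligible pain/DJD scores; DJD cats are older (≈ N(12, ·))
  with TPain and TDJD driven by a shared latent severity, preserving the
  confounding structure the regression must handle. BCS is sampled with SD
  1.3 so the discrete 1–9 scale keeps several levels in small cohorts.
  The default planted effect is an age effect that lowers both activity
  peaks (−0.12 log-counts per SD of age at the peak centers).
- **Counts** invert the analysis transform: the latent curve is constant
  within each 5-minute bin, per-minute lognormal noise (SD 0.6) is added,
  and `counts = round(exp(latent + noise) − 1)` clipped at zero.

Identical configurations (including seed) produce bit-identical cohorts and
byte-identical CSV exports. With zero noise, preprocessing recovers each
latent curve up to count rounding: the per-bin error is bounded by
`|ln(1+round(c)) − ln(1+c)|`, which is below 0.02 wherever counts reach ~25
and is asserted analytically elsewhere.

What the generator does **not** emulate: device physics (32 Hz sampling,
voltage-to-count conversion), collar non-wear gaps and removal artifacts,
owner-schedule covariates, day-to-day autocorrelation beyond the day-type
structure, and treatment periods. Passing tests therefore demonstrate that
the statistical machinery recovers planted structure under the assumed data
model — not that real accelerometer data satisfies that model.

## Pipeline

The orchestrated run mirrors the analysis sequence of a case-control study:
the two DJD sub-studies are first checked for poolability (distribution
test plus the four LRT settings); if the check rejects, they are pooled
anyway with a recorded warning, since automated gatekeeping on p-values is
fragile. Then pooled group profiles, per-group×day-type FPCA on intensity,
both regression models with bootstrap bands, the group-comparison LRT table
(weekend/weekday × activity/intensity × four covariate settings,
Bonferroni per row), paired day-type tests, and the distribution tests. All
randomness derives from one seeded generator hierarchy; the run manifest
records the seed, sizes and every decision default in force, and reruns are
byte-identical.

## Problem sizes and limitations

The test suite and acceptance script use reduced resampling sizes —
200-simulation LRT nulls, 100–200 bootstrap draws, 199–499 permutations,
and Monte-Carlo studies of 40–200 replicates — chosen as the package's
desk-scale defaults; headline-scale runs (10,000 simulations, 2,000
bootstrap draws) are a flag away and scale linearly. Known limitations: the
LRT is a working-likelihood statistic with a resampling null, not a
parametric likelihood-ratio test with an asymptotic distribution, so
p-values from different null-construction choices are comparable only
approximately; the distribution test's component count rule makes its power
depend on how curve variance concentrates; and the regression assumes
complete curves on the common grid (no sparse/irregular support).
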