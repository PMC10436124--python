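# Methods

This note records the statistical models, the synthetic-data design, the
numerical choices, and the known limitations of `qgsurv`.

## Data model

The unit of analysis is the person-period record: subject id, an interval
(start, stop] in years of time-on-study, an event indicator (1 only on a
subject's final record), that interval's annual-mean exposures (PM2.5,
MDA8 O3, temperature), and time-constant categorical covariates.  A subject
is at risk at time t if start < t ≤ stop.  Calendar time drives exposure
updates (one record per calendar year of follow-up); the hazard timescale
is time since cohort entry.  Expansion from subject-level follow-up to
person-periods conserves person-time and event counts exactly, and a
subject censored exactly at a year boundary contributes no zero-length
record.

Complete-case covariates are the contract: records reaching a fit must
carry schema-valid labels.  The default schema holds the twelve covariates
of the study's main adjustment set (age group, sex, urbanicity, region,
marital status, BMI class, cooking fuel, smoking, drinking, income,
education, plus ambient temperature as a continuous covariate).

### Quantization

Each exposure is mapped to quartile scores 0–3.  Pinned conventions, chosen
once for reproducibility where any consistent rule would do:

- cut points are the 25/50/75th percentiles over **person-period records**
  (the fitted covariate is the record-level value), type-7 linear
  interpolation;
- bins are right-closed: x ≤ q25 → 0, q25 < x ≤ q50 → 1, q50 < x ≤ q75 → 2,
  x > q75 → 3; ties at a cut point fall in the lower category;
- a degenerate distribution (q25 = q50 or q50 = q75) is an error rather
  than a silent collapse.

## Cox engine

The counting-process partial likelihood with Efron (default) or Breslow
tied-event corrections is maximized by Newton–Raphson with analytic
gradient and observed information, step-halving on any likelihood decrease,
and convergence when max|score| < 1e-8 or the relative log-likelihood
change falls below 1e-10.  The variance estimate is the inverse observed
information at the optimum.  Without tied event times Efron and Breslow
coincide exactly; the test suite checks this, checks the likelihood against
a brute-force risk-set enumeration, and checks fitted coefficients against
an independent survival library on simulated cohorts (agreement ~1e-12).

Risk-set sums are computed in O(n·p²) per evaluation: each record is at
risk for a contiguous run of ordered event times, so per-event-time sums
are differences of cumulative bucket sums, with the p×p Gram blocks
accumulated by small per-bucket BLAS products rather than materialized
per-record outer products.

Rank deficiency is detected on mean-centered design columns before
iteration (a constant column carries no partial-likelihood information even
though the raw matrix is full rank) and reported with the offending column
name.  Coefficients exceeding 15 in absolute value set a
monotone-likelihood warning flag.

### Splines

Nonlinear exposure–response uses a natural cubic spline with 3 degrees of
freedom: interior knots at the 33.3/66.7th percentiles, boundary knots at
the 1st/99th (pinned).  The basis is the truncated-power natural-spline
construction (linear beyond the boundary knots); the curve is reported as
the log-HR difference from a reference exposure (default: median) with
pointwise delta-method intervals, hence exactly zero with zero width at the
reference.

## Quantile g-computation

The mixture model is the linear, no-interaction specification: quantized
exposures enter the Cox model jointly as numeric scores; ψ = Σβ_j is the
log HR per simultaneous one-quantile increment, var(ψ) = 1ᵀΣ1 from the
coefficient covariance, and weights are each coefficient's share of its
direction's sum (summing to 1 with concordant signs, to 1 per direction
otherwise).  The bootstrap/marginal-structural variant for nonlinear
mixtures is deliberately out of scope: the reported quantity is a single
per-quantile joint HR with weights, for which the coefficient-based form is
exact.  Wald variance is used throughout.  Temperature is an adjustment
covariate, not a mixture member.

## Attributable fractions

Point estimates use the multicategory Levin formula
PAF = Σp_i(RR_i−1)/[1+Σp_i(RR_i−1)].  Two prevalence mappings are
provided:

- **single-increment** (default): one exposed category, p = 0.25,
  RR = exp(per-quantile β).  This is the operative published usage — it
  reproduces the printed PAFs from the printed HRs to rounding
  (HR 1.18 → 4.31%, HR 1.12 → 2.91%, unrounded 1.1176 → 2.86%);
- **multicategory**: categories k = 1..3 at p = 0.25 each with
  RR = exp(kβ), which gives systematically larger values and is retained
  for sensitivity.

The joint PAF is the single-increment PAF of the qgcomp mixture ψ.  The
complement-product combination 1−Π(1−PAF_i) is provided as a secondary
utility only: applied to the individual PAFs it gives 7.11%, inconsistent
with the mixture-based 4.32%, because it double-counts overlapping
contributions of correlated exposures.

Interval estimates draw 10,000 coefficient vectors from N(β̂, Σ̂) and take
percentile (2.5, 97.5) endpoints of the mapped PAFs (no bias correction).
Since the PAF depends on the draw only through the scalar 1ᵀβ, the draw is
taken on that margin — exactly equivalent in distribution.  Draws are
reproducible under a seed; doubling the draw count moves the endpoints by
less than 0.1 percentage points on the calibrated fixture.

## Subgroups and heterogeneity

Stratified analyses refit the single-pollutant and mixture models within
each level of a covariate, dropping that covariate from the adjustment set.
Between-stratum differences use z = (b₁−b₂)/√(SE₁²+SE₂²) with two-sided
normal p-values; Bonferroni correction uses m = C(levels, 2), the number of
pairwise comparisons within the variable, and both raw and adjusted values
are reported (published subgroup tables do not state which convention they
print).  Temperature subgrouping uses quartiles of subject-mean annual
temperature.  `se_from_ci` back-calculates a log-scale SE from a printed
95% interval, (ln U − ln L)/3.92 — a consistency-check utility for
published tables, not part of estimation.  VIF screening computes
1/(1−R²_k) per design column.

## Synthetic cohort generator

The generator is the package's study stand-in; its defaults are the
published cohort's printed moments, and they are fixed rather than tuned:

| quantity | default | source of calibration |
| --- | --- | --- |
| subjects | 8,490 | cohort size |
| follow-up | Normal(6.9, 2.3) yr truncated to [1, 11] | published mean (SD) |
| PM2.5 | mean 42.85, SD 12.74 µg/m³ | published text moments |
| MDA8 O3 | mean 94.19, SD 5.62 µg/m³ | published moments |
| temperature | mean 15.0, SD 4.5 °C | plausible for the study regions |
| r(PM2.5,O3), r(PM2.5,T), r(O3,T) | 0.663, 0.090, 0.428 | published correlations |
| AR(1) persistence | 0.8/yr on the latent scale | chosen to mimic slowly varying annual pollution |
| covariate margins | published baseline table | twelve main-model covariates |
| cumulative incidence | 6.9% | published event fraction |
| true per-quantile log HR | 0.68·ln 1.18 (PM2.5), 0.32·ln 1.18 (O3) | published joint estimate and weight split |

Exposures are Gaussian-copula draws: a latent trivariate normal with the
target correlation matrix, AR(1) across years within subject (which leaves
the cross-sectional correlations at their targets), scaled to the target
mean/SD and clipped at zero for the concentrations (the clip moves
< 0.05% of PM2.5 mass and is negligible for O3).  The published exposure
quartiles are mildly right-skewed relative to a normal with the published
moments; the generator pins the Gaussian marginal, so its empirical
quartiles are the Gaussian-implied ones (34.3/42.9/51.4 for PM2.5), not the
published ones — a deliberate simplification.  A second PM2.5 preset
(mean 46.20) carries the study's alternative printed summary; the two
published summaries disagree and both are available.

Covariates are drawn independently per subject at the configured margins;
dependence between covariates is injectable for stress tests but off by
default.  Events are piecewise-exponential: within each subject-year the
hazard is λ₀·exp(Σβ_j q_j + covariate terms), with q_j the quartile score
of the year's exposure computed against cut points from the full generated
exposure table (using post-censoring person-years would make cuts depend on
event times, a circularity; the difference is second order).  Event times
come from inverse-transform sampling of the accumulated hazard; with
`baseline_hazard="calibrate_to_incidence"`, λ₀ is solved by bisection so
the expected event fraction given the drawn follow-up equals the target.
Effect modifiers multiply the exposure part of the log hazard for subjects
in a named covariate level.  Everything descends from one integer seed via
SeedSequence spawning, so each stage has an independent reproducible
stream.

What the generator does **not** emulate: spatial exposure structure and
address changes, covariate–exposure dependence (e.g. urbanicity–PM2.5),
interval (wave-based) outcome detection by default (an exact-time design;
events are observed at their true times), missing data, and loss to
follow-up beyond independent censoring.  Passing recovery tests therefore
demonstrates correctness of the estimators under the assumed
proportional-hazards world, not robustness to those real-data features.

## Validation design and problem sizes

Because the study's individual-level data are not deposited, validation is
parameter recovery: set the generator truth to the published estimates,
run the full pipeline, and require the seed-averaged estimates to land on
the truth within Monte-Carlo tolerance.  The acceptance script uses 50
cohorts of 8,490 subjects per scenario (single-pollutant O3 and PM2.5,
the joint mixture, and an obese-stratum effect-modification scenario with
the stratum effect planted at the published obese-subgroup estimate), a
~59,000-subject-year exposure draw for the correlation check, and 10,000
Monte-Carlo draws for PAF intervals.  The test suite uses smaller cohorts
(1,200–8,000 subjects) for unit and property checks and 200 replicates of
n = 2,000 for Wald coverage, which must lie in [90%, 99%] at nominal 95%.

One estimator-choice note: the reported "PM2.5 weight" is the sign-rule
weight (share of the positive-direction effect), averaged over seeds.  The
naive per-seed ratio β_PM/ψ is unbounded when ψ̂ crosses zero and its mean
does not converge usefully; the sign-rule weight is bounded and is the
quantity the mixture model defines.

## Numerical details and degenerate inputs

- Linear predictors are max-centered before exponentiation.
- Newton steps solve the (positive-definite) information system directly;
  step-halving caps at 30 halvings.
- Zero events, non-finite linear predictors, non-positive-definite draw
  covariances, PAF inputs with Σp_i > 1 or RR ≤ 0, and margins not summing
  to 1 are hard errors with specific messages.
- Strata with zero events are skipped with a warning rather than fitted.
- CSV round-trips are bit-exact (`%.17g` on write, round-trip float parsing
  on read).

## Limitations

- Time-varying *coefficients* (as opposed to covariates) are not
  implemented; hazard ratios are time-constant.
- No frailty/random effects, no penalized splines, no left truncation
  beyond what start–stop encoding expresses.
- The qgcomp implementation is the coefficient-based linear specification;
  nonlinear mixture dose-response would require the bootstrap variant.
- The PAF prevalence models assume the quartile design (p = 0.25); other
  exposure codings need explicit category proportions via `paf_levin`.
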