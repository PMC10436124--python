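# qgsurv

Quantile g-computation and time-varying Cox models for air-pollution
mixture cohort studies.

## The problem

Epidemiological cohorts increasingly ask not only whether a single air
pollutant raises the risk of a chronic outcome, but what a correlated
*mixture* of pollutants does jointly, and how much of the disease burden
that mixture accounts for.  The motivating setting is a prospective cohort
of Chinese adults aged 50+ followed for about 7 years, with annual-mean
fine particulate matter (PM2.5) and maximum daily 8-hour ozone (MDA8 O3)
assigned to each participant-year and first onset of asthmatic symptoms as
the outcome.  The two exposures are strongly correlated (r ≈ 0.66), which
makes single-pollutant estimates mutually confounded and motivates a
mixture summary.

`qgsurv` implements that analysis as a reusable, tested pipeline:

1. **Counting-process Cox regression** — person-period (start, stop]
   records carry each calendar year's exposure as a time-varying covariate.
   The partial likelihood (Efron or Breslow tie handling) is maximized by
   Newton–Raphson with analytic gradient and Hessian; each exposure enters
   as a quartile score 0–3, so exp(β) is the hazard ratio per quantile
   increment.  Natural-spline (df = 3) exposure–response curves probe
   nonlinearity.
2. **Quantile g-computation** (`QGCompCox`) — all mixture exposures are
   quantized and entered jointly; the mixture effect ψ = Σβ_j is the log
   hazard ratio for a simultaneous one-quantile increase of every
   component, with var(ψ) = 1ᵀΣ1 and component weights β_j / Σ(same-sign β).
   Weights sum to 1 when all coefficients share a sign, and each direction's
   weights sum to 1 (total 2) otherwise.
3. **Population-attributable fractions** — the multicategory Levin formula
   PAF = Σp_i(RR_i−1) / [1+Σp_i(RR_i−1)], applied in single-increment form
   (exposed proportion 0.25, RR = per-quantile HR), with percentile
   confidence intervals from 10,000 multivariate-normal coefficient draws.
4. **Subgroup heterogeneity** — stratified refits (dropping the stratifying
   covariate from adjustment), two-sample z tests
   z = (b₁−b₂)/√(SE₁²+SE₂²) on the log scale, Bonferroni correction over
   the C(levels, 2) pairwise comparisons, and VIF collinearity screening.
5. **A calibrated synthetic-cohort generator** — Gaussian-copula exposures
   with AR(1) year-to-year persistence, baseline covariates at the study's
   published margins, and piecewise-exponential event times whose baseline
   hazard is calibrated by bisection to a target cumulative incidence.
   Because the study's individual-level data are not public, the generator
   is the test bed: plant the published effect sizes as simulation truth
   and verify the pipeline recovers them.

The models are scikit-learn style estimators (`CoxTimeVarying`,
`QGCompCox`): hyperparameters in the constructor, data in `fit`, results in
trailing-underscore attributes, `get_params`/`set_params`/`clone`
compatible.  Module-level helpers (`fit_cox`, `fit_qgcomp`, `paf_mc_ci`,
`subgroup_fits`) wrap them for cohort-level use.

## Worked example

```python
import numpy as np
from qgsurv import GeneratorConfig, make_cohort, fit_cox, fit_qgcomp, paf_mc_ci
from qgsurv.pipeline import DEFAULT_COVARIATES

cfg = GeneratorConfig(n_subjects=8490)          # calibrated study defaults
cohort, summary = make_cohort(cfg, seed=7)

fit = fit_cox(cohort, "pm25", DEFAULT_COVARIATES)
qg = fit_qgcomp(cohort, ["pm25", "o3"], DEFAULT_COVARIATES)
paf = paf_mc_ci(qg, "mixture", n_draws=10_000, seed=7)
```

Output for this seed:

```
subjects: 8490, events: 596 (7.0%), person-years: 55358
r(pm25, o3) = 0.664
PM2.5 per-quantile HR 1.15 (95% CI 1.07-1.24)
joint HR 1.20 (95% CI 1.10-1.31); weights pm25=0.48, o3=0.52
joint PAF 4.82% (95% CI 2.52%-7.17%)
```

Reading the numbers: the generator reproduces the cohort's scale (8,490
subjects, ~7% cumulative incidence, exposure correlation 0.66).  The
single-pollutant fit estimates the hazard ratio per quartile increment of
PM2.5; the joint HR says a simultaneous one-quantile rise of both
pollutants multiplies the symptom hazard by 1.20 in this replicate, and the
weights split that effect between the components.  The joint PAF is the
share of events attributable to the mixture under the single-increment
Levin model.  Any one seed fluctuates around the simulation truth
(joint HR 1.18, PM2.5 weight 0.68); averaging over seeds recovers it —
that is what the acceptance script measures.

The same pipeline runs from the shell:

```bash
qgsurv simulate --seed 7 --out cohort.csv
qgsurv fit-qgcomp --cohort cohort.csv --out qgfit.json
qgsurv run --seed 7 --out results/        # full simulate→fit→PAF→report run
```

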