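# Methods

## Data-generating process

The synthetic population is defined by a 210-cell joint probability table
over sex (female/male), seven 5-year age groups (55–59 … 85–89), five
education categories (5, 8, 11, 13, 17 completed years of schooling, i.e.
primary through university in the Italian system), and cognitive status
(healthy, mild cognitive impairment, dementia). The table describes the
Italian resident population aged 55–89 as of January 2023; its cells are
stored as printed percentages (3 decimals) and rescaled at load time so the
probabilities sum to exactly 1 (the printed values sum to 100.004 because
of rounding). Marginal prevalences implied by the table are roughly 9.5%
MCI and 4.0% dementia. Documented provenance of the table, recorded here as
constants only: prevalence ratios of 1.14 per year of age, 0.49 per
education level, and 1.07 for female sex for dementia, and 1.03 / 0.45 /
1.14 for MCI, with overall prevalence rescaled by ×2 (dementia) and ×6
(MCI) to match recent reports. The package does not re-derive the table.

Cohort sampling is a single flattened 210-way categorical draw per
individual — distributionally identical to hierarchical sampling and
simpler to test. Within the sampled age group, age is drawn uniformly on
the half-open interval `[low, high + 1)`: a person in the "85–89" group can
be 89.99 years old, on the reasoning that someone aged 89 years and 11
months still reports age 89. This convention is a declared choice, not an
inferred one; the closed-interval alternative `[low, high]` would make
individuals on average half a year younger, which shifts age-sensitive
stratum metrics by about one percentage point (visible mainly in the
specificity of the oldest, least-educated stratum).

### Scores

Four normative equations for the mean MoCA score of a healthy Italian are
bundled, each linear in one transformed age term and one transformed
education term, written in centered form (evaluating at the centering
constants returns the printed intercept):

| id | age basis | education basis | intercept |
|---|---|---|---|
| `aiello` (default) | age³ | ln(edu) | 24.17 |
| `conti` | age | 1/edu | 23.28 |
| `santangelo` | log₁₀(100 − age) | √edu | 21.98 |
| `montemurro` | age | edu | 25.468 |

All four are strictly decreasing in age and increasing in education over
the supported domain (age ∈ [55, 90), edu ∈ [5, 17]); this is enforced by a
grid test. `aiello` uses the natural log, `santangelo` the base-10 log,
exactly as published. None of the equations includes sex.

A raw score is the normative mean minus a status deficit (0 for healthy,
5.1 points for MCI, 10.7 for dementia — rounded consensus values from
three independent clinical studies) plus i.i.d. Gaussian noise with
σ = 2.9 points (the residual SD of the normative fit; 3.4 available as a
robustness preset). Whether the noise is added before or after the status
offset is immaterial, since both are additive. In the main configuration
scores stay continuous; the `rounded` preset rounds to the nearest integer
— half-away-from-zero, so x.5 goes up for these positive scores, making
tie cases reproducible — and then clips to [0, 30] (order fixed for
determinism, though immaterial for integer bounds).

## Correction

The correction model is an ordinary least-squares regression (via
`statsmodels`) of raw score on the generating equation's centered age and
education terms, fitted only on the healthy individuals of the development
sample. The corrected score of any individual, whatever their status, is
`raw − prediction(age, edu) + β₀`; it is never rounded or clipped. Because
the correction is an additive shift per (age, education) value, it
preserves within-cell ranks and yields exactly the same AUC, sensitivity
and specificity as the common Z-score correction (subtract β₀, divide by
the residual SD) — a property asserted in the tests.

Two choices where the procedure is underdetermined:

- The correction basis always matches the generating equation (when
  simulating under `santangelo`, the fit uses log₁₀(100 − age) and √edu).
- In the rounded/clipped variant the regression is fitted on the rounded,
  clipped scores — those are the observed data — while corrected scores
  remain continuous.

Education enters the fit through its transformed years, never through
levels.

## Metrics and cutoffs

Lower scores indicate impairment: an individual screens positive when
their score is strictly below the cutoff (scores equal to the cutoff are
negative; with continuous scores ties have probability zero, so the
convention only matters for integer-score variants). The AUC is the
Mann-Whitney statistic P(impaired < healthy) + ½ P(tie), computed through
`scikit-learn`'s ROC machinery with negated scores and verified against a
brute-force all-pairs oracle in the tests. Two contrasts are evaluated:
(MCI ∪ dementia) vs healthy, and MCI vs healthy with dementia cases
excluded — the latter mirroring the screening of previously undiagnosed
persons, and the only contrast for which sensitivity/specificity are
reported.

Cutoffs are determined marginally on the development sample: the
specificity-97.7% and specificity-84.1% cutoffs are linearly interpolated
empirical quantiles (the "type 7" rule, `numpy.quantile`'s default) of the
healthy scores at probabilities 0.023 and 0.159, and the sensitivity-84.1%
cutoff is the 0.841 quantile of the development MCI scores. The two
specificity targets correspond to mean − 2 SD and mean − 1 SD under a
normal model. For continuous scores the preselected operating point is hit
exactly in the development sample (up to 1/n). The reference
implementation's exact quantile and tie conventions are unknown; agreement
is asserted at the level of the Mann-Whitney/quantile definitions with
stochastic tolerances.

Sensitivity and specificity are evaluated in the validation sample both
marginally and per age-education stratum (7 age groups × 5 education-year
categories; the two "three-level" education columns, 11 and 13 years, are
kept distinct throughout). A stratum with no members of a class in a
replication carries an undefined (NaN) metric for that replication and is
simply dropped from that metric's across-replication mean — never counted
as zero. The marginal sensitivity equals the MCI-count-weighted average of
stratum sensitivities exactly (and analogously for specificity with
healthy counts), which is asserted to 1e-12.

## Replication engine

One replication: sample a development cohort (default n = 5,000) and an
independent validation cohort (default n = 50,000), generate scores, fit
the correction on healthy development individuals, correct everyone,
determine the three cutoffs per score type on the development sample, and
evaluate everything on the validation sample. Replications are repeated
`n_reps` times (library default 10,000, matching the full study); each
metric is summarised by its mean and empirical 2.5th/97.5th percentiles.

Seeding is counter-based: replication *i* uses
`SeedSequence(master_seed, spawn_key=(i,))`, so any replication is
reproducible in isolation and the summary is a pure function of the
configuration. Reports are plain CSV plus a JSON manifest echoing the
configuration and the mean fitted correction coefficients.

## Problem sizes used in the packaged checks

Replication means converge quickly: per-replication 95% spreads are about
±0.003 AUC and ±2–4 percentage points for sensitivity/specificity, so a
few hundred replications estimate the 10,000-replication means to well
under a tenth of those spreads. The acceptance script therefore uses 500
replications at the full n_dev = 5,000 / n_val = 50,000; the test suite
uses 250 (main configuration) and 200 (rounded variant). Sparse strata
(the youngest-most-educated cell contains ~0.03% of the population, i.e.
~15 MCI patients per 50,000-person validation sample) are the slowest to
converge, which is why stratum-level checks carry wider tolerances.

## What the generator does and does not emulate

It emulates: the demographic and cognitive-status mix of the 2023 Italian
population aged 55–89, the dependence of scores on age, education, and
status, and the develop-then-validate workflow for norm and cutoff
determination. It does not emulate: item-level test structure, selection
into testing, measurement error correlated with covariates,
heteroscedastic residuals, secular drift in education attainment, or
misdiagnosis of status labels. Passing checks therefore validate the
statistical mechanics of correction, not the clinical accuracy of the MoCA
itself. Predictive values (PPV/NPV), partial AUC, per-replication
confidence intervals, and publication-grade figure rendering are out of
scope; the stratum CSV contains everything needed to plot the
sensitivity/specificity-by-stratum figure.
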