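# Methods

## Scope and design

The package implements the standard small-area mapping workflow for anemia
severity in women of reproductive age (WRA): woman-level hemoglobin is
adjusted and thresholded into WHO severity categories, collapsed to cluster
binomial counts, modelled with a continuation-ratio space–time
binomial-logit Gaussian-process model with stacked-ensemble covariates, and
post-processed into masked grid surfaces, admin-level aggregates, counts,
YLDs, raked (calibrated) estimates, trend projections and cross-validated
error metrics.  Everything runs at desk scale on synthetic data whose
generating process matches the model, so each stage can be checked against
known truth; nothing in the package depends on restricted survey databases.

## Hemoglobin preparation

Sources may deliver raw, smoking-adjusted, elevation-adjusted or fully
adjusted hemoglobin (g/dl); a provenance flag ensures each decrement is
applied exactly once.  Defaults follow the WHO/CDC convention — elevation
decrements 0.2/0.5/0.8/1.3/1.9/2.7/3.5/4.5 g/dl starting at 1,000 m in
500 m bins, 0.3 g/dl for smokers — and are configuration data, not code.
Severity bands are closed on the left and open on the right: non-pregnant
severe <8.0, moderate [8.0, 11.0), mild [11.0, 12.0), non-anemic ≥12.0;
pregnant bands sit 1 g/dl lower.  Records outside ages 15–49 are dropped
before collapsing.  Polygon-referenced (areal) records are resampled to
pseudo-points at population-weighted cell centres, one point per 10
intersecting cells (min 1, max 100 — the proportionality constant is a
package choice, exposed in config), each carrying the full counts with
weights 1/k summing to one, so one areal record contributes one effective
observation.

## Stacked ensemble

Three child learners stand in for the conventional trio: a penalized
spline additive model (`SplineTransformer` + ridge), gradient-boosted
regression trees, and an L1-penalized linear model, all fit to empirical
logits with effective-sample-size weights (scikit-learn throughout).
Per-observation predictions are strictly out-of-sample via
cluster-stratified five-fold splitting; grid predictions come from all-data
refits.  Stage-2/3 learners are fit on the conditional denominators (women
who are anemic; women who are moderately-or-severely anemic).  In the parent
model the three logit-scale predictions carry coefficients constrained to
sum to one, implemented exactly by the reparameterization β₃ = 1 − β₁ − β₂,
so the combination is an affine combination of logits.

## Geostatistical core

Per continuation-ratio stage the latent vector stacks fixed effects, the
knot-level GP, country intercepts and a per-observation nugget.  The GP
covariance is separable: ω²·Matérn(ν=2, κ=√(8ν)/δ) between knots (Euclidean
distance on degrees — adequate at a 10° domain; no great-circle correction)
and AR1(ρ) across years.  All covariance algebra (solve, log-determinant,
quadratic form, sampling) uses the eigendecompositions of the two factors
and never materialises the Kronecker product; equality with dense
computation to 1e−8 is asserted in tests on ≤50 knot-year instances.  A
tiny jitter (1e−10·ω²) keeps the spatial factor positive definite.

The continuous field is represented on a regular knot lattice (default
spacing 3 grid cells) with bilinear interpolation to observation and
prediction points — a low-rank GP playing the role of a triangulated SPDE
basis, chosen because it is dependency-free and admits exact dense oracles.
Resampled pseudo-points contribute weighted log-likelihood terms (weight ×
binomial log-pmf), consistent with their weights summing to one.

Inference is empirical Bayes: Newton optimization of the latent field at
each hyperparameter value (the Laplace approximation), Nelder–Mead
maximization of the Laplace marginal posterior over transformed
hyperparameters (log ω², log δ, atanh ρ, log γ², log σ²), a
central-difference Hessian giving a Gaussian approximation to the
hyperparameter posterior, and posterior draws formed by mixing Gaussian
latent draws over (default) 25 hyperparameter draws.  Priors are
weakly-informative normals on the transformed scale; the range prior
centres on 0.3× the domain extent, the usual penalized-complexity-style
anchoring.  Fixed effects get a N(0, 5²) prior, which also regularizes
separated (all-0/all-1) data.  Draws across the three independently fitted
stages are paired by draw index (the pairing is arbitrary but fixed).
Grid-prevalence draws exclude the nugget (it is observation noise);
data-level predictive checks re-add it and binomial sampling.

Model variants — raw covariates, raw + GP, stackers, stackers + GP (the
standard model) — are a config switch; variants without the GP keep country
and nugget effects.

## Post-estimation

Masking precedes aggregation: cells under 10 persons/km² (threshold scaled
to the cell area) or flagged barren contribute neither numerator nor
denominator.  Aggregation is population-weighted and draw-wise; counts
multiply unit prevalence by WRA population (default 0.25 × total population
— a configured fraction standing in for an age–sex raster); YLDs use
disability weights 0.004/0.052/0.149 (mild/moderate/severe, GBD convention,
config data).  Public-health-problem classes use the <5/5–19.9/20–39.9/≥40%
bands.  Raking computes one overall-anemia factor per country-year **per
draw** (external ÷ that draw's national aggregate), interpolates linearly
between available years, carries end years constant (flagged extrapolated),
and multiplies all three severity marginals by the same factor — preserving
the severity identity and within-country spatial structure exactly; values
clipped at 1 trigger residual re-derivation of moderate and are logged.
Applying one factor to all severities (rather than raking stages
independently) is a package convention; the alternative breaks either the
identity or national exactness.

Trends: the pairwise annualized rate of change is the difference of logits
of adjacent years.  A literal reading of the ratio form logit(p_t/p_{t−1})
is available behind `use_printed_formula` for audit, but it is positive for
declining prevalence and incompatible with the logit-space projection
`Proj = logit⁻¹(logit(p_last) + AROC·k)`, so the logit-difference is the
default.  Weights W_t ∝ (t−2000)^γ with γ = 1 by default (the exponent is
elsewhere chosen by out-of-sample validation, not reproduced here).
Attainment probability is the fraction of paired draws whose projection is
≤ half the baseline-year draw; when the nominal 2012 baseline predates the
estimation window the first estimation year is used and logged.  Both
draw-level and point (mean-based) projections are reported.

## Validation

Bi-tree folds: alternating-axis splits (longitude first) at the weighted
median of sample sizes, ties to the lower side; a node splits only if its
total exceeds the target (default 2,000) and both children keep ≥500.
Leaves are assigned to five folds greedily, largest first.  All three
conventions (first axis, tie side, greedy balancing) are fixed package
choices.  Metrics are computed on sample-size-weighted unit-year aggregates
at each admin level: mean error, RMSE, CoV (100·sd/mean of predictions),
Pearson correlation, and 95% coverage against predictive intervals that
include nugget and binomial sampling noise (coverage is a data-level
statement).  Stacker predictions are computed once on the full data; their
own internal five-fold out-of-sample construction limits, but does not
eliminate, leakage into the CV comparison — acceptable for the qualitative
variant ordering it supports.

## Synthetic generator

The generator emulates exactly the structure the model assumes: logit
truth = intercept + covariate effects + Matérn⊗AR1 field (simulated at
cell level) + country effect, per stage, with a per-cluster-stage nugget at
observation time; cluster cells are drawn population-weighted; women get
categories from the truth, adjusted hemoglobin uniform within the
category's WHO band, and raw hemoglobin by *adding* the configured
decrements — making classify(adjust(raw)) an exact round trip.  The default
scenario is a 20×20 grid of 0.5° cells over 2013–2018 with 3 countries
(nested 6 admin-1, 12 admin-2 rectangles), 2 smooth covariates, ω²=0.3,
δ=4°, ρ=0.8, γ²=0.09, σ²=0.05, 150 clusters of mean size 35, four areal
polygons of 1,000 women, and a national series biased ×1.15 — sized so the
full pipeline runs in minutes.  What the generator does **not** emulate:
survey design effects beyond a single weight, covariate measurement error,
non-stationarity, hemoglobin distributions within categories (the uniform
choice is conventional; no within-category distribution is established for
real data), spatially varying age structure.  Passing tests therefore
demonstrate correctness of the machinery and calibration under a
well-specified model, not robustness to real-data misspecification.

## Numerical choices and problem sizes

Newton iterations stop at step ∞-norm 1e−9 (max 60, step-halving line
search); Nelder–Mead runs up to 350 evaluations with 5e−3 parameter
tolerance; the hyper-Hessian uses step 0.05 with eigenvalue flooring at
1e−4 for flat directions (a flat direction then yields a wide, finite
interval).  Boundary prevalences are nudged by 1e−6 before logits.  The
test and analysis configurations use 100–250 posterior draws and 150-draw
CV refits — enough for interval summaries at the precision the checks
require — while the config default remains 1,000 draws, the convention for
published uncertainty intervals.

## Known limitations

- Empirical-Bayes + Laplace understates hyperparameter skew; intervals are
  symmetric on the transformed scale.
- The knot lattice smooths features finer than its spacing; at the default
  spacing (1.5°) relative to the range (4°) the approximation error is
  negligible, but short-range fields would need a denser lattice.
- Stage draws are paired arbitrarily; cross-stage posterior dependence is
  not modelled (stages are conditionally independent given the data, but
  finite-sample pairing of extremes is meaningless).
- Raking above prevalence 1 clips; heavy upward bias in the external series
  degrades exactness by design.
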