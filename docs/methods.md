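# Methods

This note documents the models, the synthetic study design, the numerical
choices and the known limitations of the package. Everything stated here is
computed by the code; nothing is quoted from elsewhere.

## Geographic conventions

Coordinates are WGS84 decimal degrees. Rasters are row-major with row 0 at
the northern edge; the origin is the lower-left corner (ESRI ASCII
convention), registration is cell-centre, and a point belongs to the
half-open cell [x, x+Δ) × [y, y+Δ). Distances use a local equirectangular
approximation (longitude scaled by cos of the mean latitude); at the
northern-Oman study extent (< 4°) the error versus geodesics is far below
the cell size. The calibration/validation split is purely longitudinal:
records in [56.5°, 59.0°) E train, records in [56.0°, 56.5°) and
[59.0°, 59.5°) E validate; bands are half-open so a record exactly on the
lower train edge trains. When a simulated niche produces fewer than 10
validation-band records the pipeline falls back to a seeded random 25%
holdout (logged and recorded in the run summary), since a geographic split
with an empty validation band defines no evaluation.

## Interpolators

**IDW** uses weights d^(−p), default p = 2 (the common GIS default,
configurable); a target within 1e−9 degrees of a sample returns that
sample's value exactly, and predictions are convex combinations of sample
values. **Ordinary kriging** solves the standard system with a Lagrange
unbiasedness row under a linear semivariogram γ(h) = nugget + slope·h
(γ(0) = 0); with nugget 0 it is exact with zero variance at sample points.
Hotspot surfaces krige annual per-cell record counts; the sample set is
every occupied cell plus a deterministic regular-stride subset of empty
cells (capped at ~300 samples total) so that single-cluster years remain
solvable and the O(n³) solve stays fast. Change maps threshold both years
at a high quantile (default 0.9) of the *reference* year's surface, so a
literally unchanged pair can produce no gained/lost cells.

## OLS, VIF and GWR

The infestation response is fitted by least squares even when binary (a
linear probability model), matching the practice of running OLS/GWR
directly on presence indicators. OLS AIC is n·log(RSS/n) + 2(K+2); VIF_k =
1/(1−R²_k) from regressing predictor k on the others; redundancy screening
iteratively drops the highest-VIF predictor until all VIF ≤ 7.5 (a common
GIS convention — configurable, as no canonical value exists). GWR solves a
weighted least squares problem at every observation with kernel weights
w_ij = exp(−½(d_ij/b)²) (or bisquare), local R² from locally weighted sums
of squares (clipped to [0,1]), global R² from pooled fitted values, and
AIC = n·log(RSS/n) + 2(tr(S)+1) with tr(S) the hat-matrix trace as the
effective number of parameters. AIC constants differ between conventions;
these values are only ever compared within this package.

The bandwidth, when not given, is chosen by leave-one-out cross-validation
over a 12-point log-spaced grid spanning the inter-point distance range,
taking the *largest* bandwidth whose LOO error is within 1% of the best.
The smoothness preference matters: under pure noise the CV curve is flat
and an arbitrary minimum would occasionally select a narrow bandwidth,
inflating the in-sample global R² of a signal-free regression — with the
preference, the zero-effect regime collapses to OLS as it should.

## Variable screening

Pairwise Pearson correlations are computed over all unmasked cells (or
given sample points); zero-variance layers get correlation 0 with a
warning. Jackknife importance fits a caller-supplied trainer (default: a
plain, non-stepwise IRLS logistic) with each variable alone and with each
variable left out, scoring by training AUC. Selection is greedy in
decreasing gain-alone order with a name-order tie-break, accepting a
variable iff |r| < 0.7 against all already-accepted variables — this
realizes "keep the more important member of every correlated pair" and is
deterministic; an exhaustive-subset oracle in the test suite confirms the
greedy set is near-optimal on small instances. The |r| rule applies to the
magnitude: anti-correlated predictors are equally redundant.

## Bias machinery

Survey effort is a Gaussian kernel density of the records, computed as
smoothed counts divided by the smoothed valid-cell indicator so edges and
coastlines do not depress the estimate; the default kernel sd is the
shorter extent side divided by 30 (stated here because "software default"
bandwidths are otherwise irreproducible). Background points are sampled
with probability proportional to this density (bias matching). Presence
records are weighted by inverse relative density rescaled linearly to
[1, 20], after flooring densities at 1% of the mean so that empty corners
do not dominate the rescaling; a non-constant surface attains 1 and 20
exactly, a constant one maps to 1. These two uses jointly down-weight
oversampled localities and make the background mimic the survey bias.

## Learners

All features are layer values standardized against the background mean/sd,
plus squared terms; projection never clamps features to the training range.

**MaxEnt** maximizes mean presence score − log Σ_bg w_b·exp(score) −
β‖λ‖₁ (background weights act as the base measure), a convex problem
solved by FISTA (accelerated proximal gradient) with backtracking and
restart; at the optimum each feature satisfies |E_model[f] − presence
mean[f]| ≤ β (KKT). Coefficients are capped at ±30 because with β = 0 and
separable features the optimum is at infinity. The [0,1] output is a
sigmoid of the linear score centred so the weighted mean presence score
maps to 0.5; the raw normalized density is also exposed. Default β = 0.05
per (standardized) feature.

**GLM** is a binomial logistic fitted by IRLS with step-halving;
coefficients are capped at ±15 under separation (with a warning).
Bidirectional stepwise selection starts from the intercept-only model and
takes the best add-or-drop move by AIC = −2ℓ + 2(terms+1) until no move
improves, so the final AIC never exceeds the intercept-only AIC.

**BRT** is stagewise gradient boosting on binomial deviance: each stage
fits a depth-limited regression tree (greedy variance-reduction splits on
the current residual y − p, weighted, with weighted minimum-leaf mass so
duplicating a row equals doubling its weight) and applies capped Newton
leaf values (±4). Defaults: 150 trees, learning rate 0.05, depth 3, bag
fraction 0.75 — shallow-and-slow in the spirit of standard ecological
practice, but with a fixed tree count rather than held-out-deviance
selection to keep replicated ensembles cheap; all are configurable.

## Ensemble, validation, classification

Per replicate, the background is resampled with a sub-seed derived from the
master seed (SeedSequence([seed, replicate]); BRT members additionally get
SeedSequence([seed, replicate, model]) — any single member is reproducible
in isolation) and every model is refit. Members are scored on the training
presences versus their own replicate's background at the
max(sensitivity+specificity) threshold.

The consensus is the **cellwise member median** by default. A TSS-weighted
mean (TSS ≤ 0 members excluded) and a plain mean are available by
configuration, but the median is the package default for a measured
reason: in the large low-suitability tail of a sharply localized niche, an
averaged consensus inherits the fine-scale rank noise of whichever member
family has the largest absolute scores there (the boosted trees, whose
bagged plateaus order tail cells arbitrarily), which collapses the
consensus's rank correlation with the true surface even when every
GLM/MaxEnt member tracks it at ρ ≈ 0.99. The median is invariant to each
member's output scale per cell and restores ρ ≈ 0.99 at equal or better
AUC. Note the corollary: a single best member can out-rank the consensus;
ensembles buy robustness, not uniform dominance.

Validation follows the presence–background convention (background points
as pseudo-absences): AUC is the rank statistic with ties counted ½, the
threshold maximizes sensitivity + specificity over observed scores (ties
toward the lowest threshold, maximizing sensitivity), and TSS is the exact
quotient (ad−bc)/((a+c)(b+d)). Training backgrounds are bias-matched;
held-out evaluation draws its background uniformly over the domain, the
standard choice when the question is discrimination over the whole
landscape. Classification: high ≥ threshold; marginal in
[marginal_fraction·threshold, threshold), default fraction 0.5 (no
canonical value exists for the marginal/high boundary); unsuitable below.

## Projection

Scenarios are co-registered stacks (named per GCM × RCP × horizon);
members are re-predicted without refitting or clamping and combined with
the same consensus rule; class areas and a 3×3 transition matrix (row sums
= current areas, column sums = future areas) summarize change. Synthetic
future stacks are additive per-layer offsets, sufficient to test ordering
effects (e.g., warming past the niche optimum strictly shrinks the high
class) without any GCM data.

## Synthetic study design

The generator emulates the statistical structure the analysis assumes, on
a 50×70 grid of 0.05° cells over 56–59.5° E, 22–24.5° N:

- **Climate layers** (default 10): Gaussian random fields (white noise
  smoothed at 5 cells, standardized), mixed with a shared field so the
  expected pairwise Pearson r equals `layer_correlation` (default 0.3),
  with distinct per-layer affine units.
- **True suitability**: logistic of −18 + 30·z₂ − 24·z₂² + 24·z₅ − 18·z₅²
  over standardized layers bio2 and bio5 — a sharp, rare, unimodal niche
  (most of the extent near-unsuitable), chosen once so that the
  Bayes-optimal scorer (the truth itself) separates presences from uniform
  background at AUC ≥ 0.95 across seeds; this is the "strong truth, low
  noise" regime the recovery checks target, and it mirrors a real pest
  whose habitat (cultivated palm valleys) is a small fraction of the
  region.
- **Presences** (default 400): cells drawn ∝ truth × a Gaussian
  survey-effort kernel (sd 0.7°, centred mid-extent), jittered within
  cells, years uniform over 2007–2011 and 2015.
- **Station series**: stations uniform over the extent; daily temperature
  with a seasonal cycle and min ≤ mean ≤ max enforced; the infestation
  index is Σ_f slope_f(u)·z_f + noise with slope_f(u) = base + gradient ×
  (centred longitude), defaults (dew point 0.25+0.25s, min temperature
  0.12+0.10s, noise sd 1) sized once so the GWR global R² of the default
  regime lands in ≈ 0.05–0.15 — the weak-signal regime the real
  station analysis reports.

What the generator does *not* emulate: real coastlines or masks, observer
error in coordinates, temporal autocorrelation of surveys, interactions
among climate layers beyond a shared linear factor, or realistic GCM delta
patterns. Passing tests therefore demonstrate that the chain recovers
known structure under its own assumptions, not that the real-data numbers
would be reproduced.

## Problem sizes and determinism

Tests and the acceptance script run reduced problem sizes chosen as the
smallest that leave the checked signals comfortably above sampling noise:
3 replicates per model (9–15 members), 500 background points, 20-seed
loops, 300 stations × 30 days for the regression regimes; the pipeline
default remains 30 replicates and 1000 background points. Every stage
derives its randomness from one master seed via SeedSequence counters, so
whole runs are byte-reproducible.

## Known limitations

- MaxEnt features are linear + quadratic only (matching the GLM term set);
  hinge/product features are out of scope.
- GWR predicts at its fitted locations; no out-of-sample GWR surface.
- Kriging uses a fixed linear semivariogram; no variogram auto-fitting or
  anisotropy.
- The linear probability model for a binary response can fit values
  outside [0,1]; R² for such responses is inherently small and is
  interpreted only comparatively.
- Evaluation treats background as absence; true-absence metrics are not
  available in a presence-only design.
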