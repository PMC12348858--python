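# Methods

## Scope and data model

The pipeline analyses quadrat-level grassland survey tables with the
nested structure site → plot → quadrat.  A row carries site climate (MAP,
mm/y; MAT, °C), biomass pools (AGB, BGB, total, g/m²), specific leaf area
(SLA) and species richness.  Precipitation classes partition the MAP axis
at 400/500/600/700 mm/y with half-open intervals `[lo, hi)`: a value equal
to an edge belongs to the class above it, so "400–500" contains 400.0 and
excludes 500.0.  This makes the partition unambiguous where range labels
would otherwise overlap.  Validation is total — no row is silently
dropped; every violation is reported with its row number — and `total` is
computed as AGB + BGB when absent, or cross-checked at 1e-6 relative
tolerance when present.

## Trade-off statistic

Relative benefit min–max scales each component over *all* quadrats of the
analysis dataset (in-sample by design; scoring new data against a frozen
scaling clamps to [0, 1] with a warning).  The trade-off of quadrat *i* is
the RMS deviation of its two relative benefits from a baseline, signed by
`sign(RB_AGB − RB_BGB)`.

Two baselines are implemented because the RMSE formula admits two readings
of "the mean benefit":

* **per-quadrat** (default): the mean of the quadrat's own two benefits.
  With n = 2 components and the n−1 divisor this collapses to
  |RB_AGB − RB_BGB|/√2, bounded by ±1/√2, zero exactly when the two
  benefits coincide.  This is the only reading that yields one signed
  value per plotted point with those algebraic properties (antisymmetry
  under component swap, invariance under positive rescaling of either
  component), so it is the default.
* **dataset**: the dataset-wide mean benefit as the baseline; a quadrat's
  value then grows with its overall distance from the global balanced
  point, which mixes allocation imbalance with biomass magnitude.  Kept as
  an explicit mode for sensitivity analyses.

An RMSE-per-plot-area divisor is exposed (`area_normalize`); with the
constant 0.25 m² quadrats of the default design it rescales every value
identically and changes no comparison, so it is off by default.

## Allometry

Per class, log₁₀ AGB is regressed on log₁₀ BGB.  The default line is the
standardized major axis — the appropriate symmetric fit when both organs
carry sampling and measurement error; OLS is a sensitivity mode (it always
has the smaller |slope|, by slope_SMA = slope_OLS/|r|).  Confidence
intervals use the Warton & Weber closed form
b·(√(B+1) ± √B), B = t²(1−r²)/(n−2); the isometry test is the Warton
correlation test of (y − b₀x) with (y + b₀x) at b₀ = 1, two-sided.  The
slope is a ratio of log SDs and therefore identical in any log base.
A bootstrap check in the test suite confirms the analytic CI on large
samples.  Verdicts: faster-AGB iff b > 1 and p < 0.05; faster-BGB iff
b < 1 and p < 0.05; otherwise isometric.

## Group comparisons and smooths

Routing is decided by the data: Shapiro–Wilk per group plus Levene across
groups, each at α = 0.05; any rejection sends the variable down the
non-parametric route.  Under jointly valid assumptions with five groups
this keeps the parametric route with probability ≈ 0.95⁶ ≈ 0.74 — the
joint type-I behaviour of six α = 0.05 gates, confirmed by simulation in
the test suite.  Non-parametric: Kruskal–Wallis on midranks (tie-corrected)
with Dunn's pairwise z tests; Dunn p-values are Holm-adjusted (the
correction family is a free choice here; Holm dominates Bonferroni at no
cost).  Parametric: one-way ANOVA with Tukey's HSD (its p-values are
already familywise).  Pairwise decisions at α = 0.05 are condensed into a
compact letter display by the insertion algorithm; sharing no letter is
equivalent to a significant adjusted difference.

Climate–biomass responses are penalized cubic B-spline smooths (basis
dimension 10, second-difference penalty).  The penalty weight is chosen on
a 23-point log-spaced GCV grid; ties resolve toward the heavier penalty,
so noiseless linear data collapse to the linear limit (smooth edf ≈ 1,
deviance explained 1).  Exact-fit penalty candidates that abort the IRLS
loop are skipped; some admissible weight always remains.

## Driver attribution

* **Correlation screen**: pairwise Pearson r with raw two-sided p-values;
  no multiplicity adjustment is applied across the screen — it is
  descriptive, and this is stated prominently here on purpose.
* **Mantel test**: Pearson correlation of strictly-lower triangles;
  permutation of one matrix's rows/columns jointly;
  p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), resolution 1/(n_perm+1).  An
  exhaustive mode enumerates all n! relabelings for small matrices and is
  verified against manual enumeration and (sampling mode) against
  scikit-bio's implementation.  Distance matrices default to Euclidean
  distance on z-scored variables; in the pipeline the Mantel stage runs at
  site level, since sites are the climatic sampling unit and quadrat-level
  matrices would be 945² with heavy pseudo-replication.
* **%IncMSE forest**: an explicit bootstrap of scikit-learn regression
  trees (500 trees, mtry = ⌊k/3⌋, min leaf 5 — the R-style regression
  defaults); per tree, the out-of-bag MSE is compared with the OOB MSE
  after permuting one predictor, and importance is the mean relative
  increase ×100.  Everything (bootstrap, tree seeds, permutations) derives
  from one seed, so results are exactly reproducible.
* **Path model**: piecewise (local-estimation) structural equations, each
  fit by OLS on z-scored variables, so a single-predictor path equals the
  Pearson correlation.  Global topology is judged by Shipley's
  d-separation basis set — one claim per non-adjacent pair, conditioning
  on the union of both parents, testing the partial coefficient of the
  topologically earlier variable in the later one's regression — with
  Fisher's C = −2Σln pᵢ ~ χ²(2k).  Pairs declared as correlated errors
  (default: AGB ~~ BGB, which share unmeasured site drivers such as soil
  and community composition) make no independence claim.  RMSEA and CFI
  are not defined by piecewise estimation, so they are computed from the
  equivalent global model: implied covariance (I−B)⁻¹Ψ(I−B)⁻ᵀ with sample
  exogenous correlations, residual variances 1−R², and residual
  covariances for the declared correlated pairs; ML discrepancy gives the
  χ², df = p(p+1)/2 − free parameters.  Thresholds RMSEA < 0.08 and
  CFI > 0.90 are applied as conventional pass/fail flags.  The default
  topology is MAP → {SLA, AGB, BGB, trade-off} and {AGB, BGB, SLA} →
  trade-off with AGB ~~ BGB.  Biomass pools and SLA enter the model
  log-transformed before z-scoring (they are strongly right-skewed;
  correlations with climate are otherwise attenuated by the skew).

## Synthetic survey generator

The generator is the package's test bed: it emulates the hierarchical
design (63 sites × 3 plots × 5 quadrats = 945 rows by default) with a
statistical structure chosen so that every downstream stage has a known
target.

Generating model.  Site MAP ~ Uniform(262, 772) mm/y (the default regional
range); its standardized value z drives unit-variance log-scale latents
with the configured standardized coefficients (defaults: SLA 0.28,
AGB 0.53, BGB 0.60) plus independent Gaussian noise.  Log BGB is built
class by class: its within-class variance is set analytically so the
expected SMA slope of log AGB on log BGB equals the configured class slope
(defaults 1.15 / 1.12 / 1.10 / 1.00 / 1.15 — isometric only at
600–700 mm/y, faster AGB elsewhere), 92% of its within-class residual SD
is aligned with the AGB residual (producing the strong within-class
log–log correlation, r ≈ 0.9, that real organ pairs show), and the
between-class mean profile is rescaled by solving a small quadratic so the
*global* standardized MAP→BGB coefficient still equals its configured
value.  All class moments are closed-form (z is uniform, classes are
sub-intervals), so the calibration is analytic, not fitted.  Measured over
50 replicate seeds, the mean sample coefficients are 0.528 / 0.595 / 0.279
against targets 0.53 / 0.60 / 0.28.

Remaining choices: biomass is exponentiated from the log scale (median AGB
120 g/m², median BGB 950 g/m² — a root-dominated alpine turf; log SD 0.5
each).  These absolute scales are free choices: no field means/SDs are
available to calibrate them, and all pipeline statistics are either
scale-free or log-scale.  SLA is lognormal around 15 m²/kg (SLA units
are a documented convention here; the analysis standardizes it anyway).
MAT = −1 − 2·z + N(0, 1) °C, the weak negative climate coupling of
high-altitude gradients.  Richness is 1 + Poisson with a Gaussian hump in
MAP peaked at 450 mm/y (width 160 mm), clipped to 1–12, so diversity peaks
at intermediate precipitation and is independent of the biomass residuals.
One seed sequence is spawned per site; extending the design never perturbs
earlier sites, and identical config + seed is byte-identical through the
CSV round trip (floats are written as shortest round-trip reprs and read
with the round-trip parser).

What the generator does *not* emulate: spatial autocorrelation between
sites, within-plot correlation beyond the shared site climate, species
composition (only richness), measurement error models for root coring,
interannual variability, and grazing heterogeneity.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed structure, not robustness to every property of field data.

`noise_sd` scales all residual terms and exists to build degenerate
fixtures (at 0 with zero coefficients, responses are constant); the
standardized-coefficient and class-slope calibrations hold at the default
noise_sd = 1.

## Numerical and degenerate-input choices

Min–max scaling raises a degenerate-scaling error when a component is
constant.  SMA is undefined at exactly zero correlation (error) and at
zero log-BGB variance (error); class fits require n ≥ 3.  Kruskal–Wallis
uses midranks with the standard tie correction; Dunn's variance uses the
same correction.  Mantel requires symmetric, zero-diagonal, equal-shape
matrices and at least 3 objects.  The path model rejects cyclic
specifications; d-separation p-values are floored at the smallest positive
double before the log.  The covariance fit raises on a non-positive-
definite sample correlation matrix.  Forest trees with fewer than two
out-of-bag rows, or a zero baseline OOB MSE, are skipped (and counted out
of n_trees).

## Problem sizes used by the tests and acceptance script

Replicate counts are chosen to make Monte-Carlo error a small fraction of
each tolerance: 50 replicate surveys (47,250 quadrats) for path recovery
(±0.05 band, MC SE ≈ 0.003); 100–200 replicates of 500 quadrats per class
for slope recovery (bias bound 0.02, observed ≲ 0.004); 2,000 null
simulations for the type-I calibration of Kruskal–Wallis and Mantel
(MC SE ≈ 0.005 against a ±0.01 band); 500 trees for importance.

## Known limitations

* The trade-off is an exact function of the scaled biomass pair; feeding
  AGB and BGB to an importance forest *for the trade-off* therefore
  concentrates importance on those components by construction.  MAP's
  regulation is the indirect, path-model story, not the forest ranking
  (see the worked example in the README).
* Min–max scaling is range-sensitive: a single extreme quadrat rescales
  every relative benefit.  Fit scalings on the dataset you intend to
  compare within.
* The compact letter display is the minimal consistent letter assignment,
  not unique; only the sharing relation is meaningful.
* RMSEA/CFI come from a linear-Gaussian global approximation of the
  piecewise model; with strongly nonlinear couplings the two global
  verdicts (Fisher's C vs covariance fit) can disagree, and both are
  reported.
* Allometry is fit per class without site random effects; with few sites
  per class the effective sample size is smaller than n suggests.
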