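# Methods

## Problem and pipeline

`geosmr` models regional standardized mortality ratios (SMR) from gridded
environmental exposures and region-level socio-economic covariates, with two
methodological safeguards that are the package's point:

1. **Honest cross-validation under spatial autocorrelation.** Disease rates
   and exposures are spatially smooth; randomly splitting neighbouring
   regions between training and validation lets the model interpolate its
   own validation data and inflates apparent skill. The pipeline estimates
   the decorrelation distance of the SMR from its empirical semivariogram
   and builds spatially coherent CV blocks by cutting a hierarchical
   clustering dendrogram at that distance.
2. **Exact attribution.** Model predictions are decomposed into per-feature
   Shapley values, computed exactly rather than approximately.

The stages: zonal aggregation of the exposure grids → indirect
standardization → semivariogram and range → dendrogram-cut blocking →
leave-one-block-out random-forest CV (with a random-CV comparison) →
Shapley attribution.

## Indirect standardization

Expected deaths per region apply reference age-specific rates to the
region's own age pyramid, `E_i = Σ_a pop_{i,a} · rate_a`; `SMR_i = O_i / E_i`.
When the reference rates are derived from the pooled study regions,
`Σ_i E_i = Σ_i O_i` holds algebraically; the test suite checks this to
1e-9 relative on random tables. Outlying regions are flagged by Tukey
fences (outside `[Q1 − k·IQR, Q3 + k·IQR]`, linear-interpolation quartiles,
default `k = 1.5`, configurable) — a reproducible stand-in for the
discretionary exclusion of extreme regions common in practice. Flagged
regions stay in the output table with the flag set so the exclusion is
auditable; they are dropped from modelling.

## Semivariogram and range

The Matheron estimator is used per lag bin:
`γ(h) = (1 / 2N(h)) Σ_{pairs in bin} (z_i − z_j)²`, with 15 equal-width
bins from 0 to half the maximum pairwise distance (a standard
geostatistical heuristic). The sill is estimated by the sample variance of
the values; the range is the center of the first bin whose (moving-average
smoothed, window 3) semivariance reaches 95% of the sill. If the threshold
is never reached the last non-empty bin center is returned with a
`converged = False` flag. This automates the usual visual plateau
judgement; an explicit range override is available everywhere the range is
consumed. Distances are plain Euclidean for planar (synthetic) coordinates
and haversine kilometres (Earth radius 6371 km) for lon/lat inputs.

Because the sample variance under-estimates the process sill when the
domain spans only a few ranges (the spatial mean absorbs variance), the
detected range is biased low — by roughly a factor 0.5–0.9 on a 20×20 grid
with range 8. The factor-two recovery criterion used in the tests reflects
this known bias; it is a property of variogram range estimation on small
domains, not of the implementation.

## Spatial blocking

Regions are agglomerated on the inter-centroid distance matrix
(`scipy.cluster.hierarchy`) and the dendrogram is cut at the range.
Complete linkage is the default because it guarantees every block's
internal diameter is at most the cut distance, which is what makes
"cut at the decorrelation scale" meaningful; average and single linkage
are available but carry no such bound. Block count is always an outcome of
the cut, never a parameter. A cut yielding one block is an error (CV would
be impossible), with the message suggesting a smaller cut.

## Regression and metrics

The regressor is scikit-learn's `RandomForestRegressor` with library
defaults unless overridden — the analysis is about the validation scheme,
not model tuning. One forest is trained per fold; every region is
predicted exactly once out of fold. Headline `r² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²`
and `MAE = (1/n)Σ|y−ŷ|` are pooled over the concatenated out-of-fold
predictions; per-fold values are reported alongside because per-fold r² on
blocks of a handful of regions is unstable. Pooled r² of a constant target
is reported as NaN (undefined). Permutation feature importance (r²
degradation, 10 repeats) wraps scikit-learn's implementation.

The leakage comparison runs leave-one-block-out and shuffled k-fold CV
(k = 10) on identical data and reports both pooled r² values and their
difference. Per-fold model seeds derive from the master seed by a fixed
counter scheme, so every stage is independently reproducible.

## Shapley attribution

Interventional (marginal) value-function semantics: `f_x(F)` is the model
prediction averaged over background rows with the instance's values
imposed on coalition `F`. This matches the semantics of the widely used
tree-attribution framework; "remove a feature by retraining" semantics is
exponential in model fits and deliberately out of scope. Two independent
algorithms are implemented:

* **Exact enumeration** over all `2^p` coalitions (capped at p = 12) —
  model-agnostic, used as the oracle.
* **Tree traversal**: for one tree, one background row and one instance,
  the leaf-restricted game is a signed unanimity game — the composite row
  reaches the leaf iff every path feature that only the instance satisfies
  is in the coalition (set A) and every feature that only the background
  row satisfies is out (set B); a feature neither satisfies kills the leaf.
  The Shapley value of that game is closed-form
  (`(|A|−1)!|B|!/(|A|+|B|)!` per member of A, mirrored negatively for B),
  and attributions sum over leaves, background rows and trees by
  linearity. This is exact, not an approximation; the two routes agree to
  machine precision (tested at 1e-6, observed ~1e-15).

Both satisfy efficiency (base value + Σφ = prediction) and the dummy axiom
(a feature absent from every split gets exactly zero). The global ranking
orders features by mean |φ| with lexicographic tie-breaks. Default
background is the training set, subsampled to 100 rows (seeded) for the
tree path when larger; explanations default to a full-data refit after the
CV assessment.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

* **Exposure surfaces**: zero-mean Gaussian random fields with exponential
  covariance `C(d) = sill·exp(−3d/range)` (so `range` is the effective
  range: 5% residual correlation), dense Cholesky factorization with
  escalating jitter, plus optional nugget noise. Defaults: 20×20 grid,
  sill 1, nugget 0.05, range 8 cells.
* **Daily series**: base field plus iid Gaussian temporal noise. By
  default the per-cell noise s.d. is log-GRF-modulated
  (`sd·exp(0.5·g)` with `g` a unit GRF), so the "std pollutant" features
  carry spatial signal as they do in real reanalysis products; a
  homoscedastic switch exists.
* **Regions**: 60 contiguous regions grown from random seed cells by
  uniform adjacent-cell accretion (4-neighbour), guaranteeing connectivity
  on small grids where Voronoi cells could fragment.
* **Mortality**: age-structured populations (lognormal totals around
  60,000, Dirichlet age shares, five age classes) and reference rates
  rising from 2·10⁻⁴ to 3·10⁻² per person-year give expected deaths of a
  few hundred per region, comparable to annual province-level counts for a
  common cancer site. Deaths are Poisson with log relative risk linear in
  a chosen subset of standardized features, plus optionally a hidden
  smooth spatial confounder field that is *not* among the features.
* **Socio-economic stand-ins**: iid standard-normal columns, so
  feature-recovery tests have a clean null.

Features are standardized before effects are applied so betas are
comparable across features; the exported feature matrix keeps field units.

What the generator does not emulate: realistic geography or demography,
temporal autocorrelation within the daily series, measurement error
structure of reanalysis ensembles, or correlated socio-economic
covariates. Passing tests therefore demonstrate the *methods* behave as
specified under their own assumptions, not that any particular real-world
association holds.

## Study conditions used by tests and the acceptance script

* **Leakage demonstration**: 20 worlds (20×20 grid, 60 regions, seeds
  1–20 off a master seed), confounder beta 0.5 with range 10,
  feature-field range 10, no true feature effect. CV blocks are cut at the
  known generating decorrelation scale (10 cells) rather than each world's
  variogram estimate, so range-estimation noise does not blur the
  scheme comparison; range estimation is assessed separately. Observed:
  random 10-fold CV r² exceeds blocked CV r² in ~95% of worlds with a mean
  optimism gap of ~0.22.
* **Feature recovery**: 2 active of 15 features, |beta| = 0.3, 20 worlds;
  the active pair must occupy the top-2 mean-|φ| ranks.
* **Range recovery**: 20 GRF draws, range 8 on a 20×20 grid, factor-two
  tolerance (see the bias discussion above).

Problem sizes were chosen so the whole suite runs in a couple of minutes
on a single CPU while keeping each Monte-Carlo check statistically
meaningful.

## Numerical choices and edge cases

* Covariance Cholesky jitter starts at 1e-10·sill and escalates ×100 up to
  four times before raising a diagnostic error; coincident points are
  therefore equal only to ~1e-5, which the tests tolerate.
* Temporal std convention is population (ddof 0) so a single timestep is
  well-defined; sample std is a flag away.
* Zonal means are unweighted over member cells (no area or population
  weighting; both would be reasonable extensions).
* Empty lag bins carry NaN semivariance and zero pair count; the last bin
  edge is right-inclusive so the half-max-distance pair is kept.
* Clustering label numbering is canonicalized by first occurrence, making
  partitions stable under region permutation up to renaming. Exact
  distance ties resolve by scipy's internal order.
* NaNs in exposure series are a hard error with the offending cell and
  timestep named — reanalysis-style inputs are gap-free and silent
  skipping would bias zonal means.

## Known limitations

* The variogram range detector assumes an increasing-then-flat γ; cyclic
  or trending fields can fool the 95% rule (the not-converged flag and the
  override are the escape hatches).
* Exact Shapley enumeration is capped at 12 features; beyond that only the
  tree algorithm applies (itself exact for tree ensembles, but
  model-specific).
* Haversine vs planar distances change bin boundaries and cut values, not
  the method; mixing them across stages is the caller's responsibility.
* No SMR confidence intervals (Byar/exact) and no parametric variogram
  model fitting or kriging — natural extensions, deliberately out of
  scope.
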