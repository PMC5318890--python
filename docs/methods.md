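# Methods

This note records the modeling assumptions, parameter choices and numerical
decisions behind the package, in enough detail to re-derive or contest them.

## 1. Indicators

Eco-exergy density (J/L) and specific eco-exergy (kJ/g) are computed from
long plankton tables (`site_id, month, taxon, group, wet_biomass_mg_per_L`)
as documented in `lakehealth.exergy`. Choices:

- **β weights** (algae 20, protozoa 39, rotifera 163, cladocera 232,
  copepoda 232) are the standard genome-based values for these groups;
  `BetaTable` validates β ≥ 1 because detritus is the baseline and a β < 1
  would make "information" negative.
- **Conversion factors** `f_phy = 0.16`, `f_zoo = 0.06` are treated as a
  single wet-weight → reference-biomass scaling. The literature uses "dry
  weight" and "carbon biomass" loosely for these empirical constants;
  because the same factor appears in both the numerator and the
  denominator of specific eco-exergy, the choice rescales indicators
  systematically without affecting any comparative or statistical
  conclusion.
- **Zero-biomass samples**: specific eco-exergy is a ratio and is
  *undefined*, not zero, for an empty community. The scalar API raises
  `UndefinedIndicatorError`; the table API (`compute_indicators`) emits NaN
  so one bad sample cannot silently drag an aggregate toward 0.
- **Uncertainty bands** on monthly/regional aggregates are 2.5–97.5
  empirical percentiles of the member (site, month) values. These describe
  spatial/temporal spread across survey members, not a sampling-error
  confidence interval; with 33 stations per month the percentile band is a
  robust, distribution-free summary.

## 2. Non-detect chemistry

Each censored variable is classified by its non-detect fraction `f`:

| condition      | strategy                                        |
|----------------|-------------------------------------------------|
| `f > 0.50`     | drop the variable                               |
| `0.10 < f ≤ 0.50` | impute `Normal(LOD/2, LOD/4)` clamped to `[0, LOD]` |
| `0 < f ≤ 0.10` | substitute `LOD/2`                              |

Rationale: above 50% non-detect the detected values no longer characterize
the distribution and any imputation is fiction; between 10% and 50% a
stochastic fill preserves variance that constant substitution would
destroy; below 10% the bias of half-LOD substitution is negligible and
determinism is worth more than realism. The imputation distribution places
≥ 95% of its raw mass inside `[0, LOD]`; clamping (rather than rejection
sampling) keeps the draw count deterministic and the atom it creates at the
boundaries is tiny. Thresholds are strict inequalities so a variable at
exactly 10% gets the simpler treatment. `resolve_table` processes
variables in column order with a seeded substream per table so results are
reproducible and independent of unrelated variables.

## 3. Collinearity screening

Pairwise Pearson correlations with exact t-transform p-values; a pair is
"strong" if |R| > 0.7 (strictly) and p < 0.05. From each strong pair the
less-preferred member (by a fixed domain preference order favoring directly
interpretable, management-relevant variables — dissolved nutrient species
over totals, temperature over dissolved oxygen) is removed. Pairs are
processed in order of the preferred member's rank; a pair whose
to-be-removed member is already gone is skipped, so in a chain A–B, B–C
with preference A > B > C the survivors are {A, C}: B is removed for A, and
C then has no remaining strong partner. Chlorophyll-a is excluded up front
as it is mechanistically part of the response, not a driver. On the
packaged published 15-variable matrix (n = 396) this yields exactly five
strong pairs and an 11-predictor set.

## 4. Boosted regression trees

The GBM is implemented from scratch (this is the package's authored
numerical contribution); external libraries are used only as test oracles.

- **Trees** are grown best-first: `interaction_depth` is the *number of
  splits*, not tree height, so depth 5 means 5 splits / 6 leaves placed
  wherever squared-error improvement is largest.
- **Split search** is exact over midpoints of consecutive distinct sorted
  values, vectorized via argsort + cumulative sums. Improvement is
  `S_l²/n_l + S_r²/n_r − S²/n`. Ties are broken toward the lowest variable
  index, then the lowest threshold, with a 1e-12 relative guard so
  floating-point noise cannot flip the ranking between platforms.
- **Boosting** is gradient descent on Gaussian loss: each tree fits the
  current residuals on a 50% bagged subsample and is shrunk by the learning
  rate. Defaults — 1500 trees, learning rate 0.005, depth 5, 5-fold CV,
  bag fraction 0.5, minimum node size 10 — follow common practice for
  ecological response modeling at n ≈ 400: a small learning rate with many
  trees, regularized by bagging and CV-based early selection.
- **Iteration selection**: `best_iteration` minimizes the fold-averaged
  held-out MSE; the final model is refit on all data and truncated there at
  prediction time. All randomness flows through
  `np.random.SeedSequence(seed).spawn(...)` substreams (fold assignment,
  final fit, one per fold), so runs are reproducible and fold results are
  independent.
- **Relative influence** is Friedman's: per-variable sums of split
  improvements over the first `best_iteration` trees, normalized to 100.
- **Partial dependence** is computed exactly by overwriting the variable(s)
  with each grid value and averaging predictions over the training data —
  no Monte Carlo subsampling, so PDP curves are deterministic.

## 5. Adequacy metrics

NSE (Nash–Sutcliffe efficiency), RSR = √(1 − NSE), PBIAS =
100·Σ(O − P)/ΣO (negative = overprediction), and R² taken as the *squared
Pearson correlation* between observed and predicted (the convention that
makes R² ≥ NSE and isolates dispersion from bias). The adequacy gate is
NSE > 0.5, RSR ≤ 0.7, |PBIAS| ≤ 25%, evaluated on a held-out 25% of
samples never seen during fitting or CV. Zero-variance observations or a
zero observation sum make NSE/PBIAS undefined and raise `ValidationError`.

## 6. Spatial interpolation

Inverse distance weighting with power 2 (the conventional choice: smooth
but local). Predictions at a station coordinate return the station value
exactly (handled explicitly, not via an epsilon); elsewhere IDW is a convex
combination, so interpolated values are bounded by the station extremes.
Grids are written as ESRI ASCII rasters (plain text, GIS-readable);
an optional shapely polygon masks cells outside the lake to NODATA.

## 7. Synthetic survey generator

The generator emulates the *statistical shape* of a year-long monthly
survey at 33 stations across nine sub-regions (396 samples), for use as a
test bed with known truth. What it does emulate:

- Published means, plausible spreads, physical bounds and a shared seasonal
  cosine (peaking in August for temperature, solar radiation and
  precipitation; inverted for dissolved oxygen) for 17 abiotic variables
  plus a pure-noise control predictor.
- Non-detect fractions of the five censored variables close to the
  published counts out of 396 (nitrite ≈ 92% non-detect, orthophosphate
  ≈ 39%, nitrate ≈ 23%, dissolved total phosphorus ≈ 9%, ammonium ≈ 3%).
  For these variables the marginal sd is *tuned to reproduce the non-detect
  fraction* given the mean and LOD, because a published mean/sd pair cannot
  simultaneously match the published censoring counts under any
  single-family marginal; the censoring fractions are what the three-tier
  logic consumes, so they take priority.
- Plankton biomass responds on the log scale to known drivers — algae: a
  ramp in water temperature between 16 and 26 °C, a saturating response to
  orthophosphate, a linear pH term; zooplankton groups respond with
  different weights so that specific eco-exergy carries its own signal —
  plus lognormal noise (sd 0.35). This gives the downstream model a
  recoverable nonlinear truth (thresholds for PDPs, a known driver ranking,
  and a null predictor that must stay unimportant).

What it does **not** emulate: spatial autocorrelation between stations,
temporal autocorrelation beyond the shared seasonal term, inter-variable
correlation beyond what the seasonal driver induces (the screening stage is
therefore validated against the *packaged published* correlation matrix,
not the synthetic data), storm events, and bloom patchiness. Marginals are
clipped normals: clipping at the physical bounds (rather than rejection
truncation) deliberately places an atom at zero for nutrients, matching
observed minima of 0 and producing below-LOD mass.

## 8. Reproducibility

Every stochastic step derives its generator from
`SeedSequence((seed, salt))` with a distinct salt per purpose, so stages
are independently reproducible and adding a stage never perturbs another.
Pipeline outputs contain no timestamps; a rerun with the same seed and
configuration is bit-identical, and `manifest.json` records the full
resolved configuration.

## 9. Limitations

- Adequacy is judged on a single 25% holdout (n = 99), not repeated
  splits; the NSE estimate carries sampling noise of roughly ±0.05.
- The GBM supports Gaussian loss only; count-like or heavily skewed
  responses should be transformed first.
- IDW ignores anisotropy and barriers (e.g. land between bays).
- The generator's independence assumptions mean synthetic-data screening
  finds fewer collinear pairs than real surveys would; conclusions about
  the screening rules come from the published-matrix tests.
- Specific eco-exergy inherits the β table's step-function taxonomy;
  within-group composition shifts are invisible to it.
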