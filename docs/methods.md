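# Methods

This note documents the models implemented in `ecocouple`, the
conventions chosen where the methodology is genuinely open, and what the
synthetic-data generator does and does not emulate.

## Indices

**EQI.** The ecosystem quality index is the equal-weight mean of three
vegetation indicators scaled to percent: EQI = 100·(LAI + GPP + FVC)/3.
LAI and GPP must be min–max normalized to [0, 1] before the call (the
package checks this precondition rather than silently rescaling).
Fractional vegetation cover comes from the enhanced vegetation index via
FVC = (EVI − EVI_soil)/(EVI_veg − EVI_soil), clamped to [0, 1], with the
bare-soil and full-vegetation references taken as the 5th and 95th EVI
percentiles over unmasked cells. Percentiles use the linear-interpolation
definition — a fixed, testable convention.

**Normalization domain.** `minmax_normalize` on a stack defaults to
`pooled-epochs`: one min/max over all years, so that index *levels* stay
comparable across epochs (a cell's value can be read on the same scale in
2000 and 2020). `per-epoch` is available when within-year contrast is
wanted instead. Whether vegetation inputs should be normalized per epoch
or over the full record is not a settled convention; it is exposed as
the `domain` switch rather than hard-coded.

**Natural breaks.** `jenks_breaks` computes the Fisher–Jenks optimal
contiguous partition (minimal total within-class sum of squared
deviations) by the O(k·n²) dynamic program with prefix sums. Ties in the
optimum resolve toward the smallest split indices. Display class maps
should be computed on pooled multi-epoch values so legends stay constant
across years.

**Masking.** Any operation combining grids masks the union of the input
masks; a stack forces one shared mask across epochs (a cell must be
observed in all years to be analysed). This is deliberately conservative:
no value is ever fabricated under a partially observed cell.

## Four-quadrant change typing

For a period (t0, t1), ΔHFI and ΔEQI are cellwise differences; the
significance scale is the standard deviation **of each change raster**
(not of the index levels). A change is significant when |Δ| ≥
`sigma_fraction`·SD with `sigma_fraction` = 0.1; equality counts as
significant. A cell needs a signed direction on *both* axes to receive a
quadrant, so the default insignificance rule is a logical OR (small on
either axis ⇒ insignificant); an AND variant is provided since the
opposite convention also appears in practice. With a zero change-SD
(e.g. a uniform shift), every nonzero change is significant — documented
behaviour, not an error. A significant cell with an exactly zero axis
carries no direction there and stays insignificant.

## Coupling coordination degree

With both indices rescaled to [0, 1]:

    C   = 2·√(HFI·EQI) / (HFI + EQI)
    T   = a·HFI + b·EQI,  a = b = 0.5
    CCD = √(C·T)

The radical form is the canonical CCD model: it is what makes C = 1 for
balanced subsystems and CCD a meaningful [0, 1] coordination scale. The
radical-free variant (C = 2·HFI·EQI/(HFI+EQI), CCD = C·T) is retained as
`variant="literal"` for sensitivity checks. Where both inputs are zero,
C is defined as 0 — no coupling without activity or quality. The five
coordination levels use half-open intervals [lo, hi) with the top
interval closed, which removes the ambiguity of level tables whose
printed bounds overlap at 0.2/0.4/0.6/0.8.

## Driver screening

**Collinearity.** VIF_j = 1/(1 − R²_j), R²_j from OLS of driver j on all
other drivers with intercept. Exact linear dependence reports +inf
(flagged, not raised). The default filter is one-shot — every driver
with VIF > 6 is dropped in a single pass; a greedy-iterative mode
(drop the single worst, recompute) is available, and on a planted
r = 0.99 pair the two modes differ exactly as expected (both dropped
vs. one dropped, survivor's VIF returning to 1).

**Importance.** A bagged ensemble of regression trees (default 500;
scikit-learn trees, with the bootstrap drawn by the package so each
tree's out-of-bag rows are known exactly) predicts CCD from the drivers.
%IncMSE for driver j is the across-tree mean of the relative increase in
out-of-bag squared error when j's values are permuted among the tree's
OOB rows; a constant driver scores exactly 0. Significance uses a
response-permutation null (Altmann-style): the response is shuffled, the
forest refit and importances recomputed `n_permutations` times (default
100); the p-value carries the +1 continuity correction, so its smallest
attainable value is 1/(n_permutations+1) — the filter raises if that
cannot resolve the chosen alpha. This null is assumption-free and makes
the filter conservative by construction (null pass probability
k/(n_permutations+1) ≤ alpha).

**Selection** is the intersection of the two pass sets, in original
column order. Screening runs per region and uses only that region's rows.

## PLS path modeling

Reflective (Mode A) blocks, estimated by the classical alternating
algorithm: equal initial outer weights; latent scores as standardized
weighted sums of their block indicators; inner proxies from the `path`
scheme by default (predecessors contribute their multiple-regression
coefficients, successors their correlations; `centroid` and `factorial`
are options); Mode A outer-weight update as indicator–proxy covariances.
Convergence is max |Δw| < 1e-6 on unit-norm weights with max_iter = 300;
non-convergence returns the fit with `converged=False` and a warning
rather than raising.

After convergence: loadings are indicator–score correlations; the sign
indeterminacy of each latent is resolved by forcing a non-negative
loading sum per block; structural coefficients come from OLS of each
endogenous score on its predecessors' scores (all scores standardized,
so coefficients are standardized paths); communality = loading²;
GOF = √(mean communality × mean R²) with weak/medium/strong at
0.10/0.25/0.36 (boundaries closed from above). A single-indicator block
has loading 1 and communality 1 and is included in the GOF mean.

**Effects.** Direct = the edge coefficient; indirect = the sum over all
directed multi-edge paths of the products of edge coefficients; total =
direct + indirect. The path-tracing result is checked in tests against
the matrix identity Σ_{k≥1} Bᵏ, which holds exactly for any acyclic
structural matrix.

**Inference.** Nonparametric bootstrap over rows (default B = 999).
Each resample is refit and sign-aligned to the base fit block by block
(flipping a latent flips its loadings and every path touching it) before
aggregation; failed resamples are dropped and counted, with more than
10% failures aborting. SE is the bootstrap standard deviation; p-values
use the normal approximation z = estimate/SE, matching star-style
reporting (***/**/* at 0.001/0.01/0.05); percentile 95% CIs are also
emitted. Listwise deletion handles missing rows before fitting.

## Synthetic data

The generator emulates the study conditions the methods target:

- **Coupled stacks.** A 60×60 grid, epochs 2000/2010/2020, HFI starting
  near 35.7 and rising by roughly 9 points over two decades while EQI
  drifts down from about 50.4; conflict cells outweigh coordinated ones
  roughly 5:3 (strip fractions 0.42/0.25, with smaller good-for-nature,
  degradation and insignificant strips). Block trends per decade are
  +6/+4 (coordination), −5/+4 (good-for-nature), −4/−4 (degradation),
  +10/−5 (conflict) in HFI/EQI units, with i.i.d. Gaussian cell noise
  (SD 1) and 2% shared nodata. Spec validation enforces that every
  significant class's trend exceeds 10% of the analytic change-SD
  (block-trend mixture variance plus 2·noise²), so the significance rule
  cannot erase planted structure.
- **Threshold-calibrated fixture.** For probing the classifier at its
  decision boundary, `calibrated_quadrant_spec` pins the change-SD with
  four large-trend anchor strips and iterates two weak strips to exactly
  a chosen multiple (default 3×) of the 10%-of-SD threshold. Note that a
  layout in which *all* significant trends sit at 3× their own threshold
  is infeasible: the threshold is 10% of a change-SD that is itself
  dominated by those trends, so the fixed point forces noise to swamp
  the signal. Anchoring the SD with strong-trend blocks is the coherent
  construction.
- **Latent model tables.** Latents are drawn recursively along a strictly
  lower-triangular coefficient matrix; indicators are loading×latent plus
  measurement noise, standardized on export. The `standardized`
  constructor derives noise SDs so that the requested paths and loadings
  *are* the standardized truth (unit-variance latents and indicators),
  and rejects infeasible coefficient sets. The analytic standardized
  parameters are returned with every table, so estimators are scored
  against population truth, not a rival estimator. The default
  driving-mechanism model wires terrain, human activity, climate and
  vegetation to CCD along the four-hypothesis DAG with realistic
  magnitudes (e.g. Veg→CCD +0.50, Ter→Hum −0.35) and indicator
  reliabilities between 0.55 (TEM) and 0.94 (FVC).
- **Driver rasters.** A Gaussian copula places multivariate-normal scores
  on each driver's native scale (e.g. precipitation 1200±200 mm,
  population density 500±300 km⁻²) by affine maps, preserving the
  requested correlation structure; infeasible (non-PSD) correlation
  requests are rejected.
- **Drivers conditional on a response.** For end-to-end runs the driver
  table is sampled from the latent model's Gaussian conditional
  distribution given the *observed* (standardized) CCD of each cell.
  Cross-covariances between drivers and response then match the latent
  model exactly regardless of the CCD's marginal shape — which is all a
  covariance-based estimator sees.

What the generator does **not** emulate: spatial autocorrelation beyond
block structure (the methods are per-cell, so geostatistical fields add
nothing to their validation); real marginal distributions of remote
sensing products; spatially varying driver–response relationships within
a region; and the actual geography of any study area. Passing tests
therefore demonstrate correctness of the algorithms and their
statistical calibration under known truth, not fidelity to any
particular real landscape.

## Pipeline conventions

Regions for screening and PLS come from the union-period (first→last
epoch) quadrant map, so a region is defined by its long-run trajectory;
per-decade maps are computed too. Screening and PLS run on the last
epoch's CCD by default. Latents left without surviving indicators after
screening are dropped (with a warning) along with their edges — fitted
paths are then conditional on the pruned graph; interpreting a fitted
coefficient as the planted structural parameter requires either that the
full model survives or that omitted latents carry no paths into the
response. All stages are seeded from the config's global seed, CSV
output uses a fixed float format, and the JSON report records a config
hash, so identical config+seed reproduces outputs byte for byte.

## Problem sizes used in the shipped checks

The acceptance checks run at sizes chosen to make Monte-Carlo error
small relative to the tolerances: CCD identity on 10³ grid points plus
10⁶ random pairs; quadrant recovery over 20 seeds of a 60×60 grid;
natural-breaks and VIF oracle comparisons on 200 and 100 random
instances; screening null calibration with 200 replicates of a
150-row/5-driver table (30 trees, 49 permutations — the calibration
property is size-free); path recovery with 50 replicates at n = 5000
and consistency across n ∈ {500, 2000, 8000}; bootstrap type-I error
with 500 null replicates at n = 300, B = 199. At 200 replicates a
per-driver null pass rate has a binomial SD of ≈1.4 percentage points,
so calibration is asserted on the mean rate across drivers plus a
per-driver anti-conservatism bound — the direction in which the
permutation test could actually fail.

## Known limitations

- PLS-PM path estimates attenuate toward zero as indicator reliability
  drops (visible in the worked example: planted 0.50, recovered ≈0.41
  with mixed-reliability indicators); recovery tolerances assume
  loadings ≳ 0.85.
- The bootstrap normal-approximation p-values can be mildly
  anti-conservative at small n (measured type-I ≈ 6–7% at n = 300);
  percentile CIs are provided alongside.
- One-shot VIF exclusion can discard an entire correlated pair where the
  iterative mode would keep one member; both are provided, one-shot
  being the default.
- Raster I/O covers single-band TIFF (with a JSON sidecar for
  georeferencing) and ESRI ASCII grid; multi-band files, reprojection
  and resampling are out of scope — inputs must be pre-aligned.
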