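# Methods

This note documents the models and procedures `vorscape` implements, the
conventions adopted where the field leaves choices open, the defaults
and why, and what the synthetic-data generator does and does not
emulate.

## The VORS health index

Each tile of the analysis grid receives four components on [0, 1] and
their geometric mean, `EHI = (EV·EO·ER·ES)^(1/4)`.  The geometric mean
is deliberate: a collapse of any single component (no vigour, no
services…) drives the composite to zero, which an arithmetic mean would
mask.  A zero component therefore yields EHI = 0 rather than an error.
EHI is classified into five equal-interval classes with half-open bins
and a closed top bin — `[0, 0.2)` degraded … `[0.8, 1]` highest — so
boundary values (0.2, 0.4, 0.6, 0.8) are assigned upward and every value
receives exactly one label.

**Vigour** is the tile mean of NDVI over valid cells, min-max normalized
across the whole run.  Whether vigour should use raw or normalized NDVI
is a genuinely open choice; tile-mean-then-normalize was adopted because
it keeps the component scale-free and comparable across snapshots.

**Organization** combines landscape-pattern sub-indices with fixed
weights that sum to exactly 1.00: 0.25 SHDI + 0.10 MPFD + 0.25 FN₁ +
0.10 CONT + (0.07 FN + 0.03 COHESION) for each of the three focal
classes (forest, grassland, water in the default legend).  Every
sub-index is min-max normalized to [0, 1] over all tiles and snapshots
of a run before weighting — without this the sub-indices live on
incommensurate scales and EO is unbounded.  Fragmentation enters as
`1 − minmax(FN)` because high patch density means *low* organization;
this inversion is a package convention and materially affects EO values.
Focal classes absent from a tile contribute 0 to their two terms and are
flagged (`present_c*` columns), never silently imputed.

**Resilience** is the area-weighted mean of per-class resilience
coefficients, `ER = Σ A_i·ERC_i`, computed over valid cells; a class
missing from the coefficient table is a hard error, since a default
would silently bias the score.

**Services** evaluates `ESC_j · (1 + SNE_j/100)` per pixel and averages
over the tile, where `SNE_j` sums the percent neighbour-effect terms
`SNE(class_j, class_neighbour)` over the pixel's queen (8-cell)
neighbourhood; boundary pixels use the neighbours that exist.  The
neighbourhood definition (pixel-scale, queen) is a documented package
choice — regional assessments rarely state theirs.  With SNE ≡ 0 the
formula collapses exactly to the tile mean of ESC, which the tests
assert to 1e-12.

**Coefficient tables.**  ERC/ESC/SNE values are expert-knowledge
parameters, not estimable from the raster itself.  The package ships a
documented default table for a six-class legend (cropland, forest,
grassland, water, built-up, unused) with natural vegetated classes high
and built-up low, in `src/vorscape/data/default_coefficients.yaml`; real
studies should supply their own table (`CoefficientTables.from_yaml`).

**Normalization scope** is pooled across all snapshots (years) of a run
so that scores are comparable over time; per-year normalization would
make interannual change unreadable.

## Landscape metrics

Patches are connected components per class, 8-connected by default
(4-connected selectable).  Perimeter counts cell edges adjacent to a
different class, nodata, or the window boundary (the "boundary counts as
edge" convention — it changes P for edge patches).  Per-class patch
areas always sum to the class cell count (asserted as an invariant).

* **SHDI** = −Σ p_k ln p_k over class shares; 0 for one class, ln K at
  K equal shares.
* **MPFD** averages `2 ln(0.25 P)/ln a` over patches with a ≥ 2;
  single-cell patches (ln a = 0) are excluded, and if all patches are
  excluded the metric is undefined (NaN + flag) and sits at the
  normalization floor downstream.  Square patches score exactly 1.
* **CONTAG** = `1 + Σ q ln q / (2 ln K)` with
  `q_ik = p_i · g_ik / Σ_k g_ik` from 4-neighbour adjacency counts,
  both orders counted.  A single-class window is defined as 1 (maximal
  aggregation).  Note a genuine property of this formula: a two-class
  checkerboard scores *higher* (0.5) than two solid half-windows
  (≈0.18 at 4×4), because the checkerboard's adjacency distribution is
  deterministic and therefore low-entropy; the intuitive
  "aggregated > interspersed" ordering holds against maximal-entropy
  configurations (e.g. fine stripes, which score 0), not against the
  checkerboard.  The tests pin both fixtures to a hand-count oracle.
* **COHESION** = `[1 − ΣP/Σ(P√a)] / [1 − 1/√Z]` for a focal class in a
  window of Z cells, on [0, 1]; all-single-cell configurations give 0,
  a class filling the window gives 1.
* **Fragmentation** is raw patch density (patches per window cell) at
  landscape or class scope; no formula is standard in the assessment
  literature, so the simplest density was adopted and the inversion
  happens at the organization stage (above).

**Window size.**  The analysis grid defaults to a window of 10 cells
(8 in the pipeline's desk-scale config).  Tiny windows (2×2) are
accepted but several metrics are then undefined (contagion and MPFD
degenerate) and come back flagged; window size is a config parameter,
not a constant.

## Spatial autocorrelation

Weights default to queen contiguity on the tile grid, binary then
row-standardized; rook and zone-adjacency (queen at pixel level between
zone maps) builders are provided.  Tiles with missing EHI are dropped
from the weights (re-standardizing the remainder), never zero-imputed.

Global Moran's I uses the classic normalization with the 1/n variance;
with row-standardized weights the mean of the local statistics equals
the global statistic exactly (asserted to 1e-12).  Inference is by
permutation: full relabelling with a two-sided pseudo p-value
`(1 + #{|I_perm| ≥ |I_obs|})/(1 + n_perm)` for the global statistic
(999 permutations by default), and conditional randomization (unit i
held fixed, neighbours drawn without replacement from the remaining
n−1 values) for LISA.  The LISA pseudo p-value is the *folded*
two-sided one — twice the smaller tail, capped at 1 — because the raw
smaller-tail convention rejects at about twice the nominal level under
exchangeable noise (measured 0.090 at α = 0.05); with the folded p the
measured type-I rate is ≈0.04 at 199 permutations.  Significant units
are labelled by the quadrant of (z_i, lag): HH, LL, HL, LH.  No
multiple-testing correction is applied by default (matching common
LISA practice); Benjamini–Hochberg is available behind `fdr=True`.

## Regression and GWR

OLS is solved by least squares with R², adjusted R², per-variable VIF
(`1/(1−R²_j)` from auxiliary regressions) and a Gaussian small-sample
AICc.  Exploratory selection enumerates all 2^p − 1 candidate subsets,
screens out Max-VIF ≥ 7.5, and ranks survivors by adjusted R²
descending; failed fits are recorded, not fatal.  Ties across runs are
reported, not harmonized — cross-year consistency of the chosen subset
is a judgement left to the analyst.

GWR solves weighted least squares at every location with a
fixed-distance Gaussian kernel `exp(−½ (d/b)²)` (the form with the ½;
adaptive kernels are out of scope).  The hat-matrix trace
`tr(S) = Σ x_i (XᵀW_iX)⁻¹x_i` gives the effective parameter count, and

    AICc = 2n ln σ̂ + n ln 2π + n (n + tr S) / (n − 2 − tr S)

with σ̂² = RSS/n.  OLS AICc uses the same functional form with
tr(S) = p + 1, and the GWR adjusted R² uses residual df = n − tr(S), so
both statistics reduce exactly to their OLS counterparts in the
infinite-bandwidth limit (asserted to 1e-6 at 10⁶× the data diameter).
The AICc denominator is guarded: fits with n − 2 − tr(S) ≤ 0 error out
with a suggestion to raise the bandwidth floor.

**Bandwidth selection** is golden-section search on [0.05, 2.0] × data
diameter to relative tolerance 1e-3, with singular fits scoring +inf
and a warning when the evaluation trace is visibly non-unimodal.  A
known behaviour documented here deliberately: under spatially *constant*
truth, single replicates select a local bandwidth on chance structure
roughly 20–30% of the time — the tr(S)-based AICc slightly
under-penalizes local fits and the search maximizes over noise.  This
is a property of AICc bandwidth selection, not of this implementation
(the AICc curves were verified point-by-point); the tests and the
acceptance script therefore assert the *median* selected bandwidth over
replicates, which prefers the global end with high probability.

Duplicate zone centroids are jittered by 1e-9× the data diameter with a
warning (distance kernels cannot handle coincident points).  Predictors
and response are used unstandardized.

## Synthetic data

The generator provides the study conditions for every test:

* **Categorical landscapes**: white noise smoothed by an isotropic
  Gaussian kernel (sigma = `spatial_range` cells) and thresholded at
  class-proportion quantiles.  This gives spatially coherent patches
  with essentially exact class shares; it is *not* a calibrated
  geostatistical model (no variogram target), which downstream tests do
  not need.
* **Climate surfaces**: planar trend + Gaussian noise.
* **NDVI**: per-class means + noise, clipped to [0, 1], tying vigour to
  land use as in real mosaics.
* **Zones** (county analogues): multi-source BFS growth from random
  seed cells — contiguous, disjoint, exhaustive; centroids are
  unweighted means of member cell centres.  Zone covariates (GDP, PD,
  UR, LUI, BI) are part stochastic, part tied to zone land cover (LUI
  to built-up/cropland shares, BI to composition diversity).
* **GWR scenarios**: known coefficient surfaces (constant, linear in
  coordinates, or radial) evaluated at given locations, i.i.d. standard
  normal design unless supplied, `y` assembled exactly as
  `β₀(u,v) + Σ β_j(u,v) x_j + ε` with the noise draws stored, so the
  identity is testable to machine precision.

Coordinates follow the raster convention: cell centres at
`(col + 0.5, row + 0.5) × cell_size`, origin top-left, row index
increasing downward.  One master seed feeds all stages through a
documented SeedSequence-spawning scheme (`stage_seed`), so stages rerun
independently yet reproducibly and all derived seeds stay below 2³¹.

What the generator does **not** emulate: real geography (no coastline,
elevation or administrative shapes), temporally correlated change
between snapshots (years are independent draws), mixed pixels,
observation error structure of satellite NDVI, or spatially dependent
regression designs.  Passing tests therefore demonstrate correctness of
the algorithms and calibration of the inference under clean, known
conditions — not that any particular real landscape satisfies the
model's assumptions.

## Pipeline defaults and problem sizes

The end-to-end pipeline defaults to two snapshot years on a 96×96 grid
(1 km cells), 8-cell windows (144 tiles), 60 zones, queen weights, 999
permutations, VIF threshold 7.5 and the default coefficient tables —
deliberate desk-scale sizes that exercise every stage in seconds while
keeping all statistics well-conditioned (n = 144 tiles for Moran,
n = 60 zones for regression).  Every stage writes CSV (fixed float
format), ASCII grids and GeoJSON under the run directory and records
itself in `manifest.json`; reruns with the same config and seed are
bit-identical, which the test suite asserts via checksums.

## Known limitations

* Fixed (global) Gaussian bandwidth only; no multiscale or per-variable
  bandwidths, no adaptive nearest-neighbour kernels.
* No bootstrap or analytic inference on local GWR coefficients.
* LISA p-values are unadjusted by default (option available); cluster
  counts at α = 0.05 include the expected false positives.
* Contagion/cohesion conventions follow one consistent reading of the
  Fragstats definitions; other tools differ in boundary and
  double-count details, so absolute metric values are comparable within
  this package, not across tools.
* The services neighbour model is pixel-scale queen adjacency; other
  radii change ES and hence EHI.
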