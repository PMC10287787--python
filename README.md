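# vorscape

Ecosystem-health assessment and spatial driver analysis on gridded
landscapes: a composite **VORS** health index (Vigour, Organization,
Resilience, Services) computed per analysis-grid tile, spatial
autocorrelation analysis (global Moran's *I* and LISA cluster maps), and
quantification of spatially nonstationary driver effects via all-subsets
variable screening, OLS and **geographically weighted regression** (GWR)
with AICc-optimal Gaussian bandwidths.

The package is aimed at landscape ecologists and spatial analysts who
want a scriptable, fully reproducible version of the regional
ecosystem-health workflow that is usually assembled from Fragstats +
ArcGIS: every step is a plain Python function, every run is seeded, and
a built-in synthetic-landscape generator provides inputs with known
ground truth for validation at desk scale.

## The model

Per tile of an analysis grid laid over a categorical land-use raster:

```
EHI = (EV · EO · ER · ES)^(1/4)                       (geometric mean, in [0,1])

EV  = normalized tile-mean NDVI                        (vigour)
EO  = 0.25·SHDI + 0.10·MPFD + 0.25·FN₁ + 0.10·CONT    (organization;
      + Σ_{f ∈ forest, grassland, water} (0.07·FN_f + 0.03·COHE_f)   weights sum to 1)
ER  = Σ_i A_i · ERC_i                                  (resilience; area-weighted coefficients)
ES  = (1/n) Σ_j ESC_j · (1 + SNE_j / 100)              (services; neighbour-adjusted coefficients)
```

with all sub-indices min-max normalized over the run (fragmentation
inverted, since high fragmentation means low organization) and EHI
classified into five equal-interval health classes.  Spatial structure
of the resulting tile scores is tested with

```
Moran's I = n ΣΣ W_ij z_i z_j / (S² ΣΣ W_ij),   I_i = n z_i Σ_j w_ij z_j / Σ z²
```

under permutation inference, and driver effects are modelled locally by

```
β̂(u_i, v_i) = (Xᵀ W(u_i,v_i) X)⁻¹ Xᵀ W(u_i,v_i) y,   w_ij = exp(−½ (d_ij/b)²)
```

with the bandwidth *b* minimizing the small-sample AICc.  Candidate
covariates are screened by enumerating all subsets, discarding those
with Max-VIF ≥ 7.5 and ranking the rest by adjusted R².

## Worked example

```python
import numpy as np
from vorscape import (SimulationConfig, gen_categorical_landscape,
                      gen_ndvi_from_landuse, score_snapshots,
                      build_contiguity_weights, moran_permutation_test)

landuse = gen_categorical_landscape(SimulationConfig(nrows=120, ncols=120,
                                                     spatial_range=6.0, seed=3))
ndvi = gen_ndvi_from_landuse(landuse, (0.55, 0.85, 0.60, 0.10, 0.15, 0.20),
                             noise_sd=0.05, seed=4)
(tiles,) = score_snapshots([(landuse, ndvi)], window_size=10)
w = build_contiguity_weights(12, 12, "queen", row_standardize=True)
gm = moran_permutation_test(tiles["EHI"].to_numpy(), w, 999, seed=5)
print(f"I = {gm.I:.4f}, p = {gm.p_perm:.4f}")
```

prints

```
I = 0.3057, p = 0.0010
```

a strongly positive global Moran's *I* (null expectation −1/143 ≈
−0.007): tiles of similar ecosystem health cluster in space, as expected
for a patchy landscape whose health score inherits the land-use spatial
structure.  The scripts in `examples/` walk through each capability —
landscape simulation, landscape metrics, VORS scoring, Moran/LISA, and
driver analysis with OLS-vs-GWR diagnostics; `examples/05_gwr_drivers.py`
recovers a known linearly varying coefficient surface with correlation
0.993 while GWR's AICc drops from 1105 to 627 and the residual Moran's
*I* falls from 0.33 to −0.04 relative to OLS.

The same workflow runs end to end from a shell:

```bash
vorscape run-all --out my_run --seed 1          # or per stage:
vorscape simulate --out my_run --seed 1
vorscape metrics  --out my_run
...
vorscape report   --out my_run
```

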