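"""Spatially varying driver effects: exploratory selection, OLS vs GWR.

A synthetic scenario with a known coefficient surface (the slope of x1
rises linearly west to east) shows how all-subsets screening finds the
informative covariates and how GWR recovers the nonstationary effect
that a global OLS fit averages away.
"""

import numpy as np
import pandas as pd

from vorscape import (RegressionDataset, build_contiguity_weights, compare_models,
                      exploratory_regression, gen_gwr_scenario, gwr_fit, ols_fit,
                      select_bandwidth)

idx = np.arange(400)
coords = np.column_stack([idx % 20 + 0.5, idx // 20 + 0.5]).astype(float)
truth = gen_gwr_scenario(
    coords,
    [{"kind": "linear", "intercept": 1.0, "dv": 0.1},   # drifting baseline
     {"kind": "linear", "du": 0.1},                      # x1 effect grows with u
     {"kind": "constant", "value": -0.5}],               # x2 effect constant
    noise_sd=0.5, seed=42,
)

# exploratory screen over the two real covariates plus three decoys
rng = np.random.default_rng(0)
cand = pd.DataFrame(np.column_stack([truth.X, rng.normal(size=(400, 3))]),
                    columns=["x1", "x2", "d1", "d2", "d3"])
table = exploratory_regression(cand, truth.y, coords)
print("top 3 subsets by adjusted R2 (Max-VIF screen at 7.5):")
print(table[table["rank"].notna()].nsmallest(3, "rank")
      [["variables", "adj_r2", "aicc", "max_vif"]].to_string(index=False))

ds = RegressionDataset(truth.y, truth.X, coords, names=["x1", "x2"])
ols = ols_fit(ds)
bw = select_bandwidth(ds)
gwr = gwr_fit(ds, bw)
w = build_contiguity_weights(20, 20, "queen", True)
print(f"\nAICc-optimal Gaussian bandwidth: {bw:.2f}")
print(compare_models(ols, gwr, w).round(3).to_string(index=False))
corr = np.corrcoef(gwr.local_beta[:, 1], truth.beta_surfaces[:, 1])[0, 1]
print(f"\ncorrelation(estimated beta1 surface, true surface) = {corr:.3f}")
print("GWR's lower AICc and near-null residual Moran's I show the local "
      "model absorbs the spatial structure the global fit leaves behind.")
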