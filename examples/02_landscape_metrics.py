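"""Per-tile landscape pattern metrics on an analysis grid.

Each 10x10-cell tile gets Shannon diversity, mean patch fractal dimension,
contagion, patch density (fragmentation) and per-focal-class cohesion --
the raw ingredients of the ecosystem-organization score.
"""

from vorscape import (AnalysisGrid, SimulationConfig, compute_window_metrics,
                      gen_categorical_landscape)

landuse = gen_categorical_landscape(SimulationConfig(nrows=100, ncols=100,
                                                     spatial_range=5.0, seed=7))
grid = AnalysisGrid.for_raster(landuse, window_size=10)
metrics = compute_window_metrics(landuse, grid, focal_classes=(2, 3, 4))

print(metrics[["tile_row", "tile_col", "shdi", "mpfd", "contag",
               "fn_landscape", "cohe_c2"]].head(8).to_string(index=False))
print(f"\n{len(metrics)} tiles; shdi in [0, ln K], contag in [0,1] "
      "(1 = fully aggregated), fn_landscape = patches per cell "
      "(higher = more fragmented), cohe_c2 = forest cohesion.")
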