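"""End-to-end run: simulate -> metrics -> VORS -> Moran/LISA -> selection ->
OLS/GWR, from one config and one seed, with all outputs written to disk.

Equivalent CLI:  vorscape run-all --out scratch/demo_run --seed 1
"""

from vorscape import RunConfig, report, run_pipeline

config = RunConfig(out_dir="scratch/demo_run", seed=1, n_years=2,
                   nrows=96, ncols=96, n_zones=60, window_size=8)
manifest = run_pipeline(config)
print(report(manifest))
print("\nOutputs (ASCII grids, CSV, GeoJSON) and manifest.json are in",
      config.out_dir)
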