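"""End-to-end orchestration: simulate -> metrics -> VORS -> Moran/LISA ->
variable selection -> OLS/GWR, from a single config with one master seed.

Each stage persists its outputs (ASCII grids, CSV, GeoJSON) under the
run directory and records itself in ``manifest.json``, so stages can be
re-run individually and a completed run is reproducible bit-for-bit
from the same config and seed.  Multi-year runs share one normalization
scope so health scores are comparable across snapshots.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .landscape import compute_window_metrics
from .rasters import AnalysisGrid, read_ascii_grid, write_ascii_grid, ContinuousRaster
from .regression import (RegressionDataset, compare_models, exploratory_regression,
                         gwr_fit, ols_fit, select_bandwidth)
from .spatial import (build_contiguity_weights, build_zone_adjacency_weights,
                      lisa_clusters, moran_permutation_test)
from .vors import CoefficientTables, score_snapshots

__all__ = ["RunConfig", "Pipeline", "run_pipeline", "report"]

log = logging.getLogger("vorscape")

STAGES = ("simulate", "metrics", "vors", "moran", "select", "regress")

_CSV_FMT = "%.10g"


@dataclass
class RunConfig:
    """Every tunable of a pipeline run, with desk-scale defaults."""

    mode: str = "synthetic"  # synthetic | files
    out_dir: str = "vorscape_run"
    seed: int = 0
    n_years: int = 2
    # synthetic landscape block
    nrows: int = 96
    ncols: int = 96
    cell_size: float = 1.0
    n_classes: int = 6
    class_proportions: tuple = (0.20, 0.22, 0.30, 0.06, 0.07, 0.15)
    spatial_range: float = 4.0
    ndvi_class_means: tuple = (0.55, 0.85, 0.60, 0.10, 0.15, 0.20)
    ndvi_noise_sd: float = 0.05
    n_zones: int = 60
    # files mode: per-year raster paths
    landuse_files: tuple = ()
    ndvi_files: tuple = ()
    zone_file: str = ""
    zone_table_file: str = ""
    # analysis block
    window_size: int = 8
    focal_classes: tuple = (2, 3, 4)
    connectivity: int = 8
    coefficients_file: str = ""  # empty -> built-in defaults
    weights_scheme: str = "queen"
    n_permutations: int = 999
    lisa_alpha: float = 0.05
    vif_threshold: float = 7.5
    bandwidth_bounds: tuple = ()  # empty -> [0.05, 2.0] x diameter
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        return cfg

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        for name in ("class_proportions", "ndvi_class_means", "focal_classes",
                     "landuse_files", "ndvi_files", "bandwidth_bounds"):
            setattr(self, name, tuple(getattr(self, name)))
        if self.mode == "files":
            for p in (*self.landuse_files, *self.ndvi_files, self.zone_file):
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
            if not self.landuse_files:
                raise ValueError("files mode requires landuse_files")


class Pipeline:
    """Stateful runner; stages read prior outputs from the run directory."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    # ---- manifest bookkeeping -------------------------------------------
    @property
    def manifest_path(self) -> Path:
        return self.out / "manifest.json"

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        return {"config": asdict(self.cfg), "seed": self.cfg.seed, "stages": {}}

    def _record(self, stage: str, outputs: list[Path], **summary) -> None:
        man = self._load_manifest()
        man["config"] = asdict(self.cfg)
        man["stages"][stage] = {
            "outputs": [str(p.relative_to(self.out)) for p in outputs],
            **summary,
        }
        self.manifest_path.write_text(json.dumps(man, indent=2, sort_keys=True, default=str))

    def _write_csv(self, df: pd.DataFrame, path: Path) -> Path:
        df.to_csv(path, index=False, float_format=_CSV_FMT)
        return path

    # ---- stage: simulate -------------------------------------------------
    def stage_simulate(self) -> list[Path]:
        cfg = self.cfg
        outputs = []
        if cfg.mode == "files":
            return self._ingest_files()
        for year in range(cfg.n_years):
            seed_lu = synthetic.stage_seed(cfg.seed, 10 + year)
            sim = synthetic.SimulationConfig(
                nrows=cfg.nrows, ncols=cfg.ncols, cell_size=cfg.cell_size,
                n_classes=cfg.n_classes, class_proportions=cfg.class_proportions,
                spatial_range=cfg.spatial_range, seed=seed_lu,
            )
            landuse = synthetic.gen_categorical_landscape(sim)
            ndvi = synthetic.gen_ndvi_from_landuse(
                landuse, cfg.ndvi_class_means, cfg.ndvi_noise_sd,
                seed=synthetic.stage_seed(cfg.seed, 20 + year),
            )
            p1 = self.out / f"year{year}_landuse.asc"
            p2 = self.out / f"year{year}_ndvi.asc"
            write_ascii_grid(p1, landuse)
            write_ascii_grid(p2, ndvi)
            outputs += [p1, p2]
        # climate surfaces shared across years (long-term means)
        amt = synthetic.gen_continuous_surface(
            cfg.nrows, cfg.ncols, gradient=(0.04, 0.01), intercept=2.0,
            noise_sd=0.3, seed=synthetic.stage_seed(cfg.seed, 30),
            cell_size=cfg.cell_size,
        )
        amp = synthetic.gen_continuous_surface(
            cfg.nrows, cfg.ncols, gradient=(-1.2, 2.0), intercept=300.0,
            noise_sd=15.0, seed=synthetic.stage_seed(cfg.seed, 31),
            cell_size=cfg.cell_size,
        )
        zones = synthetic.gen_zones(cfg.nrows, cfg.ncols, cfg.n_zones,
                                    seed=synthetic.stage_seed(cfg.seed, 32),
                                    cell_size=cfg.cell_size)
        landuse0 = read_ascii_grid(self.out / "year0_landuse.asc", categorical=True)
        zcov = synthetic.gen_zone_covariates(zones, landuse0,
                                             seed=synthetic.stage_seed(cfg.seed, 33))
        p3, p4 = self.out / "amt.asc", self.out / "amp.asc"
        write_ascii_grid(p3, amt)
        write_ascii_grid(p4, amp)
        from .rasters import CategoricalRaster
        p5 = self.out / "zones.asc"
        write_ascii_grid(p5, CategoricalRaster(zones.zone_ids, cfg.cell_size, 0))
        p6 = self._write_csv(zcov, self.out / "zones.csv")
        outputs += [p3, p4, p5, p6]
        self._record("simulate", outputs, n_years=cfg.n_years,
                     seeds={"master": cfg.seed})
        return outputs

    def _ingest_files(self) -> list[Path]:
        cfg = self.cfg
        outputs = []
        for year, (lu, nd) in enumerate(zip(cfg.landuse_files, cfg.ndvi_files)):
            for src, dst in ((lu, f"year{year}_landuse.asc"), (nd, f"year{year}_ndvi.asc")):
                data = Path(src).read_text()
                (self.out / dst).write_text(data)
                outputs.append(self.out / dst)
        if cfg.zone_file:
            (self.out / "zones.asc").write_text(Path(cfg.zone_file).read_text())
            outputs.append(self.out / "zones.asc")
        if cfg.zone_table_file:
            (self.out / "zones.csv").write_text(Path(cfg.zone_table_file).read_text())
            outputs.append(self.out / "zones.csv")
        self._record("simulate", outputs, n_years=len(cfg.landuse_files), mode="files")
        return outputs

    # ---- helpers ---------------------------------------------------------
    def _landuse(self, year: int):
        return read_ascii_grid(self.out / f"year{year}_landuse.asc", categorical=True)

    def _ndvi(self, year: int):
        return read_ascii_grid(self.out / f"year{year}_ndvi.asc")

    def _n_years(self) -> int:
        man = self._load_manifest()
        return int(man["stages"]["simulate"].get("n_years", self.cfg.n_years))

    def _grid(self, landuse) -> AnalysisGrid:
        return AnalysisGrid.for_raster(landuse, self.cfg.window_size)

    def _tables(self) -> CoefficientTables:
        if self.cfg.coefficients_file:
            return CoefficientTables.from_yaml(self.cfg.coefficients_file)
        return CoefficientTables.defaults()

    # ---- stage: metrics --------------------------------------------------
    def stage_metrics(self) -> list[Path]:
        outputs = []
        n_rows = 0
        for year in range(self._n_years()):
            landuse = self._landuse(year)
            grid = self._grid(landuse)
            df = compute_window_metrics(landuse, grid, self.cfg.focal_classes,
                                        self.cfg.connectivity)
            outputs.append(self._write_csv(df, self.out / f"year{year}_metrics.csv"))
            n_rows += len(df)
        self._record("metrics", outputs, n_rows=n_rows,
                     window_size=self.cfg.window_size)
        return outputs

    # ---- stage: vors -----------------------------------------------------
    def stage_vors(self) -> list[Path]:
        cfg = self.cfg
        snapshots = [(self._landuse(y), self._ndvi(y)) for y in range(self._n_years())]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = score_snapshots(snapshots, cfg.window_size, self._tables(),
                                      cfg.focal_classes, cfg.connectivity)
        outputs = []
        for year, df in enumerate(results):
            outputs.append(self._write_csv(df, self.out / f"year{year}_vors.csv"))
            grid = self._grid(snapshots[year][0])
            ehi = df["EHI"].to_numpy().reshape(grid.n_tile_rows, grid.n_tile_cols)
            p = self.out / f"year{year}_ehi.asc"
            write_ascii_grid(p, ContinuousRaster(ehi, grid.window_size * grid.cell_size))
            outputs.append(p)
        self._record("vors", outputs, n_rows=sum(len(d) for d in results))
        return outputs

    # ---- stage: moran ----------------------------------------------------
    def stage_moran(self) -> list[Path]:
        cfg = self.cfg
        outputs = []
        global_rows = []
        for year in range(self._n_years()):
            df = pd.read_csv(self.out / f"year{year}_vors.csv")
            grid_rows = df["tile_row"].max() + 1
            grid_cols = df["tile_col"].max() + 1
            w = build_contiguity_weights(grid_rows, grid_cols, cfg.weights_scheme, True)
            ehi = df["EHI"].to_numpy()
            keep = np.isfinite(ehi)
            wk = w.subset(keep) if not keep.all() else w
            seed = synthetic.stage_seed(cfg.seed, 40 + year)
            gm = moran_permutation_test(ehi[keep], wk, cfg.n_permutations, seed)
            li = lisa_clusters(ehi[keep], wk, cfg.lisa_alpha, cfg.n_permutations, seed)
            global_rows.append({"year": year, "moran_i": gm.I, "expected_i": gm.expected_I,
                                "z_norm": gm.z_norm, "p_perm": gm.p_perm,
                                "n_permutations": gm.n_permutations, "n_units": int(keep.sum())})
            lisa_df = df.loc[keep, ["tile_row", "tile_col", "centre_x", "centre_y", "EHI"]].copy()
            lisa_df["I_local"] = li.I_local
            lisa_df["p_perm"] = li.p_perm
            lisa_df["cluster"] = li.cluster
            outputs.append(self._write_csv(lisa_df, self.out / f"year{year}_lisa.csv"))
            outputs.append(self._write_lisa_geojson(lisa_df, year))
        outputs.append(self._write_csv(pd.DataFrame(global_rows),
                                       self.out / "moran_global.csv"))
        self._record("moran", outputs, n_years=self._n_years(),
                     n_permutations=cfg.n_permutations)
        return outputs

    def _write_lisa_geojson(self, lisa_df: pd.DataFrame, year: int) -> Path:
        half = 0.5 * self.cfg.window_size * self.cfg.cell_size
        feats = []
        for _, row in lisa_df.iterrows():
            x, y = row["centre_x"], row["centre_y"]
            ring = [[x - half, y - half], [x + half, y - half],
                    [x + half, y + half], [x - half, y + half], [x - half, y - half]]
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"I_local": row["I_local"], "p": row["p_perm"],
                               "cluster": row["cluster"], "EHI": row["EHI"]},
            })
        p = self.out / f"year{year}_lisa.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
        return p

    # ---- stage: select ---------------------------------------------------
    def _zone_table(self, year: int) -> pd.DataFrame:
        zones_r = read_ascii_grid(self.out / "zones.asc", categorical=True)
        zcov = pd.read_csv(self.out / "zones.csv")
        landuse = self._landuse(year)
        grid = self._grid(landuse)
        vors = pd.read_csv(self.out / f"year{year}_vors.csv")
        # per-cell EHI (each cell inherits its tile's EHI), then zone means
        ehi_tiles = vors["EHI"].to_numpy().reshape(grid.n_tile_rows, grid.n_tile_cols)
        ws = grid.window_size
        cell_ehi = np.repeat(np.repeat(ehi_tiles, ws, axis=0), ws, axis=1)
        cell_ehi = cell_ehi[: grid.nrows, : grid.ncols]
        amt = read_ascii_grid(self.out / "amt.asc").values
        amp = read_ascii_grid(self.out / "amp.asc").values
        z = zones_r.values.ravel()
        nz = int(z.max())
        counts = np.bincount(z, minlength=nz + 1)[1:]

        def zmean(a):
            return np.bincount(z, weights=np.nan_to_num(a.ravel()), minlength=nz + 1)[1:] / counts

        tab = zcov.copy()
        tab["AMT"] = zmean(amt)
        tab["AMP"] = zmean(amp)
        tab["EHI"] = zmean(cell_ehi)
        return tab

    def stage_select(self) -> list[Path]:
        year = self._n_years() - 1
        tab = self._zone_table(year)
        outputs = [self._write_csv(tab, self.out / "zone_table.csv")]
        candidates = tab[["AMT", "AMP", "GDP", "PD", "UR", "LUI", "BI"]]
        coords = tab[["centroid_x", "centroid_y"]].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = exploratory_regression(candidates, tab["EHI"].to_numpy(), coords,
                                           self.cfg.vif_threshold)
        outputs.append(self._write_csv(table, self.out / "exploratory.csv"))
        best = table.loc[table["rank"] == 1, "variables"]
        self._record("select", outputs, n_rows=len(table),
                     selected=(best.iloc[0] if len(best) else ""))
        return outputs

    # ---- stage: regress --------------------------------------------------
    def stage_regress(self) -> list[Path]:
        cfg = self.cfg
        man = self._load_manifest()
        selected = man["stages"]["select"].get("selected", "")
        names = [s.strip() for s in selected.split("+")] if selected else ["AMT", "AMP", "LUI", "BI"]
        tab = pd.read_csv(self.out / "zone_table.csv")
        coords = tab[["centroid_x", "centroid_y"]].to_numpy()
        ds = RegressionDataset(tab["EHI"].to_numpy(), tab[names].to_numpy(),
                               coords, names=names)
        ols = ols_fit(ds)
        bounds = cfg.bandwidth_bounds or (None, None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bw = select_bandwidth(ds, *bounds)
        gwr = gwr_fit(ds, bw)
        zones_r = read_ascii_grid(self.out / "zones.asc", categorical=True)
        w = build_zone_adjacency_weights(zones_r.values)
        diag = compare_models(ols, gwr, w)
        diag.insert(0, "bandwidth", bw)
        diag.insert(0, "variables", " + ".join(names))
        outputs = [self._write_csv(diag, self.out / "diagnostics.csv")]
        coef = pd.DataFrame(gwr.local_beta, columns=["intercept"] + names)
        coef.insert(0, "zone_id", tab["zone_id"])
        coef["u"] = coords[:, 0]
        coef["v"] = coords[:, 1]
        coef["fitted"] = gwr.fitted
        coef["residual"] = gwr.residuals
        outputs.append(self._write_csv(coef, self.out / "local_coefficients.csv"))
        feats = [{
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row["u"], row["v"]]},
            "properties": {k: row[k] for k in ["zone_id", "intercept", *names, "residual"]},
        } for _, row in coef.iterrows()]
        pgeo = self.out / "local_coefficients.geojson"
        pgeo.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
        outputs.append(pgeo)
        self._record("regress", outputs, bandwidth=bw, n_rows=len(coef),
                     aicc_ols=ols.aicc, aicc_gwr=gwr.aicc)
        return outputs

    # ---- run-all ---------------------------------------------------------
    def run(self, stages=STAGES) -> dict:
        for stage in stages:
            log.info("running stage %s", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        return self._load_manifest()


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the pipeline (all stages by default); returns the manifest."""
    return Pipeline(config).run(stages)


def report(manifest: dict) -> str:
    """Human-readable run summary from a manifest."""
    stages = manifest.get("stages", {})
    if not stages:
        return "no stages have been run"
    out_dir = Path(manifest.get("config", {}).get("out_dir", "."))
    lines = [f"vorscape run ({len(stages)} stages complete)"]
    if "moran" in stages:
        gm = pd.read_csv(out_dir / "moran_global.csv")
        for _, r in gm.iterrows():
            lines.append(
                f"  year {int(r['year'])}: global Moran's I = {r['moran_i']:.4f} "
                f"(E[I] = {r['expected_i']:.4f}, p = {r['p_perm']:.4f})"
            )
        for year in range(int(gm["year"].max()) + 1):
            li = pd.read_csv(out_dir / f"year{year}_lisa.csv")
            counts = li["cluster"].value_counts().to_dict()
            lines.append(f"  year {year} LISA clusters: " + ", ".join(
                f"{k}={v}" for k, v in sorted(counts.items())))
    else:
        lines.append("  Moran section absent")
    if "select" in stages:
        tab = pd.read_csv(out_dir / "exploratory.csv")
        top = tab[tab["rank"].notna()].nsmallest(3, "rank")
        lines.append("  top variable combinations (adj R2, AICc, Max-VIF):")
        for _, r in top.iterrows():
            lines.append(f"    {int(r['rank'])}. {r['variables']}: "
                         f"{r['adj_r2']:.3f}, {r['aicc']:.1f}, {r['max_vif']:.2f}")
    if "regress" in stages:
        diag = pd.read_csv(out_dir / "diagnostics.csv")
        r = diag.iloc[0]
        lines.append(
            f"  OLS vs GWR [{r['variables']}] (bandwidth {r['bandwidth']:.2f}): "
            f"AICc {r['aicc_ols']:.1f} -> {r['aicc_gwr']:.1f}, "
            f"adj R2 {r['adj_r2_ols']:.3f} -> {r['adj_r2_gwr']:.3f}, "
            f"residual Moran's I {r['moran_ols']:.3f} -> {r['moran_gwr']:.3f}"
        )
    else:
        lines.append("  GWR section absent")
    return "\n".join(lines)
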