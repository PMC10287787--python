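"""Ecosystem-health (VORS) scoring.

The composite ecosystem health index of a tile is the geometric mean of
four components, each on [0, 1]:

    EHI = (EV * EO * ER * ES) ** (1/4)

* **EV, vigour** — tile-mean NDVI, min-max normalized across the run.
* **EO, organization** — weighted sum of normalized landscape-pattern
  sub-indices: 0.25 SHDI + 0.10 MPFD + 0.25 FN1 + 0.10 CONT plus
  (0.07 FN + 0.03 COHESION) for each of the three focal classes
  (forest, grassland, water), weights summing to 1.  Fragmentation
  enters inverted (1 - minmax) because high fragmentation means low
  organization.
* **ER, resilience** — area-weighted mean of per-class resilience
  coefficients: ER = sum_i A_i * ERC_i.
* **ES, services** — mean over window pixels of
  ESC_j * (1 + SNE_j / 100), where SNE_j sums the percent
  neighbour-effect terms over the pixel's queen (8-cell) neighbourhood,
  then min-max normalized across tiles.

Normalization is pooled across all snapshots (years) of a run so that
scores are comparable over time.  EHI is classified into five
equal-interval classes: degraded [0, 0.2), unhealthy [0.2, 0.4),
average [0.4, 0.6), suboptimal [0.6, 0.8), highest [0.8, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .landscape import compute_window_metrics
from .rasters import AnalysisGrid, CategoricalRaster, ContinuousRaster

__all__ = [
    "CoefficientTables",
    "EO_WEIGHTS",
    "HEALTH_CLASSES",
    "normalize_minmax",
    "compute_vigour",
    "compute_organization",
    "compute_resilience",
    "compute_services",
    "compute_ehi",
    "classify_ehi",
    "score_snapshots",
]

# organization sub-index weights; they sum to exactly 1.00
EO_WEIGHTS = {
    "shdi": 0.25,
    "mpfd": 0.10,
    "fn_landscape": 0.25,
    "contag": 0.10,
    "fn_focal": 0.07,  # per focal class
    "cohe_focal": 0.03,  # per focal class
}

HEALTH_CLASSES = ("degraded", "unhealthy", "average", "suboptimal", "highest")


@dataclass
class CoefficientTables:
    """Per-class resilience (ERC), service (ESC) and neighbour-effect (SNE) tables.

    ``sne[(a, b)]`` is the percent adjustment contributed to a pixel of
    class ``a`` by one adjacent cell of class ``b``.
    """

    erc: dict
    esc: dict
    sne: dict
    class_names: dict | None = None

    def __post_init__(self) -> None:
        classes = set(self.erc)
        if set(self.esc) != classes:
            raise ValueError("ERC and ESC must cover the same classes")
        for c, v in self.erc.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"ERC[{c}]={v} outside [0, 1]")
        for c, v in self.esc.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"ESC[{c}]={v} outside [0, 1]")
        for (a, b) in ((a, b) for a in classes for b in classes):
            if (a, b) not in self.sne:
                raise ValueError(f"SNE missing pair ({a}, {b})")

    @property
    def classes(self) -> list:
        return sorted(self.erc)

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientTables":
        sne = {}
        for a, row in d["sne"].items():
            for b, v in row.items():
                sne[(int(a), int(b))] = float(v)
        return cls(
            erc={int(k): float(v) for k, v in d["erc"].items()},
            esc={int(k): float(v) for k, v in d["esc"].items()},
            sne=sne,
            class_names={int(k): v for k, v in d.get("class_names", {}).items()} or None,
        )

    @classmethod
    def from_yaml(cls, path) -> "CoefficientTables":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def defaults(cls) -> "CoefficientTables":
        """Built-in six-class legend defaults (documented, replaceable)."""
        ref = resources.files("vorscape.data") / "default_coefficients.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text()))


def normalize_minmax(values) -> np.ndarray:
    """Linear map of finite values onto [0, 1]; NaN passes through.

    A constant input maps to all 0.5 with a warning (no spread to
    normalize over).
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() == 0:
        return np.full_like(x, np.nan)
    lo, hi = np.nanmin(x[finite]), np.nanmax(x[finite])
    if hi == lo:
        warnings.warn("constant input to normalize_minmax; returning 0.5", stacklevel=2)
        out = np.full_like(x, 0.5)
        out[~finite] = np.nan
        return out
    return (x - lo) / (hi - lo)


def compute_vigour(ndvi: ContinuousRaster, grid: AnalysisGrid) -> np.ndarray:
    """Raw vigour per tile: mean NDVI over valid cells (NaN if none)."""
    out = np.empty(grid.n_tiles)
    k = 0
    for _, _, rs, cs in grid.iter_tiles():
        win = ndvi.values[rs, cs]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[k] = np.nanmean(win) if np.isfinite(win).any() else np.nan
        k += 1
    return out


def compute_organization(metrics: pd.DataFrame, focal_classes=(2, 3, 4)) -> np.ndarray:
    """Organization score per tile from a (possibly multi-year) metrics table.

    Every sub-index is min-max normalized over the whole table (pooled
    scope), fragmentation indices are inverted (1 - minmax), and the
    printed weights are applied.  Terms for focal classes absent from a
    tile contribute 0 (the table's presence flags mark them).
    """
    w = EO_WEIGHTS
    shdi_n = normalize_minmax(metrics["shdi"].to_numpy())
    mpfd_raw = metrics["mpfd"].to_numpy().copy()
    # undefined MPFD (all patches single-cell) sits at the normalization floor
    undef = ~np.isfinite(mpfd_raw) & metrics["valid"].to_numpy(dtype=bool)
    if np.isfinite(mpfd_raw).any():
        mpfd_raw[undef] = np.nanmin(mpfd_raw)
    mpfd_n = normalize_minmax(mpfd_raw)
    contag_n = normalize_minmax(metrics["contag"].to_numpy())
    fn1_inv = 1.0 - normalize_minmax(metrics["fn_landscape"].to_numpy())
    eo = (w["shdi"] * shdi_n + w["mpfd"] * mpfd_n
          + w["fn_landscape"] * fn1_inv + w["contag"] * contag_n)
    for c in focal_classes:
        present = metrics[f"present_c{c}"].to_numpy(dtype=bool)
        fn = metrics[f"fn_c{c}"].to_numpy()
        cohe = metrics[f"cohe_c{c}"].to_numpy()
        fn_inv = 1.0 - normalize_minmax(fn)
        cohe_n = normalize_minmax(cohe)
        term = np.where(present, w["fn_focal"] * np.nan_to_num(fn_inv)
                        + w["cohe_focal"] * np.nan_to_num(cohe_n), 0.0)
        eo = eo + term
    return eo


def compute_resilience(landuse: CategoricalRaster, grid: AnalysisGrid,
                       tables: CoefficientTables) -> np.ndarray:
    """ER per tile: area-weighted resilience coefficient sum_i A_i * ERC_i."""
    lut_max = int(landuse.values.max())
    lut = np.full(lut_max + 1, np.nan)
    for c, v in tables.erc.items():
        if c <= lut_max:
            lut[c] = v
    out = np.empty(grid.n_tiles)
    k = 0
    for _, _, rs, cs in grid.iter_tiles():
        win = landuse.values[rs, cs]
        vals = win[win != landuse.nodata_code]
        if vals.size == 0:
            out[k] = np.nan
        else:
            coeffs = lut[vals]
            if np.isnan(coeffs).any():
                missing = sorted(set(vals[np.isnan(coeffs)].tolist()))
                raise KeyError(f"land-use classes {missing} missing from ERC table")
            out[k] = coeffs.mean()
        k += 1
    return out


def _sne_field(landuse: CategoricalRaster, tables: CoefficientTables) -> np.ndarray:
    """Per-pixel SNE_j (percent): sum of neighbour-effect terms over the
    queen neighbourhood; boundary pixels use available neighbours only."""
    classes = tables.classes
    kmax = int(max(classes))
    mat = np.zeros((kmax + 1, kmax + 1))
    for (a, b), v in tables.sne.items():
        mat[a, b] = v
    codes = landuse.values
    if int(codes.max()) > kmax or np.any(
        (codes != landuse.nodata_code) & ~np.isin(codes, classes)
    ):
        present = set(np.unique(codes).tolist()) - {landuse.nodata_code}
        missing = sorted(present - set(classes))
        if missing:
            raise KeyError(f"land-use classes {missing} missing from SNE table")
    nr, nc = codes.shape
    padded = np.full((nr + 2, nc + 2), landuse.nodata_code, dtype=codes.dtype)
    padded[1:-1, 1:-1] = codes
    sne = np.zeros((nr, nc))
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = padded[1 + dr : 1 + dr + nr, 1 + dc : 1 + dc + nc]
            ok = (nb != landuse.nodata_code) & (codes != landuse.nodata_code)
            sne[ok] += mat[codes[ok], nb[ok]]
    return sne


def compute_services(landuse: CategoricalRaster, grid: AnalysisGrid,
                     tables: CoefficientTables) -> np.ndarray:
    """Raw ES per tile: mean over pixels of ESC_j * (1 + SNE_j / 100)."""
    kmax = int(max(tables.classes))
    esc_lut = np.full(kmax + 1, np.nan)
    for c, v in tables.esc.items():
        esc_lut[c] = v
    codes = landuse.values
    present = set(np.unique(codes).tolist()) - {landuse.nodata_code}
    missing = sorted(c for c in present if c > kmax or np.isnan(esc_lut[c]))
    if missing:
        raise KeyError(f"land-use classes {missing} missing from ESC table")
    sne = _sne_field(landuse, tables)
    with np.errstate(invalid="ignore"):
        pixel = np.where(codes != landuse.nodata_code,
                         esc_lut[np.clip(codes, 0, kmax)] * (1.0 + sne / 100.0), np.nan)
    out = np.empty(grid.n_tiles)
    k = 0
    for _, _, rs, cs in grid.iter_tiles():
        win = pixel[rs, cs]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[k] = np.nanmean(win) if np.isfinite(win).any() else np.nan
        k += 1
    return out


def compute_ehi(ev, eo, er, es) -> np.ndarray:
    """EHI = fourth root of the product of the four components.

    A zero component gives EHI 0 (meaningful: fully degraded); negative
    components are an error.
    """
    comps = [np.asarray(c, dtype=float) for c in (ev, eo, er, es)]
    for c in comps:
        if np.any(c[np.isfinite(c)] < 0):
            raise ValueError("VORS components must be nonnegative")
    prod = comps[0] * comps[1] * comps[2] * comps[3]
    return prod ** 0.25


def classify_ehi(ehi) -> np.ndarray:
    """Five equal-interval health classes; half-open bins, top bin closed."""
    x = np.asarray(ehi, dtype=float)
    finite = x[np.isfinite(x)]
    if np.any((finite < -1e-9) | (finite > 1 + 1e-9)):
        raise ValueError("EHI must lie in [0, 1]")
    idx = np.digitize(np.clip(x, 0, 1), [0.2, 0.4, 0.6, 0.8], right=False)
    out = np.array([HEALTH_CLASSES[i] if np.isfinite(v) else "missing"
                    for i, v in zip(idx.ravel(), x.ravel())], dtype=object)
    return out.reshape(x.shape)


def score_snapshots(
    snapshots,
    window_size: int = 10,
    tables: CoefficientTables | None = None,
    focal_classes=(2, 3, 4),
    connectivity: int = 8,
) -> list[pd.DataFrame]:
    """Full VORS scoring of one or more (land-use, NDVI) snapshots.

    Normalization of vigour, organization sub-indices and services is
    pooled across all snapshots so scores share a common scale, as a
    multi-year comparison requires.  Returns one tile table per
    snapshot with components, EHI and health class.
    """
    if tables is None:
        tables = CoefficientTables.defaults()
    metrics_list, ev_raw, er_list, es_raw, grids = [], [], [], [], []
    for landuse, ndvi in snapshots:
        grid = AnalysisGrid.for_raster(landuse, window_size)
        grids.append(grid)
        metrics_list.append(
            compute_window_metrics(landuse, grid, focal_classes, connectivity)
        )
        ev_raw.append(compute_vigour(ndvi, grid))
        er_list.append(compute_resilience(landuse, grid, tables))
        es_raw.append(compute_services(landuse, grid, tables))
    pooled_metrics = pd.concat(metrics_list, ignore_index=True)
    eo_all = compute_organization(pooled_metrics, focal_classes)
    ev_all = normalize_minmax(np.concatenate(ev_raw))
    es_all = normalize_minmax(np.concatenate(es_raw))
    results = []
    ofs = 0
    for metrics, grid, er in zip(metrics_list, grids, er_list):
        n = len(metrics)
        ev = ev_all[ofs : ofs + n]
        eo = eo_all[ofs : ofs + n]
        es = es_all[ofs : ofs + n]
        ehi = compute_ehi(ev, eo, er, es)
        df = metrics[["tile_row", "tile_col", "centre_x", "centre_y", "n_valid"]].copy()
        df["EV"] = ev
        df["EO"] = eo
        df["ER"] = er
        df["ES"] = es
        df["EHI"] = ehi
        df["health_class"] = classify_ehi(ehi)
        results.append(df)
        ofs += n
    return results
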