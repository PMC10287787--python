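"""Seeded synthetic landscapes, covariate surfaces, zones and GWR scenarios.

These generators stand in for real land-use / NDVI / climate / county
data so that every stage of the analysis can be exercised at desk scale
with known ground truth.

Categorical landscapes are built by thresholding a kernel-smoothed white
noise field at the quantiles implied by the requested class proportions:
a positive ``spatial_range`` yields patchy, positively autocorrelated
class membership, while ``spatial_range = 0`` gives i.i.d. cells.

All generators are deterministic given their seed.  Pipelines derive
per-stage seeds from one master seed via :func:`stage_seed`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import deque

import numpy as np
from scipy import ndimage

from .rasters import CategoricalRaster, ContinuousRaster, ZoneMap

__all__ = [
    "SimulationConfig",
    "GWRScenarioTruth",
    "stage_seed",
    "gen_categorical_landscape",
    "gen_continuous_surface",
    "gen_ndvi_from_landuse",
    "gen_zones",
    "gen_gwr_scenario",
    "gen_zone_covariates",
]


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Derive an independent sub-seed (< 2**31) from a master seed.

    Uses numpy's SeedSequence spawning so stages can be re-run
    independently yet reproducibly.
    """
    child = np.random.SeedSequence(master_seed).spawn(stage_index + 1)[stage_index]
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class SimulationConfig:
    """Parameters of a synthetic categorical landscape.

    ``spatial_range`` is the correlation length in cells (the sigma of
    the Gaussian smoothing kernel); ``class_proportions`` must sum to 1.
    """

    nrows: int = 100
    ncols: int = 100
    cell_size: float = 1.0
    n_classes: int = 6
    class_proportions: tuple = (0.20, 0.22, 0.30, 0.06, 0.07, 0.15)
    spatial_range: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if self.nrows < 4 or self.ncols < 4:
            raise ValueError("nrows and ncols must be >= 4")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if len(props) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if np.any(props < 0):
            raise ValueError("class_proportions must be nonnegative")
        if self.spatial_range < 0 or self.noise_sd < 0:
            raise ValueError("spatial_range and noise_sd must be nonnegative")
        self.class_proportions = tuple(props)


def gen_categorical_landscape(config: SimulationConfig) -> CategoricalRaster:
    """Simulate a spatially autocorrelated land-use raster.

    A standard-normal white-noise field is smoothed with an isotropic
    Gaussian kernel of sigma ``spatial_range`` and thresholded at the
    quantiles implied by ``class_proportions``; class codes are
    1..n_classes.  Quantile thresholding makes realized proportions
    track the requested ones closely on large grids.
    """
    rng = np.random.default_rng(config.seed)
    fld = rng.standard_normal((config.nrows, config.ncols))
    if config.spatial_range > 0:
        fld = ndimage.gaussian_filter(fld, sigma=config.spatial_range, mode="reflect")
    cum = np.cumsum(config.class_proportions)[:-1]
    if len(cum):
        thresholds = np.quantile(fld, cum)
        codes = (np.searchsorted(thresholds, fld, side="right") + 1).astype(np.int64)
    else:
        codes = np.ones_like(fld, dtype=np.int64)
    return CategoricalRaster(codes, cell_size=config.cell_size, nodata_code=0)


def gen_continuous_surface(
    nrows: int,
    ncols: int,
    gradient=(0.0, 0.0),
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    cell_size: float = 1.0,
) -> ContinuousRaster:
    """Planar trend surface plus Gaussian noise (climate analogue).

    ``value(r, c) = intercept + gradient[0]*r + gradient[1]*c + eps``.
    """
    if nrows < 1 or ncols < 1:
        raise ValueError("dimensions must be >= 1")
    rows, cols = np.indices((nrows, ncols), dtype=float)
    vals = intercept + gradient[0] * rows + gradient[1] * cols
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    return ContinuousRaster(vals, cell_size=cell_size)


def gen_ndvi_from_landuse(
    landuse: CategoricalRaster,
    class_means,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ContinuousRaster:
    """NDVI keyed to land-use class: per-cell class mean + noise, clipped to [0, 1]."""
    means = np.asarray(class_means, dtype=float)
    if np.any((means < 0) | (means > 1)):
        raise ValueError("class means must lie in [0, 1]")
    codes = landuse.values
    lut = np.full(int(codes.max()) + 1, np.nan)
    lut[1 : len(means) + 1] = means
    vals = lut[codes]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        vals = np.clip(vals, 0.0, 1.0)
    vals[codes == landuse.nodata_code] = np.nan
    return ContinuousRaster(vals, cell_size=landuse.cell_size)


def gen_zones(nrows: int, ncols: int, n_zones: int, seed: int = 0, cell_size: float = 1.0) -> ZoneMap:
    """Partition the grid into contiguous zones grown from random seed cells.

    Multi-source breadth-first growth (grid-geodesic Voronoi): zones are
    guaranteed contiguous, nonempty, pairwise disjoint and exhaustive.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    if n_zones > nrows * ncols:
        raise ValueError("more zones than cells")
    rng = np.random.default_rng(seed)
    flat = rng.choice(nrows * ncols, size=n_zones, replace=False)
    zone = np.zeros((nrows, ncols), dtype=np.int64)
    queue: deque = deque()
    for z, f in enumerate(flat, start=1):
        r, c = divmod(int(f), ncols)
        zone[r, c] = z
        queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        z = zone[r, c]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and zone[rr, cc] == 0:
                zone[rr, cc] = z
                queue.append((rr, cc))
    return ZoneMap(zone, cell_size=cell_size)


@dataclass
class GWRScenarioTruth:
    """A regression scenario with known smoothly varying local coefficients.

    ``beta_surfaces`` has one column per coefficient (intercept first)
    evaluated at each location; the stored response satisfies
    ``y = rowwise dot(beta_surfaces, [1, X]) + noise`` exactly.
    """

    coords: np.ndarray
    X: np.ndarray
    beta_surfaces: np.ndarray
    noise_sd: float
    y: np.ndarray
    noise: np.ndarray = field(repr=False, default=None)


def _eval_surface(spec, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    if callable(spec):
        return np.asarray(spec(u, v), dtype=float)
    kind = spec.get("kind", "constant")
    if kind == "constant":
        return np.full_like(u, float(spec["value"]))
    if kind == "linear":
        return (
            float(spec.get("intercept", 0.0))
            + float(spec.get("du", 0.0)) * u
            + float(spec.get("dv", 0.0)) * v
        )
    if kind == "radial":
        u0, v0 = spec.get("center", (u.mean(), v.mean()))
        scale = float(spec.get("scale", 1.0))
        d2 = (u - u0) ** 2 + (v - v0) ** 2
        return float(spec.get("offset", 0.0)) + float(spec.get("amplitude", 1.0)) * np.exp(
            -0.5 * d2 / scale**2
        )
    raise ValueError(f"unknown surface kind {kind!r}")


def gen_gwr_scenario(
    coords,
    surface_specs,
    noise_sd: float = 0.0,
    seed: int = 0,
    X=None,
) -> GWRScenarioTruth:
    """Assemble ``y_i = beta_0(u_i,v_i) + sum_j beta_j(u_i,v_i) x_ij + eps_i``.

    Parameters
    ----------
    coords
        (n, 2) location coordinates (u, v).
    surface_specs
        One spec per coefficient, intercept first: a callable ``f(u, v)``
        or a dict with ``kind`` in {constant, linear, radial}.
    X
        Optional (n, p) design; drawn i.i.d. standard normal if omitted.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    p = len(surface_specs) - 1
    if p < 0:
        raise ValueError("need at least an intercept surface")
    if n < p + 3:
        raise ValueError("need at least p + 3 locations")
    rng = np.random.default_rng(seed)
    if X is None:
        X = rng.standard_normal((n, p))
    else:
        X = np.asarray(X, dtype=float)
        if X.shape != (n, p):
            raise ValueError("X shape does not match coords / surface_specs")
    u, v = coords[:, 0], coords[:, 1]
    beta = np.column_stack([_eval_surface(s, u, v) for s in surface_specs])
    design = np.column_stack([np.ones(n), X])
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    y = np.einsum("ij,ij->i", beta, design) + noise
    return GWRScenarioTruth(coords=coords, X=X, beta_surfaces=beta, noise_sd=noise_sd, y=y, noise=noise)


def gen_zone_covariates(
    zones: ZoneMap,
    landuse: CategoricalRaster,
    seed: int = 0,
    class_legend: dict | None = None,
) -> "pandas.DataFrame":
    """Zone-level socio-economic covariate table (county-yearbook analogue).

    Produces GDP density, population density, urbanization rate,
    land-use intensity and a biodiversity index per zone.  LUI and BI
    are tied to zone land-cover composition (built-up/cropland shares
    and Shannon diversity of classes); GDP/PD/UR are smooth functions of
    the zone centroid plus lognormal noise, mimicking the spatial
    gradients of real regional statistics.
    """
    import pandas as pd

    legend = class_legend or {"cropland": 1, "forest": 2, "grassland": 3,
                              "water": 4, "builtup": 5, "unused": 6}
    rng = np.random.default_rng(seed)
    nz = zones.n_zones
    flat_zone = zones.zone_ids.ravel()
    flat_lu = landuse.values.ravel()
    counts = np.bincount(flat_zone, minlength=nz + 1)[1:].astype(float)

    def zone_share(code: int) -> np.ndarray:
        sel = np.bincount(flat_zone, weights=(flat_lu == code).astype(float), minlength=nz + 1)[1:]
        return sel / counts

    shares = {name: zone_share(code) for name, code in legend.items()}
    # Shannon diversity of land-use composition per zone
    shdi = np.zeros(nz)
    for s in shares.values():
        pos = s > 0
        shdi[pos] -= s[pos] * np.log(s[pos])

    cx, cy = zones.centroids[:, 0], zones.centroids[:, 1]
    xr = (cx - cx.min()) / max(np.ptp(cx), 1e-12)
    yr = (cy - cy.min()) / max(np.ptp(cy), 1e-12)

    lui = 1.0 * shares["builtup"] + 0.6 * shares["cropland"] + 0.2 * shares["grassland"]
    bi = shdi / np.log(len(legend))
    ur = np.clip(0.2 + 0.5 * shares["builtup"] * 5 + rng.normal(0, 0.05, nz), 0, 1)
    gdp = np.exp(0.5 + 2.0 * xr + rng.normal(0, 0.3, nz))
    pd_density = np.exp(1.0 + 1.5 * yr + rng.normal(0, 0.3, nz))
    return pd.DataFrame(
        {
            "zone_id": np.arange(1, nz + 1),
            "centroid_x": cx,
            "centroid_y": cy,
            "GDP": gdp,
            "PD": pd_density,
            "UR": ur,
            "LUI": lui,
            "BI": bi,
        }
    )
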