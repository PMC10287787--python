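"""Landscape pattern metrics on windows of a categorical raster.

Implements the metric families consumed by the ecosystem-organization
score: Shannon diversity (SHDI), mean patch fractal dimension (MPFD),
contagion (CONTAG), patch cohesion (COHESION) and fragmentation (patch
density), computed per tile of an :class:`~vorscape.rasters.AnalysisGrid`.

Conventions (configurable where noted):

* patch connectivity is 8-neighbour by default (4 selectable);
* window boundary edges count toward patch perimeter;
* contagion adjacencies are 4-neighbour, each adjacency counted in both
  orders (double-count);
* single-cell patches are excluded from the MPFD mean (their
  ``ln(area)`` is zero); if every patch is excluded the metric is
  undefined and flagged.

Raw fragmentation is patch count per window cell; inversion and min-max
normalization happen downstream where the organization score is
assembled, so that the values reported here are the plain densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .rasters import AnalysisGrid, CategoricalRaster

__all__ = [
    "PatchSet",
    "label_patches",
    "shannon_diversity",
    "mean_patch_fractal_dimension",
    "contagion",
    "patch_cohesion",
    "fragmentation",
    "compute_window_metrics",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class PatchSet:
    """Connected components of a window, one record per patch.

    ``area`` is the cell count; ``perimeter`` counts cell edges adjacent
    to a different class, nodata, or the window boundary.
    """

    class_code: np.ndarray  # (n_patches,)
    area: np.ndarray  # (n_patches,)
    perimeter: np.ndarray  # (n_patches,)
    connectivity: int = 8
    valid: bool = True
    labels: np.ndarray = field(default=None, repr=False)  # per-class label image map

    @property
    def n_patches(self) -> int:
        return len(self.area)

    def for_class(self, code: int) -> "PatchSet":
        m = self.class_code == code
        return PatchSet(self.class_code[m], self.area[m], self.perimeter[m],
                        self.connectivity, self.valid)


def label_patches(window: np.ndarray, connectivity: int = 8, nodata: int = 0) -> PatchSet:
    """Label per-class connected components and measure area and perimeter."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    window = np.asarray(window)
    if window.size == 0:
        raise ValueError("empty window")
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    classes = np.unique(window)
    classes = classes[classes != nodata]
    if len(classes) == 0:
        return PatchSet(np.array([], int), np.array([], int), np.array([], int),
                        connectivity, valid=False)
    codes, areas, perims = [], [], []
    for c in classes:
        mask = window == c
        lab, n = ndimage.label(mask, structure=struct)
        if n == 0:
            continue
        a = np.bincount(lab.ravel(), minlength=n + 1)[1:]
        # perimeter: edges where the cell's 4-neighbour differs in class
        # (different class, nodata, or outside the window)
        padded = np.pad(mask, 1, constant_values=False)
        exposed = np.zeros(mask.shape, dtype=int)
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nb = padded[1 + dr : 1 + dr + mask.shape[0], 1 + dc : 1 + dc + mask.shape[1]]
            exposed += mask & ~nb
        p = np.bincount(lab.ravel(), weights=exposed.ravel(), minlength=n + 1)[1:].astype(int)
        codes.append(np.full(n, c))
        areas.append(a)
        perims.append(p)
    return PatchSet(
        np.concatenate(codes), np.concatenate(areas), np.concatenate(perims), connectivity
    )


def _class_proportions(window: np.ndarray, nodata: int = 0):
    vals = window[window != nodata]
    if vals.size == 0:
        raise ValueError("window has no valid cells")
    classes, counts = np.unique(vals, return_counts=True)
    return classes, counts / vals.size


def shannon_diversity(window: np.ndarray, nodata: int = 0) -> float:
    """SHDI = -sum_k p_k ln p_k over class proportions of the window."""
    _, p = _class_proportions(window, nodata)
    return float(-(p * np.log(p)).sum() + 0.0)  # +0.0 normalizes -0.0


def mean_patch_fractal_dimension(patches: PatchSet) -> float:
    """Mean of per-patch ``2 ln(0.25 P) / ln(a)`` over patches with area >= 2.

    Returns NaN (undefined) when every patch is a single cell.
    """
    keep = patches.area >= 2
    if not np.any(keep):
        return float("nan")
    a = patches.area[keep].astype(float)
    p = patches.perimeter[keep].astype(float)
    return float(np.mean(2.0 * np.log(0.25 * p) / np.log(a)))


def _adjacency_counts(window: np.ndarray, nodata: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """4-neighbour class adjacency matrix, double-count convention."""
    classes = np.unique(window)
    classes = classes[classes != nodata]
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    g = np.zeros((k, k))
    remap = np.full(int(window.max()) + 1, -1)
    for c, i in idx.items():
        remap[c] = i
    w = remap[window]
    pairs = [(w[:, :-1], w[:, 1:]), (w[:-1, :], w[1:, :])]
    for a, b in pairs:
        ok = (a >= 0) & (b >= 0)
        np.add.at(g, (a[ok], b[ok]), 1)
        np.add.at(g, (b[ok], a[ok]), 1)
    return classes, g


def contagion(window: np.ndarray, nodata: int = 0) -> float:
    """Contagion on [0, 1]: 1 + sum q ln q / (2 ln K).

    ``q_ik = p_i * g_ik / sum_k g_ik`` from 4-neighbour adjacency counts
    ``g`` (double-count).  A single-class window is maximally aggregated
    by convention (1).  High values mean large aggregated patches, low
    values maximal interspersion.
    """
    classes, p = _class_proportions(window, nodata)
    k = len(classes)
    if k == 1:
        return 1.0
    _, g = _adjacency_counts(window, nodata)
    rowsum = g.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = p[:, None] * np.where(rowsum > 0, g / np.where(rowsum == 0, 1, rowsum), 0.0)
    pos = q > 0
    val = 1.0 + (q[pos] * np.log(q[pos])).sum() / (2.0 * np.log(k))
    return float(min(max(val, 0.0), 1.0))


def patch_cohesion(patches: PatchSet, focal_class: int, window_cell_count: int) -> float:
    """Patch cohesion of a focal class on [0, 1].

    ``[1 - sum P / sum(P sqrt(a))] / [1 - 1/sqrt(Z)]`` with Z the window
    cell count.  Returns 0 when the focal class is absent (callers flag
    this separately) and 0 when all focal patches are single cells.
    """
    sub = patches.for_class(focal_class)
    if sub.n_patches == 0:
        return 0.0
    if window_cell_count < 2:
        return float("nan")
    p = sub.perimeter.astype(float)
    a = sub.area.astype(float)
    raw = 1.0 - p.sum() / (p * np.sqrt(a)).sum()
    return float(raw / (1.0 - 1.0 / np.sqrt(window_cell_count)))


def fragmentation(patches: PatchSet, window_cell_count: int,
                  scope: str = "landscape", focal_class: int | None = None) -> float:
    """Raw fragmentation: patch count per window cell (patch density)."""
    if scope == "landscape":
        n = patches.n_patches
    elif scope == "class":
        if focal_class is None:
            raise ValueError("focal_class required for class scope")
        n = patches.for_class(focal_class).n_patches
    else:
        raise ValueError("scope must be 'landscape' or 'class'")
    return float(n) / float(window_cell_count)


def compute_window_metrics(
    raster: CategoricalRaster,
    grid: AnalysisGrid,
    focal_classes=(2, 3, 4),
    connectivity: int = 8,
) -> pd.DataFrame:
    """Per-tile landscape metrics table.

    One row per tile, keyed by tile row/col and tile-centre coordinates.
    Undefined metrics are NaN with a companion flag column, never
    silently zero-filled.  ``focal_classes`` are the class codes of the
    ecologically important patch types (forest, grassland, water in the
    default legend) whose fragmentation/cohesion enter the organization
    score; column names carry the class code (``fn_c2``, ``cohe_c2``...).
    """
    rows = []
    nodata = raster.nodata_code
    for tr, tc, rs, cs in grid.iter_tiles():
        win = raster.values[rs, cs]
        z = win.size
        rec = {
            "tile_row": tr,
            "tile_col": tc,
            "centre_x": 0.5 * (cs.start + cs.stop) * raster.cell_size,
            "centre_y": 0.5 * (rs.start + rs.stop) * raster.cell_size,
            "n_valid": int((win != nodata).sum()),
        }
        if rec["n_valid"] == 0:
            rec.update({"shdi": np.nan, "mpfd": np.nan, "contag": np.nan,
                        "fn_landscape": np.nan, "valid": False, "mpfd_defined": False})
            for c in focal_classes:
                rec[f"fn_c{c}"] = np.nan
                rec[f"cohe_c{c}"] = np.nan
                rec[f"present_c{c}"] = False
            rows.append(rec)
            continue
        patches = label_patches(win, connectivity=connectivity, nodata=nodata)
        mpfd = mean_patch_fractal_dimension(patches)
        rec.update(
            {
                "shdi": shannon_diversity(win, nodata),
                "mpfd": mpfd,
                "mpfd_defined": bool(np.isfinite(mpfd)),
                "contag": contagion(win, nodata),
                "fn_landscape": fragmentation(patches, z, "landscape"),
                "valid": True,
            }
        )
        for c in focal_classes:
            present = bool((patches.class_code == c).any())
            rec[f"present_c{c}"] = present
            rec[f"fn_c{c}"] = fragmentation(patches, z, "class", c) if present else np.nan
            rec[f"cohe_c{c}"] = patch_cohesion(patches, c, z) if present else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
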