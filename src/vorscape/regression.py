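"""Global (OLS) and geographically weighted regression with model selection.

The local model is

    y_i = beta_0(u_i, v_i) + sum_j beta_j(u_i, v_i) x_ij + eps_i

estimated at each location by weighted least squares,

    beta_hat(u_i, v_i) = (X' W_i X)^(-1) X' W_i y,

with a fixed-distance Gaussian kernel ``w_ij = exp(-0.5 (d_ij / b)^2)``.
The bandwidth ``b`` is chosen by golden-section search minimizing the
small-sample corrected AICc

    AICc = 2 n ln(sigma_hat) + n ln(2 pi) + n (n + tr(S)) / (n - 2 - tr(S)),

where ``S`` is the hat matrix of the local fits and ``tr(S)`` the
effective number of parameters.  OLS uses the same functional form with
``tr(S) = p + 1`` so that global and local AICc are directly
comparable (and coincide in the infinite-bandwidth limit).

Exploratory variable selection enumerates every non-empty candidate
subset, screens out subsets whose maximum variance inflation factor
reaches the collinearity threshold (7.5 by default), and ranks the
survivors by adjusted R-squared, mirroring the all-subsets screening
used in regional driver analyses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial import SpatialWeights, global_morans_i

__all__ = [
    "RegressionDataset",
    "OLSResult",
    "GWRResult",
    "ols_fit",
    "vif",
    "exploratory_regression",
    "gaussian_kernel_weights",
    "gwr_fit",
    "select_bandwidth",
    "compare_models",
]


def _data_diameter(coords: np.ndarray) -> float:
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    return float(np.linalg.norm(hi - lo))


@dataclass
class RegressionDataset:
    """Zone-level response, covariates and centroid coordinates."""

    y: np.ndarray
    X: np.ndarray
    coords: np.ndarray
    names: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.coords = np.asarray(self.coords, dtype=float)
        n, p = self.X.shape
        if self.names is None:
            self.names = [f"x{j + 1}" for j in range(p)]
        if self.y.size != n or self.coords.shape != (n, 2):
            raise ValueError("inconsistent shapes in regression dataset")
        if np.isnan(self.y).any() or np.isnan(self.X).any() or np.isnan(self.coords).any():
            raise ValueError("missing values not allowed")
        if n <= p + 2:
            raise ValueError("need n > p + 2 observations")
        # coincident centroids break distance kernels; jitter deterministically
        _, inv, counts = np.unique(self.coords, axis=0, return_inverse=True, return_counts=True)
        if np.any(counts > 1):
            warnings.warn("duplicate coordinates jittered", stacklevel=2)
            eps = 1e-9 * max(_data_diameter(self.coords), 1.0)
            rng = np.random.default_rng(12345)
            dup = counts[inv] > 1
            self.coords = self.coords + np.where(
                dup[:, None], rng.normal(0, eps, self.coords.shape), 0.0
            )

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _gaussian_aicc(rss: float, n: int, trace_s: float) -> float:
    if n - 2.0 - trace_s <= 0:
        raise ValueError("AICc undefined: effective parameters too close to n")
    sigma = np.sqrt(rss / n)
    return float(2 * n * np.log(sigma) + n * np.log(2 * np.pi)
                 + n * (n + trace_s) / (n - 2.0 - trace_s))


@dataclass
class OLSResult:
    beta: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    r2: float
    adj_r2: float
    aicc: float
    vif: np.ndarray | None
    names: list[str]

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)


def _find_collinear(Xd: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    rank = 0
    for j in range(Xd.shape[1]):
        r = np.linalg.matrix_rank(Xd[:, : j + 1])
        if r == rank:
            bad.append(names[j] if j > 0 else "intercept")
        rank = r
    return bad


def ols_fit(dataset: RegressionDataset) -> OLSResult:
    """Ordinary least squares with R2, adjusted R2, Gaussian AICc and VIF."""
    y, X = dataset.y, dataset.X
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xd) < p + 1:
        cols = _find_collinear(Xd, ["intercept"] + list(dataset.names))
        raise np.linalg.LinAlgError(
            f"design matrix rank-deficient; collinear columns: {cols}"
        )
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    fitted = Xd @ beta
    resid = y - fitted
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    aicc = _gaussian_aicc(rss, n, p + 1.0)
    v = vif(X) if p >= 2 else None
    return OLSResult(beta, resid, fitted, r2, adj_r2, aicc, v, list(dataset.names))


def vif(X) -> np.ndarray:
    """Variance inflation factors: 1 / (1 - R2_j) regressing each column
    on the others (with intercept); perfect collinearity reports inf."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 columns")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant column in VIF input")
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        rss = float(resid @ resid)
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2j = 1.0 - rss / tss
        out[j] = np.inf if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
    return out


def exploratory_regression(
    candidates: pd.DataFrame,
    y,
    coords,
    vif_threshold: float = 7.5,
) -> pd.DataFrame:
    """All-subsets OLS screening and ranking.

    Enumerates every non-empty subset of the candidate columns, records
    adjusted R2, AICc and Max-VIF per subset, marks subsets passing the
    Max-VIF screen, and ranks passing subsets by adjusted R2 descending
    (rank 1 = best).  Failed fits are recorded with NaN statistics, not
    fatal.
    """
    y = np.asarray(y, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    names = list(candidates.columns)
    rows = []
    for size in range(1, len(names) + 1):
        for combo in itertools.combinations(names, size):
            rec = {"variables": " + ".join(combo), "n_vars": size}
            try:
                ds = RegressionDataset(y, candidates[list(combo)].to_numpy(),
                                       coords, names=list(combo))
                fit = ols_fit(ds)
                maxvif = float(np.max(fit.vif)) if fit.vif is not None else 1.0
                rec.update({"adj_r2": fit.adj_r2, "aicc": fit.aicc, "max_vif": maxvif,
                            "passed": bool(maxvif < vif_threshold)})
            except (np.linalg.LinAlgError, ValueError) as exc:
                rec.update({"adj_r2": np.nan, "aicc": np.nan, "max_vif": np.inf,
                            "passed": False, "error": str(exc)})
            rows.append(rec)
    table = pd.DataFrame(rows)
    table["rank"] = np.nan
    passing = table.index[table["passed"]]
    order = table.loc[passing, "adj_r2"].sort_values(ascending=False).index
    table.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return table


def gaussian_kernel_weights(coords, focal_index: int, bandwidth: float) -> np.ndarray:
    """Fixed Gaussian kernel weights ``exp(-0.5 (d/b)^2)`` to one focal point."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords - coords[focal_index], axis=1)
    return np.exp(-0.5 * (d / bandwidth) ** 2)


@dataclass
class GWRResult:
    local_beta: np.ndarray  # (n, p+1), intercept first
    fitted: np.ndarray
    residuals: np.ndarray
    trace_s: float
    effective_params: float
    aicc: float
    r2: float
    adj_r2: float
    bandwidth: float
    kernel: str = "gaussian"
    names: list[str] = field(default=None)

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)


def gwr_fit(dataset: RegressionDataset, bandwidth: float) -> GWRResult:
    """Geographically weighted regression at a fixed Gaussian bandwidth.

    Solves the weighted normal equations at every location, accumulates
    the hat-matrix trace ``sum_i x_i (X'W_i X)^-1 x_i`` (the kernel
    weight at zero distance is 1), and reports the trace-based AICc and
    adjusted R2 with effective parameters ``tr(S)``.
    """
    y, X, coords = dataset.y, dataset.X, dataset.coords
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.empty((n, p + 1))
    fitted = np.empty(n)
    trace_s = 0.0
    for i in range(n):
        w = gaussian_kernel_weights(coords, i, bandwidth)
        Xw = Xd * w[:, None]
        xtwx = Xd.T @ Xw
        xtwy = Xw.T @ y
        try:
            c = np.linalg.cholesky(xtwx)
            bi = np.linalg.solve(c.T, np.linalg.solve(c, xtwy))
            si = Xd[i] @ np.linalg.solve(c.T, np.linalg.solve(c, Xd[i]))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"near-singular local design at location {i} "
                f"(bandwidth {bandwidth:g} too small; increase the bandwidth floor)"
            ) from exc
        beta[i] = bi
        fitted[i] = Xd[i] @ bi
        trace_s += si  # w_ii = 1 at distance 0
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    if n - trace_s - 1 <= 0:
        raise ValueError("effective parameters exceed observations; increase bandwidth")
    # residual df = n - tr(S); reduces exactly to the OLS n - p - 1 as b -> inf
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - trace_s)
    aicc = _gaussian_aicc(rss, n, trace_s)
    return GWRResult(beta, fitted, resid, trace_s, trace_s, aicc, r2, adj_r2,
                     bandwidth, "gaussian", list(dataset.names))


def select_bandwidth(
    dataset: RegressionDataset,
    b_min: float | None = None,
    b_max: float | None = None,
    rel_tol: float = 1e-3,
    return_trace: bool = False,
):
    """Golden-section search for the AICc-minimizing Gaussian bandwidth.

    Default search interval is [0.05, 2.0] times the data diameter.
    Bandwidths whose local fits are singular score +inf.  If the AICc
    trace is visibly non-unimodal the best bandwidth found is returned
    with a warning.
    """
    diam = _data_diameter(dataset.coords)
    if b_min is None:
        b_min = 0.05 * diam
    if b_max is None:
        b_max = 2.0 * diam
    if b_min <= 0 or b_max < b_min:
        raise ValueError("invalid bandwidth bounds")

    cache: dict[float, float] = {}

    def f(b: float) -> float:
        if b not in cache:
            try:
                cache[b] = gwr_fit(dataset, b).aicc
            except (np.linalg.LinAlgError, ValueError):
                cache[b] = np.inf
        return cache[b]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = b_min, b_max
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fa, fb, fc, fd = f(a), f(b), f(c), f(d)
    if not (np.isfinite(fa) or np.isfinite(fc)) and not (np.isfinite(fb) or np.isfinite(fd)):
        raise ValueError("AICc not finite anywhere in the search interval")
    while (b - a) > rel_tol * max(abs(a), abs(b), 1e-30):
        if fc <= fd:
            b, fb = d, fd
            d, fd = c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, fa = c, fc
            c, fc = d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    trace = sorted(cache.items())
    best = min(cache, key=cache.get)
    vals = [v for _, v in trace if np.isfinite(v)]
    # crude unimodality audit on the evaluation trace
    diffs = np.sign(np.diff(vals)) if len(vals) > 2 else np.array([])
    n_turns = int(np.count_nonzero(np.diff(diffs[diffs != 0]) != 0)) if diffs.size else 0
    if n_turns > 1:
        warnings.warn("AICc trace not unimodal; returning best bandwidth found",
                      stacklevel=2)
    if return_trace:
        return best, trace
    return best


def compare_models(ols: OLSResult, gwr: GWRResult, w: SpatialWeights) -> pd.DataFrame:
    """OLS-vs-GWR diagnostics: AICc, adjusted R2 and residual Moran's I."""
    moran_o = global_morans_i(ols.residuals, w).I
    moran_g = global_morans_i(gwr.residuals, w).I
    return pd.DataFrame(
        [{
            "aicc_ols": ols.aicc, "aicc_gwr": gwr.aicc,
            "adj_r2_ols": ols.adj_r2, "adj_r2_gwr": gwr.adj_r2,
            "moran_ols": moran_o, "moran_gwr": moran_g,
        }]
    )
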