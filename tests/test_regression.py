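"""OLS / VIF / exploratory selection / GWR against closed forms, the
normal-equation oracle and statsmodels as an independent cross-check."""

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from vorscape import (
    RegressionDataset,
    build_zone_adjacency_weights,
    compare_models,
    exploratory_regression,
    gaussian_kernel_weights,
    gen_gwr_scenario,
    gen_zones,
    global_morans_i,
    gwr_fit,
    ols_fit,
    select_bandwidth,
    vif,
)


def random_dataset(rng, n=40, p=3):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p + 1)
    y = beta[0] + X @ beta[1:] + rng.normal(0, 0.5, n)
    coords = rng.uniform(0, 10, (n, 2))
    return RegressionDataset(y, X, coords)


class TestOls:
    def test_exact_line(self):
        x = np.linspace(0, 1, 10)
        y = 2 + 3 * x
        ds = RegressionDataset(y, x[:, None], np.column_stack([x, x * 0]))
        fit = ols_fit(ds)
        assert np.allclose(fit.beta, [2.0, 3.0], atol=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_orthogonal_regressor_zero_slope(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, -2.0, 2.0, 0.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0, 1.0, 1.0, -2.0])
        y = y - np.polyfit(x, y, 1)[0] * x  # force orthogonality
        coords = np.column_stack([np.arange(8.0), np.zeros(8)])
        fit = ols_fit(RegressionDataset(y, x[:, None], coords))
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-10)

    def test_eight_point_normal_equation_oracle(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 2.0],
                      [5.0, 5.0], [6.0, 3.0], [7.0, 6.0], [8.0, 4.0]])
        y = np.array([3.1, 3.9, 7.2, 7.8, 11.1, 11.9, 15.2, 15.8])
        coords = np.column_stack([np.arange(8.0), np.arange(8.0)])
        fit = ols_fit(RegressionDataset(y, X, coords))
        Xd = np.column_stack([np.ones(8), X])
        oracle = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert np.allclose(fit.beta, oracle, rtol=1e-8)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        ds = random_dataset(rng)
        fit = ols_fit(ds)
        sm_fit = sm.OLS(ds.y, sm.add_constant(ds.X)).fit()
        assert np.allclose(fit.beta, sm_fit.params, atol=1e-10)
        assert fit.r2 == pytest.approx(sm_fit.rsquared, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(sm_fit.rsquared_adj, abs=1e-10)
        assert np.allclose(fit.residuals, sm_fit.resid, atol=1e-10)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(1)
        ds = random_dataset(rng)
        fit = ols_fit(ds)
        assert np.abs(fit.residuals @ ds.X).max() < 1e-8

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=20)
        X = np.column_stack([x1, 2 * x1])
        y = rng.normal(size=20)
        ds = RegressionDataset.__new__(RegressionDataset)
        ds.y, ds.X, ds.coords, ds.names = y, X, rng.uniform(0, 1, (20, 2)), ["a", "b"]
        with pytest.raises(np.linalg.LinAlgError, match="b"):
            ols_fit(ds)


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = np.column_stack([np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n)])
        assert np.allclose(vif(X), 1.0, atol=1e-8)

    def test_duplicate_column_infinite(self):
        x = np.random.default_rng(0).normal(size=30)
        out = vif(np.column_stack([x, x]))
        assert np.isinf(out).all()

    def test_equicorrelated_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        n = 500
        z = rng.normal(size=n)
        X = np.column_stack([np.sqrt(0.5) * z + np.sqrt(0.5) * rng.normal(size=n)
                             for _ in range(3)])
        ours = vif(X)
        Xd = np.column_stack([np.ones(n), X])
        theirs = [variance_inflation_factor(Xd, j + 1) for j in range(3)]
        assert np.allclose(ours, theirs, rtol=1e-8)


class TestExploratory:
    def test_enumerates_all_subsets(self):
        rng = np.random.default_rng(0)
        cand = pd.DataFrame(rng.normal(size=(40, 7)), columns=list("abcdefg"))
        y = rng.normal(size=40)
        coords = rng.uniform(0, 1, (40, 2))
        table = exploratory_regression(cand, y, coords)
        assert len(table) == 127

    def test_planted_duplicate_never_passes(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(50, 3))
        cand = pd.DataFrame(np.column_stack([base, base[:, 0]]),
                            columns=["a", "b", "c", "a_dup"])
        y = rng.normal(size=50)
        table = exploratory_regression(cand, y, rng.uniform(0, 1, (50, 2)))
        both = table["variables"].str.contains("a_dup") & table["variables"].str.contains(r"\ba\b")
        assert not table.loc[both, "passed"].any()

    def test_recovers_true_pair(self):
        rng = np.random.default_rng(2)
        cand = pd.DataFrame(rng.normal(size=(100, 7)),
                            columns=[f"x{j}" for j in range(1, 8)])
        y = 1.0 + 2.0 * cand["x1"] + 1.5 * cand["x3"] + rng.normal(0, 0.5, 100)
        table = exploratory_regression(cand, y.to_numpy(), rng.uniform(0, 1, (100, 2)))
        top = table.loc[table["rank"] == 1, "variables"].iloc[0]
        assert "x1" in top and "x3" in top

    def test_ranking_is_descending_adj_r2(self):
        rng = np.random.default_rng(3)
        cand = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = cand["a"].to_numpy() + rng.normal(0, 1, 30)
        table = exploratory_regression(cand, y, rng.uniform(0, 1, (30, 2)))
        ranked = table[table["rank"].notna()].sort_values("rank")
        assert ranked["adj_r2"].is_monotonic_decreasing
        assert (ranked["max_vif"] < 7.5).all()


class TestKernel:
    def test_closed_forms(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
        w = gaussian_kernel_weights(coords, 0, bandwidth=5.0)
        assert w[0] == 1.0
        assert w[1] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_infinite_bandwidth_limit(self):
        coords = np.random.default_rng(0).uniform(0, 1, (10, 2))
        w = gaussian_kernel_weights(coords, 3, bandwidth=1e9)
        assert np.allclose(w, 1.0, atol=1e-12)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel_weights(np.zeros((3, 2)), 0, 0.0)


class TestGwr:
    def test_ols_limit(self, lattice_coords):
        sc = gen_gwr_scenario(lattice_coords,
                              [{"kind": "linear", "du": 0.05},
                               {"kind": "linear", "dv": 0.1},
                               {"kind": "constant", "value": 1.0}],
                              noise_sd=0.3, seed=4)
        ds = RegressionDataset(sc.y, sc.X, lattice_coords)
        ols = ols_fit(ds)
        diam = np.linalg.norm(lattice_coords.max(0) - lattice_coords.min(0))
        g = gwr_fit(ds, 1e6 * diam)
        assert np.abs(g.local_beta - ols.beta).max() < 1e-6
        assert g.aicc == pytest.approx(ols.aicc, rel=1e-6)

    def test_constant_truth_recovered_exactly(self, lattice_coords):
        sc = gen_gwr_scenario(lattice_coords,
                              [{"kind": "constant", "value": 1.0},
                               {"kind": "constant", "value": -2.0}],
                              noise_sd=0.0, seed=5)
        ds = RegressionDataset(sc.y, sc.X, lattice_coords)
        g = gwr_fit(ds, 5.0)
        assert np.allclose(g.local_beta, [1.0, -2.0], atol=1e-8)

    def test_varying_coefficient_recovery(self, lattice_coords):
        sc = gen_gwr_scenario(lattice_coords,
                              [{"kind": "constant", "value": 1.0},
                               {"kind": "linear", "du": 0.1},
                               {"kind": "constant", "value": -0.5}],
                              noise_sd=0.5, seed=7)
        ds = RegressionDataset(sc.y, sc.X, lattice_coords)
        bw = select_bandwidth(ds)
        g = gwr_fit(ds, bw)
        r = np.corrcoef(g.local_beta[:, 1], sc.beta_surfaces[:, 1])[0, 1]
        assert r > 0.9
        assert g.aicc < ols_fit(ds).aicc

    def test_hat_trace_bounds(self, lattice_coords):
        sc = gen_gwr_scenario(lattice_coords,
                              [{"kind": "constant", "value": 0.0},
                               {"kind": "linear", "du": 0.1}],
                              noise_sd=0.3, seed=8)
        ds = RegressionDataset(sc.y, sc.X, lattice_coords)
        for bw in (2.0, 5.0, 20.0):
            g = gwr_fit(ds, bw)
            assert ds.p + 1 - 1e-6 <= g.trace_s <= ds.n

    def test_duplicate_coordinates_jittered_with_warning(self):
        rng = np.random.default_rng(9)
        coords = np.repeat(rng.uniform(0, 1, (10, 2)), 2, axis=0)
        X = rng.normal(size=(20, 1))
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="jitter"):
            ds = RegressionDataset(y, X, coords)
        assert len(np.unique(ds.coords, axis=0)) == 20

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            RegressionDataset([1.0, np.nan, 2.0, 3.0, 4.0, 5.0],
                              np.zeros((6, 1)) + np.arange(6)[:, None],
                              np.random.default_rng(0).uniform(0, 1, (6, 2)))


class TestBandwidthSearch:
    def test_selected_bandwidth_beats_probe_grid(self, lattice_coords):
        sc = gen_gwr_scenario(lattice_coords,
                              [{"kind": "linear", "du": 0.1},
                               {"kind": "linear", "dv": -0.1}],
                              noise_sd=0.3, seed=10)
        ds = RegressionDataset(sc.y, sc.X, lattice_coords)
        bw, trace = select_bandwidth(ds, return_trace=True)
        best_aicc = gwr_fit(ds, bw).aicc
        diam = np.linalg.norm(lattice_coords.max(0) - lattice_coords.min(0))
        probes = np.geomspace(0.05 * diam, 2.0 * diam, 20)
        probe_aiccs = []
        for b in probes:
            try:
                probe_aiccs.append(gwr_fit(ds, b).aicc)
            except (np.linalg.LinAlgError, ValueError):
                probe_aiccs.append(np.inf)
        assert best_aicc <= min(probe_aiccs) + 1e-6

    def test_constant_coefficients_prefer_global_bandwidth(self):
        """Under spatially constant truth the global model wins: the median
        selected bandwidth over replicates sits in the upper search region.
        (Single replicates occasionally localize on chance structure — an
        inherent property of AICc bandwidth selection.)"""
        m = 8
        idx = np.arange(m * m)
        coords = np.column_stack([idx % m + 0.5, idx // m + 0.5]).astype(float)
        diam = np.linalg.norm(coords.max(0) - coords.min(0))
        specs = [{"kind": "constant", "value": v} for v in (1.0, 2.0, -1.0)]
        bws = []
        for seed in range(5):
            sc = gen_gwr_scenario(coords, specs, noise_sd=0.5, seed=seed)
            bws.append(select_bandwidth(RegressionDataset(sc.y, sc.X, coords)))
        assert np.median(bws) >= 0.5 * 2.0 * diam

    def test_varying_coefficients_select_smaller_bandwidth(self, lattice_coords):
        const = gen_gwr_scenario(lattice_coords,
                                 [{"kind": "constant", "value": 1.0},
                                  {"kind": "constant", "value": 1.0}],
                                 noise_sd=0.5, seed=12)
        vary = gen_gwr_scenario(lattice_coords,
                                [{"kind": "constant", "value": 1.0},
                                 {"kind": "linear", "du": 0.3}],
                                noise_sd=0.5, seed=12)
        bw_c = select_bandwidth(RegressionDataset(const.y, const.X, lattice_coords))
        bw_v = select_bandwidth(RegressionDataset(vary.y, vary.X, lattice_coords))
        assert bw_v < bw_c


class TestCompareModels:
    @staticmethod
    def _zone_weights(n_side, n_zones, seed):
        zm = gen_zones(n_side, n_side, n_zones, seed=seed)
        return build_zone_adjacency_weights(zm.zone_ids)

    def test_identical_models_agree(self, lattice_coords):
        sc = gen_gwr_scenario(lattice_coords,
                              [{"kind": "constant", "value": 1.0},
                               {"kind": "constant", "value": 0.5}],
                              noise_sd=0.3, seed=13)
        ds = RegressionDataset(sc.y, sc.X, lattice_coords)
        ols = ols_fit(ds)
        diam = np.linalg.norm(lattice_coords.max(0) - lattice_coords.min(0))
        g = gwr_fit(ds, 1e6 * diam)
        # grid-cell adjacency weights for the 400 lattice points
        from vorscape import build_contiguity_weights
        w = build_contiguity_weights(20, 20, "queen", True)
        diag = compare_models(ols, g, w)
        r = diag.iloc[0]
        assert r["aicc_ols"] == pytest.approx(r["aicc_gwr"], rel=1e-6)
        assert r["adj_r2_ols"] == pytest.approx(r["adj_r2_gwr"], abs=1e-6)
        assert r["moran_ols"] == pytest.approx(r["moran_gwr"], abs=1e-6)

    def test_spatial_scenario_direction(self, lattice_coords):
        """GWR should absorb spatial structure: lower AICc and residual
        autocorrelation no worse than OLS."""
        sc = gen_gwr_scenario(lattice_coords,
                              [{"kind": "linear", "du": 0.2},
                               {"kind": "linear", "du": 0.1},
                               {"kind": "constant", "value": -0.5}],
                              noise_sd=0.5, seed=14)
        ds = RegressionDataset(sc.y, sc.X, lattice_coords)
        ols = ols_fit(ds)
        g = gwr_fit(ds, select_bandwidth(ds))
        from vorscape import build_contiguity_weights
        w = build_contiguity_weights(20, 20, "queen", True)
        diag = compare_models(ols, g, w).iloc[0]
        assert diag["aicc_gwr"] < diag["aicc_ols"]
        assert diag["moran_gwr"] <= diag["moran_ols"]

    def test_white_noise_residual_moran_near_null(self):
        rng = np.random.default_rng(15)
        from vorscape import build_contiguity_weights
        w = build_contiguity_weights(10, 10, "queen", True)
        resid = rng.normal(size=100)
        I = global_morans_i(resid, w).I
        assert abs(I - (-1 / 99)) < 0.1
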