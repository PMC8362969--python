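"""OLS/GWR/GTWR estimators: kernels, local solves, bandwidth selection."""

import math

import numpy as np
import pandas as pd
import pytest

import gtwrkit as g
from gtwrkit.models import _golden_section
from tests.conftest import constant_surfaces


def brute_force_local_beta(panel, spec):
    """Independent dense per-point weighted solve (explicit W matrix)."""
    X, y = panel.design, panel.y
    uvt = np.column_stack([panel.coords, panel.times])
    betas = np.empty((panel.n, X.shape[1]))
    for i in range(panel.n):
        d2 = ((uvt[:, :2] - uvt[i, :2]) ** 2).sum(1) + spec.tau * (
            uvt[:, 2] - uvt[i, 2]
        ) ** 2
        W = np.diag(np.exp(-d2 / spec.spatial_bandwidth**2))
        betas[i] = np.linalg.inv(X.T @ W @ X) @ (X.T @ W @ y)
    return betas


def independent_gwr(panel, h):
    """Separately coded cross-sectional GWR via sqrt-weighted lstsq."""
    X, y = panel.design, panel.y
    coords = panel.coords
    betas = np.empty((panel.n, X.shape[1]))
    for i in range(panel.n):
        d2 = ((coords - coords[i]) ** 2).sum(1)
        sw = np.sqrt(np.exp(-d2 / h**2))
        betas[i], *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return betas


class TestKernelPrimitives:
    @pytest.mark.parametrize(
        "a,b,tau,expected",
        [
            ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 5.0, 0.0),
            ((0.0, 0.0, 0.0), (3.0, 4.0, 0.0), 7.0, 25.0),
            ((0.0, 0.0, 0.0), (0.0, 0.0, 2.0), 4.0, 16.0),
        ],
    )
    def test_squared_distance(self, a, b, tau, expected):
        assert g.squared_st_distance(a, b, tau) == pytest.approx(expected)
        assert g.squared_st_distance(b, a, tau) == pytest.approx(expected)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            g.squared_st_distance((0, 0, 0), (1, 1, 1), -1.0)

    def test_weight_at_zero_distance(self):
        assert g.kernel_weight(0.0, 2.0) == 1.0

    def test_weight_at_bandwidth(self):
        assert g.kernel_weight(4.0, 2.0) == pytest.approx(math.exp(-1))

    def test_exponential_identity(self):
        h = 3.0
        assert g.kernel_weight(4 * h**2, h) == pytest.approx(
            g.kernel_weight(h**2, h) ** 4, abs=1e-12
        )

    def test_strictly_decreasing(self):
        w = g.kernel_weight(np.linspace(0, 100, 50), 5.0)
        assert np.all(np.diff(w) < 0)

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            g.kernel_weight(1.0, 0.0)


class TestAicc:
    def test_direct_formula_evaluation(self):
        n, rss, tr = 100, 50.0, 10.0
        expected = (
            n * math.log(rss / n)
            + n * math.log(2 * math.pi)
            + n * (n + tr) / (n - 2 - tr)
        )
        assert g.aicc(n, rss, tr) == pytest.approx(expected)

    def test_penalty_increases_with_effective_parameters(self):
        values = [g.aicc(100, 50.0, tr) for tr in (5.0, 10.0, 20.0, 40.0)]
        assert np.all(np.diff(values) > 0)

    def test_overfit_rejected(self):
        with pytest.raises(ValueError):
            g.aicc(10, 1.0, 9.0)


class TestOls:
    def test_exact_line_recovery(self):
        frame = pd.DataFrame(
            {
                "unit_id": [f"u{i}" for i in range(10)],
                "u": np.arange(10.0),
                "v": np.zeros(10),
                "t": np.zeros(10, dtype=int),
                "x": np.arange(10.0),
            }
        )
        frame["response"] = 1.0 + 2.0 * frame.x
        panel = g.PanelDataset(frame, ("x",))
        fit = g.fit_ols(panel)
        assert fit.coefficients[0] == pytest.approx([1.0, 2.0], abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_null_response_gives_near_zero_r2(self):
        rng = np.random.default_rng(0)
        cfg = g.SyntheticConfig(n_units=129, n_months=36, seed=0)
        panel, _ = g.generate_panel(cfg)
        shuffled = panel.frame.copy()
        shuffled["response"] = rng.permutation(shuffled["response"].to_numpy())
        fit = g.fit_ols(g.PanelDataset(shuffled, panel.covariate_names))
        assert fit.r2 < 0.05

    def test_rank_deficient_design_names_columns(self):
        frame = pd.DataFrame(
            {
                "unit_id": [f"u{i}" for i in range(20)],
                "u": np.arange(20.0),
                "v": np.zeros(20),
                "t": np.zeros(20, dtype=int),
                "x1": np.arange(20.0),
            }
        )
        frame["x2"] = 2.0 * frame.x1
        frame["response"] = frame.x1
        panel = g.PanelDataset(frame, ("x1", "x2"))
        with pytest.raises(ValueError, match="x2"):
            g.fit_ols(panel)


class TestGtwr:
    def test_matches_brute_force_oracle(self, toy_panel):
        spec = g.KernelSpec(5.0, 2.0)
        fit = g.fit_gtwr(toy_panel, spec)
        expected = brute_force_local_beta(toy_panel, spec)
        assert np.max(np.abs(fit.coefficients - expected)) < 1e-10

    def test_flat_kernel_limit_equals_ols(self, toy_panel):
        h = 1e6 * toy_panel.domain_diameter()
        fit = g.fit_gtwr(toy_panel, g.KernelSpec(h, 0.0))
        ols = g.fit_ols(toy_panel)
        assert np.max(np.abs(fit.coefficients - ols.coefficients[0])) < 1e-6

    def test_tau_zero_single_slice_equals_independent_gwr(self, toy_panel):
        sliced = toy_panel.time_slice(0)
        fit = g.fit_gtwr(sliced, g.KernelSpec(5.0, 0.0))
        expected = independent_gwr(sliced, 5.0)
        assert np.max(np.abs(fit.coefficients - expected)) < 1e-10

    def test_weighted_residual_orthogonality(self, toy_panel):
        spec = g.KernelSpec(5.0, 1.0)
        fit = g.fit_gtwr(toy_panel, spec)
        X, y = toy_panel.design, toy_panel.y
        uvt = np.column_stack([toy_panel.coords, toy_panel.times])
        for i in range(0, toy_panel.n, 3):
            d2 = ((uvt[:, :2] - uvt[i, :2]) ** 2).sum(1) + spec.tau * (
                uvt[:, 2] - uvt[i, 2]
            ) ** 2
            w = np.exp(-d2 / spec.spatial_bandwidth**2)
            resid_local = y - X @ fit.coefficients[i]
            assert np.max(np.abs(X.T @ (w * resid_local))) < 1e-8

    def test_translation_invariance(self, toy_panel):
        spec = g.KernelSpec(5.0, 1.0)
        base = g.fit_gtwr(toy_panel, spec)
        shifted = toy_panel.frame.copy()
        shifted["u"] += 1e4
        shifted["v"] -= 5e3
        shifted["t"] += 7
        moved = g.PanelDataset(shifted, toy_panel.covariate_names)
        fit = g.fit_gtwr(moved, spec)
        assert np.allclose(fit.fitted, base.fitted, atol=1e-8)

    def test_coordinate_scaling_invariance(self, toy_panel):
        base = g.fit_gtwr(toy_panel, g.KernelSpec(5.0, 0.0))
        c = 37.5
        scaled_frame = toy_panel.frame.copy()
        scaled_frame["u"] *= c
        scaled_frame["v"] *= c
        scaled = g.PanelDataset(scaled_frame, toy_panel.covariate_names)
        fit = g.fit_gtwr(scaled, g.KernelSpec(5.0 * c, 0.0))
        assert np.allclose(fit.coefficients, base.coefficients, atol=1e-8)

    def test_hat_trace_decreases_with_bandwidth(self, toy_panel):
        traces = [
            g.fit_gtwr(toy_panel, g.KernelSpec(h, 0.0)).trace_s
            for h in (2.0, 4.0, 8.0, 16.0, 32.0)
        ]
        assert np.all(np.diff(traces) < 0)

    def test_gwr_is_gtwr_with_tau_zero(self, toy_panel):
        sliced = toy_panel.time_slice(1)
        a = g.fit_gwr(sliced, 4.0)
        b = g.fit_gtwr(sliced, g.KernelSpec(4.0, 0.0))
        assert np.array_equal(a.coefficients, b.coefficients)

    def test_two_clusters_with_different_truth(self):
        # local fits should track each cluster's coefficient better than
        # the pooled global estimate
        rng = np.random.default_rng(8)
        n_per = 40
        coords = np.vstack(
            [
                rng.uniform(0, 10, size=(n_per, 2)),
                rng.uniform(100, 110, size=(n_per, 2)),
            ]
        )
        x = rng.normal(0, 1, 2 * n_per)
        beta_true = np.r_[np.full(n_per, 1.0), np.full(n_per, 3.0)]
        y = beta_true * x + rng.normal(0, 0.1, 2 * n_per)
        frame = pd.DataFrame(
            {
                "unit_id": [f"u{i}" for i in range(2 * n_per)],
                "u": coords[:, 0],
                "v": coords[:, 1],
                "t": np.zeros(2 * n_per, dtype=int),
                "x": x,
                "response": y,
            }
        )
        panel = g.PanelDataset(frame, ("x",))
        local = g.fit_gwr(panel, h=10.0)
        ols = g.fit_ols(panel)
        j = local.coefficient_names.index("x")
        err_local = np.abs(local.coefficients[:, j] - beta_true).mean()
        err_ols = np.abs(ols.coefficients[0, j] - beta_true).mean()
        assert err_local < err_ols


class TestCvAndBandwidth:
    def test_noise_free_smooth_data_cv_near_zero(self):
        cfg = g.SyntheticConfig(
            n_units=20,
            n_months=6,
            n_stations=4,
            noise_sd=0.0,
            coefficient_surfaces=constant_surfaces(),
            seed=6,
        )
        panel, _ = g.generate_panel(cfg)
        h = 10 * panel.domain_diameter()
        cv = g.cv_score(panel, g.KernelSpec(h, 0.0))
        assert cv < 1e-6 * float(panel.y @ panel.y)

    def test_tiny_bandwidth_much_worse_than_moderate(self, toy_panel):
        cv_tiny = g.cv_score(toy_panel, g.KernelSpec(0.05, 0.0))
        cv_good = g.cv_score(toy_panel, g.KernelSpec(8.0, 0.0))
        assert cv_tiny > 5 * cv_good

    def test_selection_is_deterministic(self, toy_panel):
        kwargs = dict(
            model="gtwr", tau_grid=[0.0, 1.0], h_grid=[2.0, 5.0, 10.0]
        )
        a = g.select_bandwidth(toy_panel, **kwargs)
        b = g.select_bandwidth(toy_panel, **kwargs)
        assert (a.spatial_bandwidth, a.tau) == (b.spatial_bandwidth, b.tau)

    def test_constant_beta_prefers_flat_kernel(self):
        # with spatially constant coefficients the CV curve flattens out:
        # the selected bandwidth is far above the nearest-neighbour spacing
        # and the upper search bound does essentially as well
        cfg = g.SyntheticConfig(
            n_units=30,
            n_months=12,
            n_stations=5,
            noise_sd=0.3,
            coefficient_surfaces=constant_surfaces(),
            seed=3,
        )
        panel, _ = g.generate_panel(cfg)
        grid = list(np.geomspace(panel.nn_spacing(), panel.domain_diameter(), 6))
        spec = g.select_bandwidth(panel, "gtwr", tau_grid=[0.0], h_grid=grid)
        assert spec.spatial_bandwidth >= 3 * panel.nn_spacing()
        cv_top = g.cv_score(panel, g.KernelSpec(grid[-1], 0.0))
        cv_sel = g.cv_score(panel, spec)
        assert cv_top <= 1.05 * cv_sel

    def test_temporal_beta_selects_positive_tau(self):
        surfaces = (
            g.CoefficientSurface("intercept", base=1.0),
            g.CoefficientSurface("aqi", base=0.5, amp=0.3),
            g.CoefficientSurface("unemployment", base=0.03),
            g.CoefficientSurface("income", base=-0.0003),
        )
        cfg = g.SyntheticConfig(
            n_units=30,
            n_months=12,
            n_stations=5,
            noise_sd=0.3,
            coefficient_surfaces=surfaces,
            seed=3,
        )
        panel, _ = g.generate_panel(cfg)
        grid = list(np.geomspace(panel.nn_spacing(), panel.domain_diameter(), 5))
        spec = g.select_bandwidth(
            panel, "gtwr", tau_grid=[0.0, 1e8, 1e9, 1e10], h_grid=grid
        )
        assert spec.tau > 0.0

    def test_monotone_cv_warns_at_boundary(self):
        with pytest.warns(UserWarning, match="monotone"):
            x, fx = _golden_section(lambda h: h, 1.0, 2.0)
        assert x == 1.0


class TestPanelValidation:
    def test_duplicate_unit_month_rejected(self, toy_panel):
        bad = pd.concat([toy_panel.frame, toy_panel.frame.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            g.PanelDataset(bad, toy_panel.covariate_names)

    def test_moving_unit_rejected(self, toy_panel):
        bad = toy_panel.frame.copy()
        bad.loc[bad.index[1], "u"] += 1.0
        with pytest.raises(ValueError, match="constant within"):
            g.PanelDataset(bad, toy_panel.covariate_names)

    def test_missing_values_rejected(self, toy_panel):
        bad = toy_panel.frame.copy()
        bad.loc[bad.index[0], "x1"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            g.PanelDataset(bad, toy_panel.covariate_names)

    def test_csv_roundtrip(self, toy_panel, tmp_path):
        path = tmp_path / "panel.csv"
        toy_panel.to_csv(path)
        back = g.PanelDataset.from_csv(path, toy_panel.covariate_names)
        assert np.allclose(back.y, toy_panel.y)
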