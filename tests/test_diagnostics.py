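"""VIF, Moran's I and the local-coefficient nonstationarity screen."""

import numpy as np
import pytest

import gtwrkit as g
from gtwrkit.diagnostics import knn_weights, moran_by_month, morans_i, vif
from tests.conftest import constant_surfaces


def rook_weights(side: int) -> np.ndarray:
    """Row-standardised rook adjacency on a side x side grid."""
    n = side * side
    W = np.zeros((n, n))
    for i in range(side):
        for j in range(side):
            a = i * side + j
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < side and 0 <= nj < side:
                    W[a, ni * side + nj] = 1.0
    return W / W.sum(axis=1, keepdims=True)


class TestVif:
    def test_orthogonal_covariates_have_unit_vif(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(100, 3))
        q, _ = np.linalg.qr(raw - raw.mean(0))
        out = vif(q, names=["a", "b", "c"])
        assert np.allclose(out.to_numpy(), 1.0, atol=1e-8)

    def test_correlated_pair_closed_form(self):
        # exact sample correlation 0.9 by construction
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(200, 2))
        q, _ = np.linalg.qr(raw - raw.mean(0))
        z1, z2 = q[:, 0], q[:, 1]
        x1 = z1
        x2 = 0.9 * z1 + np.sqrt(1 - 0.81) * z2
        out = vif(np.column_stack([x1, x2]))
        expected = 1.0 / (1.0 - 0.81)
        assert out.iloc[0] == pytest.approx(expected, abs=1e-6)
        assert out.iloc[1] == pytest.approx(5.263, abs=1e-3)
        assert (out > 5.0).all()

    def test_duplicated_column_flagged_infinite(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        out = vif(np.column_stack([x, x, rng.normal(size=100)]))
        assert np.isinf(out.iloc[0]) and np.isinf(out.iloc[1])

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(150, 3))
        X[:, 1] += 0.7 * X[:, 0]
        base = vif(X).to_numpy()
        rescaled = vif(X * np.array([2.0, -0.5, 1000.0]) + np.array([5, -3, 100]))
        assert np.allclose(rescaled.to_numpy(), base, rtol=1e-8)

    def test_single_covariate_rejected(self):
        with pytest.raises(ValueError):
            vif(np.random.default_rng(0).normal(size=(50, 1)))


class TestMoransI:
    def test_expected_value_closed_form(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 100, size=(129, 2))
        W = knn_weights(coords, k=8)
        res = morans_i(rng.standard_normal(129), W, n_perm=49, seed=0)
        assert res.expected_I == -1.0 / 128
        assert res.expected_I == pytest.approx(-0.0078125)

    def test_checkerboard_strongly_negative(self):
        side = 6
        values = np.array(
            [1.0 if (i + j) % 2 == 0 else -1.0 for i in range(side) for j in range(side)]
        )
        res = morans_i(values, rook_weights(side), n_perm=99, seed=0)
        assert res.I < -0.5
        assert not res.clustered

    def test_smooth_gradient_clusters(self):
        side = 6
        values = np.array([float(i) for i in range(side) for _ in range(side)])
        values += np.random.default_rng(1).normal(0, 0.1, side * side)
        res = morans_i(values, rook_weights(side), n_perm=999, seed=0)
        assert res.I > 0
        assert res.p_value < 0.05
        assert res.clustered

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            morans_i(np.ones(36), rook_weights(6), n_perm=9)

    def test_permutation_rejection_rate_calibrated(self):
        # under iid noise a 5% one-sided test should reject about 5% of
        # the time
        side = 6
        W = rook_weights(side)
        rejections = 0
        trials = 200
        for s in range(trials):
            rng = np.random.default_rng(s)
            res = morans_i(rng.standard_normal(side * side), W, n_perm=199, seed=s)
            rejections += res.p_value < 0.05
        assert rejections / trials == pytest.approx(0.05, abs=0.04)


@pytest.fixture(scope="module")
def fits():
    cfg = g.SyntheticConfig(
        n_units=25,
        n_months=6,
        n_stations=5,
        noise_sd=0.2,
        coefficient_surfaces=constant_surfaces(),
        seed=10,
    )
    panel, _ = g.generate_panel(cfg)
    h = 5 * panel.domain_diameter()
    gtwr = g.fit_gtwr(panel, g.KernelSpec(h, 0.0))
    gwr_slices = [g.fit_gwr(panel.time_slice(t), h) for t in range(6)]
    ols = g.fit_ols(panel)
    return panel, gtwr, gwr_slices, ols


class TestNonstationarityTable:
    def test_constant_truth_large_bandwidth_homogeneous(self, fits):
        _, gtwr, gwr_slices, ols = fits
        table = g.nonstationarity_table(gtwr, gwr_slices, ols)
        aqi = table[table.variable == "aqi"].iloc[0]
        assert aqi.iqr_gtwr < aqi.twice_se_ols
        assert not aqi.heterogeneous

    def test_strong_spatial_variation_flagged(self):
        surfaces = (
            g.CoefficientSurface("intercept", base=1.0),
            g.CoefficientSurface("aqi", base=0.5, gu=2.0),
            g.CoefficientSurface("unemployment", base=0.03),
            g.CoefficientSurface("income", base=-0.0003),
        )
        cfg = g.SyntheticConfig(
            n_units=30,
            n_months=6,
            n_stations=5,
            noise_sd=0.2,
            coefficient_surfaces=surfaces,
            seed=11,
        )
        panel, _ = g.generate_panel(cfg)
        h = panel.domain_diameter() / 6
        gtwr = g.fit_gtwr(panel, g.KernelSpec(h, 0.0))
        gwr_slices = [g.fit_gwr(panel.time_slice(t), h) for t in range(6)]
        ols = g.fit_ols(panel)
        table = g.nonstationarity_table(gtwr, gwr_slices, ols)
        aqi = table[table.variable == "aqi"].iloc[0]
        assert aqi.heterogeneous
        assert aqi.iqr_gtwr > aqi.twice_se_ols

    def test_iqr_uses_linear_interpolation_quartiles(self):
        # {1..5}: Q1 = 2, Q3 = 4 under the type-7 convention
        assert np.percentile([1, 2, 3, 4, 5], 75) - np.percentile(
            [1, 2, 3, 4, 5], 25
        ) == pytest.approx(2.0)
        from gtwrkit.diagnostics import _iqr

        assert _iqr(np.array([1.0, 2.0, 3.0, 4.0, 5.0])) == pytest.approx(2.0)

    def test_record_order_permutation_invariant(self, fits):
        panel, gtwr, gwr_slices, ols = fits
        table = g.nonstationarity_table(gtwr, gwr_slices, ols)
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n)
        shuffled = g.LocalFitResult(
            model=gtwr.model,
            coefficient_names=gtwr.coefficient_names,
            coefficients=gtwr.coefficients[perm],
            fitted=gtwr.fitted[perm],
            residuals=gtwr.residuals[perm],
            hat=gtwr.hat[perm],
            r2=gtwr.r2,
            trace_s=gtwr.trace_s,
            aicc=gtwr.aicc,
        )
        table2 = g.nonstationarity_table(shuffled, gwr_slices, ols)
        assert np.allclose(table.iqr_gtwr, table2.iqr_gtwr)

    def test_mismatched_covariates_rejected(self, fits, toy_panel):
        _, gtwr, gwr_slices, _ = fits
        other_ols = g.fit_ols(toy_panel)
        with pytest.raises(ValueError, match="covariate"):
            g.nonstationarity_table(gtwr, gwr_slices, other_ols)


def test_moran_by_month_on_clustered_residuals(small_panel):
    panel, _ = small_panel
    ols = g.fit_ols(panel)
    report = moran_by_month(panel.frame, ols.residuals, k=6, n_perm=99, seed=0)
    assert len(report) == panel.frame["t"].nunique()
    assert report["p_value"].between(0, 1).all()
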