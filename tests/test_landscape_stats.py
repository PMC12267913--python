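import numpy as np
import pandas as pd
import pytest
from scipy import stats

from canopyflux.landscape_stats import (
    LOSS_LOG_OFFSET,
    anova_by_type,
    empirical_semivariogram,
    fit_multiple,
    fit_univariate,
    prepare_response,
    residual_range,
    spatial_loo_cv,
)
from canopyflux.synthetic_landscape import correlated_field


def cell_grid(n_side=20, cell=100.0):
    rr, cc = np.mgrid[0:n_side, 0:n_side]
    return pd.DataFrame({"x": (cc.ravel() + 0.5) * cell, "y": (rr.ravel() + 0.5) * cell})


def grf_on_cells(n_side, range_m, rng, cell=100.0):
    return correlated_field((n_side, n_side), range_m, cell, rng).ravel()


class TestAnova:
    def test_identical_groups_f_near_zero(self):
        base = np.tile(np.arange(20, dtype=float), 2)
        rec = pd.DataFrame({"y": np.concatenate([base, base]),
                            "forest_type": ["a"] * 40 + ["b"] * 40})
        out = anova_by_type(rec, "y")
        assert out["F"] == pytest.approx(0.0, abs=1e-10)

    def test_separated_groups_all_pairwise_significant(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame({
            "y": np.concatenate([rng.normal(m, 1.0, 30) for m in (10, 20, 30)]),
            "forest_type": np.repeat(["a", "b", "c"], 30),
        })
        out = anova_by_type(rec, "y")
        assert out["p"] < 1e-10
        assert out["pairwise"]["reject"].all()

    def test_degenerate_groups_rejected(self):
        rec = pd.DataFrame({"y": [1.0, 2.0, 3.0], "forest_type": ["a", "a", "b"]})
        with pytest.raises(ValueError, match="groups"):
            anova_by_type(rec, "y")

    def test_loss_response_is_log_transformed(self):
        rec = pd.DataFrame({"losses_volume": [-5.0, 0.0, 10.0]})
        y = prepare_response(rec, "losses_volume")
        np.testing.assert_allclose(
            y, np.log(np.abs(rec.losses_volume.to_numpy()) + LOSS_LOG_OFFSET)
        )


class TestUnivariate:
    def test_near_noiseless_slope_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 100)
        rec = pd.DataFrame({"x": x, "y": 2.0 * x + rng.normal(0, 1e-8, 100),
                            "forest_type": ["a"] * 100})
        res = fit_univariate(rec, "y", "x")
        assert res.per_type.loc["a", "slope"] == pytest.approx(2.0, abs=1e-6)
        assert res.pooled_r == pytest.approx(1.0, abs=1e-6)

    def test_type_specific_slope_recovery(self):
        rng = np.random.default_rng(2)
        frames = []
        for t, slope in zip("abc", (1.0, 2.0, 3.0)):
            x = rng.uniform(0, 1, 200)
            frames.append(pd.DataFrame({
                "x": x, "y": slope * x + rng.normal(0, 0.1, 200), "forest_type": t}))
        res = fit_univariate(pd.concat(frames, ignore_index=True), "y", "x")
        for t, slope in zip("abc", (1.0, 2.0, 3.0)):
            est = res.per_type.loc[t, "slope"]
            se = res.per_type.loc[t, "slope_se"]
            assert abs(est - slope) < 3 * se

    def test_null_correlation_small(self):
        rng = np.random.default_rng(3)
        rec = pd.DataFrame({"x": rng.normal(size=500), "y": rng.normal(size=500),
                            "forest_type": ["a"] * 500})
        res = fit_univariate(rec, "y", "x")
        assert abs(res.pooled_r) < 0.1

    def test_tiny_type_gets_no_slope(self):
        rng = np.random.default_rng(4)
        rec = pd.DataFrame({
            "x": np.r_[rng.uniform(0, 1, 50), [0.5, 0.6]],
            "y": np.r_[rng.uniform(0, 1, 50), [0.5, 0.6]],
            "forest_type": ["a"] * 50 + ["b"] * 2,
        })
        res = fit_univariate(rec, "y", "x")
        assert "b" not in res.per_type.index
        assert "a" in res.per_type.index


class TestMultiple:
    def test_orthogonal_exact_recovery(self):
        n = 200
        x1 = np.tile([-1.0, 1.0], n // 2)
        x2 = np.repeat([-1.0, 1.0], n // 2)
        y = 3.0 + 2.0 * x1 - 1.5 * x2
        rec = pd.DataFrame({"x1": x1, "x2": x2, "resp": y})
        res = fit_multiple(rec, "resp", ["x1", "x2"])
        # coefficients are on the z-scale; x1/x2 have unit sd here
        assert res.coefficients.loc["x1", "coef"] == pytest.approx(2.0, abs=1e-8)
        assert res.coefficients.loc["x2", "coef"] == pytest.approx(-1.5, abs=1e-8)
        assert res.r2 == pytest.approx(1.0)

    def test_nested_r2_monotone(self):
        rng = np.random.default_rng(5)
        rec = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        rec["resp"] = rec.a + 0.5 * rec.b + rng.normal(0, 1, 300)
        full = fit_multiple(rec, "resp", ["a", "b", "c"])
        reduced = fit_multiple(rec, "resp", ["a"])
        assert full.r2 >= reduced.r2

    def test_row_order_invariance(self):
        rng = np.random.default_rng(6)
        rec = pd.DataFrame({"a": rng.normal(size=100)})
        rec["resp"] = 2 * rec.a + rng.normal(0, 0.5, 100)
        r1 = fit_multiple(rec, "resp", ["a"])
        r2 = fit_multiple(rec.sample(frac=1, random_state=0).reset_index(drop=True), "resp", ["a"])
        assert r1.r2 == pytest.approx(r2.r2)
        assert r1.coefficients.loc["a", "coef"] == pytest.approx(r2.coefficients.loc["a", "coef"])


class TestResidualRange:
    def _fit(self, rec):
        return fit_multiple(rec, "resp", ["x1"])

    def test_white_noise_reports_no_structure(self):
        rng = np.random.default_rng(7)
        rec = cell_grid(15)
        rec["x1"] = rng.normal(size=len(rec))
        rec["resp"] = rng.normal(size=len(rec))
        r = residual_range(rec, self._fit(rec))
        assert r <= 100.0  # at most one bin width

    def test_recovers_grf_range_within_30_percent(self):
        # field drawn from an exact spherical covariance with range 300 m
        rng = np.random.default_rng(8)
        rec = cell_grid(20)
        coords = rec[["x", "y"]].to_numpy()
        h = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        a = 300.0
        cov = np.where(h < a, 1 - 1.5 * h / a + 0.5 * (h / a) ** 3, 0.0)
        L = np.linalg.cholesky(cov + 1e-8 * np.eye(len(coords)))
        rec["x1"] = rng.normal(size=len(rec))
        rec["resp"] = L @ rng.normal(size=len(coords))
        r = residual_range(rec, self._fit(rec))
        assert 0.7 * 300 <= r <= 1.3 * 300

    def test_constant_residuals_zero_range(self):
        rec = cell_grid(10)
        rec["x1"] = np.zeros(len(rec))
        rec["resp"] = np.full(len(rec), 3.0)
        assert residual_range(rec, self._fit(rec)) == 0.0

    def test_too_few_records_rejected(self):
        rec = cell_grid(4)
        rec["x1"] = np.arange(16.0)
        rec["resp"] = np.arange(16.0)
        with pytest.raises(ValueError, match="30"):
            residual_range(rec, self._fit(rec))

    def test_semivariogram_sill_matches_variance(self):
        rng = np.random.default_rng(9)
        coords = cell_grid(12)[["x", "y"]].to_numpy()
        vals = rng.normal(size=len(coords))
        v = empirical_semivariogram(coords, vals, 100.0)
        assert v.gamma.iloc[-3:].mean() == pytest.approx(vals.var(), rel=0.35)


class TestSpatialCV:
    def test_zero_buffer_matches_naive_r2_on_strong_signal(self):
        rng = np.random.default_rng(10)
        rec = cell_grid(12)
        rec["x1"] = rng.uniform(0, 1, len(rec))
        rec["resp"] = 4.0 * rec.x1 + rng.normal(0, 0.05, len(rec))
        naive = fit_multiple(rec, "resp", ["x1"]).r2
        cv = spatial_loo_cv(rec, "resp", ["x1"], 0.0)
        assert cv.spatial_r2 == pytest.approx(naive, abs=0.02)

    def test_autocorrelated_null_optimism(self):
        # spatially structured predictors and response, no real relation:
        # naive LOO looks predictive, the buffered CV does not
        naive_r2, spatial_r2 = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rec = cell_grid(15)
            rec["x1"] = grf_on_cells(15, 400.0, rng)
            rec["resp"] = grf_on_cells(15, 400.0, rng)
            naive_r2.append(spatial_loo_cv(rec, "resp", ["x1"], 0.0).spatial_r2)
            spatial_r2.append(spatial_loo_cv(rec, "resp", ["x1"], 400.0).spatial_r2)
        assert np.mean(naive_r2) > np.mean(spatial_r2)

    def test_signal_fraction_recovered(self):
        rng = np.random.default_rng(11)
        rec = cell_grid(15)
        rec["x1"] = rng.uniform(-1, 1, len(rec))
        sigma = 0.5
        rec["resp"] = rec.x1 + rng.normal(0, sigma, len(rec))
        cv = spatial_loo_cv(rec, "resp", ["x1"], 0.0)
        frac = rec.x1.var() / (rec.x1.var() + sigma**2)
        assert cv.spatial_r2 == pytest.approx(frac, abs=0.07)

    def test_oversized_buffer_skips_cells(self):
        rng = np.random.default_rng(12)
        rec = cell_grid(4)
        rec["x1"] = rng.normal(size=len(rec))
        rec["resp"] = rng.normal(size=len(rec))
        with pytest.raises(ValueError, match="too few"):
            spatial_loo_cv(rec, "resp", ["x1"], 10_000.0)
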