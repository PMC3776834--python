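import numpy as np
import pandas as pd
import pytest

from nes_atlas.environment import (
    EnvLayerStack,
    compute_slope,
    extract_at_points,
    fit_aurelhy,
    fit_variogram,
    jackknife_compare,
    ordinary_kriging_weights,
    predict_at_stations,
    predict_aurelhy,
    thin_plate_spline_predict,
    topographic_pca,
)
from nes_atlas.grids import GridSpec, Raster
from nes_atlas.synthetic_data import gaussian_random_field_sampler


def _plane_dem(n=40, cell=1000.0, ax=0.1, ay=0.0, base=0.0):
    g = GridSpec(0.0, 0.0, cell, n, n)
    xs, ys = g.cell_centers()
    return Raster(base + ax * xs + ay * ys, g)


def _plane_stations(dem, n=30, seed=0):
    rng = np.random.default_rng(seed)
    g = dem.grid
    x = rng.uniform(g.x0, g.x0 + g.nx * g.cell * 0.999, n)
    y = rng.uniform(g.y0, g.y0 + g.ny * g.cell * 0.999, n)
    elev, _ = dem.sample(x, y)
    return pd.DataFrame({"x": x, "y": y, "elevation": elev, "rainfall": np.zeros(n)})


class TestSlope:
    def test_flat_dem_zero_slope(self):
        g = GridSpec(0, 0, 100.0, 10, 10)
        slope = compute_slope(Raster(np.full(g.shape, 42.0), g))
        np.testing.assert_allclose(slope.values, 0.0, atol=1e-12)

    def test_inclined_plane_closed_form(self):
        dem = _plane_dem(ax=0.1)  # rises 100 m per 1000 m
        slope = compute_slope(dem)
        np.testing.assert_allclose(slope.values, np.degrees(np.arctan(0.1)), rtol=1e-6)

    def test_invariant_to_constant_offset(self):
        dem = _plane_dem(ax=0.05, ay=0.02)
        lifted = Raster(dem.values + 500.0, dem.grid)
        np.testing.assert_allclose(compute_slope(dem).values, compute_slope(lifted).values)

    def test_non_finite_elevation_rejected(self):
        g = GridSpec(0, 0, 100.0, 5, 5)
        vals = np.zeros(g.shape)
        vals[2, 2] = np.nan
        with pytest.raises(ValueError):
            compute_slope(Raster(vals, g))


class TestTopographicPca:
    def test_inclined_plane_first_component_dominates(self):
        scores, model = topographic_pca(_plane_dem(ax=0.1), scales=(1, 2))
        assert model.explained_variance_ratio_[0] >= 0.99

    def test_constant_dem_rejected(self):
        g = GridSpec(0, 0, 100.0, 20, 20)
        with pytest.raises(ValueError, match="zero variance"):
            topographic_pca(Raster(np.full(g.shape, 7.0), g))

    def test_duplicated_scale_gives_identical_paired_loadings(self):
        rng = np.random.default_rng(3)
        g = GridSpec(0, 0, 1000.0, 25, 25)
        dem = Raster(rng.normal(500, 100, g.shape), g)
        _, model = topographic_pca(dem, scales=(2, 2), kept_variance=0.99)
        n = model.components_.shape[1] // 2
        np.testing.assert_allclose(model.components_[:, :n], model.components_[:, n:], atol=1e-8)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(4)
        g = GridSpec(0, 0, 1000.0, 15, 15)
        dem = Raster(rng.normal(500, 100, g.shape), g)
        from nes_atlas.environment import _topo_features

        feats = _topo_features(dem.values, (1,))
        from sklearn.decomposition import PCA

        pca = PCA()
        scores = pca.fit_transform(feats)
        back = scores @ pca.components_ + pca.mean_
        np.testing.assert_allclose(back, feats, atol=1e-8)


class TestVariogramAndKriging:
    def test_kriging_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        st = rng.uniform(0, 50000, size=(25, 2))
        tg = rng.uniform(0, 50000, size=(40, 2))
        w = ordinary_kriging_weights(st, tg, (50.0, 2000.0, 15000.0))
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-8)

    def test_range_recovered_from_known_field(self):
        """Median fitted range over 20 seeds within 50% of the true 30 km."""
        fitted = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            f = gaussian_random_field_sampler(rng, 150.0, 30000.0)
            xy = rng.uniform(0, 100000, size=(100, 2))
            _, _, a = fit_variogram(xy, f(xy[:, 0], xy[:, 1]), nugget=0.0)
            fitted.append(a)
        assert abs(np.median(fitted) - 30000.0) / 30000.0 < 0.5


class TestAurelhy:
    def test_noiseless_linear_field_fits_exactly(self):
        dem = _plane_dem(ax=0.08, ay=0.03, base=100.0)
        st = _plane_stations(dem)
        st["rainfall"] = 900.0 + 1.4 * st["elevation"]
        model = fit_aurelhy(st, dem, scales=(1, 2), kept_variance=0.999)
        assert float(np.abs(model.station_residuals).max()) < 1e-6
        nugget, psill, _ = model.variogram
        assert nugget + psill < 1e-6

    def test_exact_interpolation_at_stations_with_zero_nugget(self, world):
        _, topo = topographic_pca(world.dem)
        model = fit_aurelhy(world.stations, world.dem, topo=topo, nugget=0.0)
        pred = predict_at_stations(model, world.dem, world.stations[["x", "y"]].to_numpy())
        obs = world.stations["rainfall"].to_numpy()
        assert np.max(np.abs(pred - obs) / np.abs(obs)) < 1e-6

    def test_constant_rainfall_gives_flat_surface(self):
        dem = _plane_dem(ax=0.05)
        st = _plane_stations(dem)
        st["rainfall"] = 1200.0
        model = fit_aurelhy(st, dem, scales=(1,), kept_variance=0.999)
        surf, frac = predict_aurelhy(model, dem)
        np.testing.assert_allclose(surf.values, 1200.0, rtol=1e-6)

    def test_overshoot_truncated_at_ceiling(self):
        dem = _plane_dem(ax=0.2, base=0.0)
        st = _plane_stations(dem)
        st["rainfall"] = 1000.0 + 1.0 * st["elevation"]  # up to ~9000 mm
        model = fit_aurelhy(st, dem, scales=(1,), kept_variance=0.999, ceiling_mm=4900.0)
        surf, frac = predict_aurelhy(model, dem)
        assert surf.values.max() == 4900.0
        assert frac > 0

    def test_zero_variogram_residuals_reduce_to_regression_surface(self):
        dem = _plane_dem(ax=0.06)
        st = _plane_stations(dem)
        st["rainfall"] = 800.0 + 2.0 * st["elevation"]
        model = fit_aurelhy(st, dem, scales=(1,), kept_variance=0.999, ceiling_mm=1e9)
        surf, _ = predict_aurelhy(model, dem)
        xs, ys = dem.grid.cell_centers()
        xy = np.column_stack([xs.ravel(), ys.ravel()])
        pcs = model.topo.scores_at(dem, xy[:, 0], xy[:, 1])
        trend = model.trend(xy, pcs).reshape(dem.grid.shape)
        np.testing.assert_allclose(surf.values, trend, rtol=1e-5)

    def test_refit_on_predictions_reproduces_coefficients(self):
        dem = _plane_dem(ax=0.08)
        st = _plane_stations(dem)
        st["rainfall"] = 900.0 + 1.4 * st["elevation"]
        model = fit_aurelhy(st, dem, scales=(1,), kept_variance=0.999, ceiling_mm=1e9)
        st2 = st.copy()
        st2["rainfall"] = predict_at_stations(model, dem, st[["x", "y"]].to_numpy())
        model2 = fit_aurelhy(st2, dem, topo=model.topo)
        np.testing.assert_allclose(model2.coef_, model.coef_, atol=1e-6)


class TestJackknife:
    def test_noiseless_linear_field_both_methods_near_exact(self):
        dem = _plane_dem(ax=0.08)
        st = _plane_stations(dem, n=25)
        st["rainfall"] = 700.0 + 1.1 * st["elevation"]
        out = jackknife_compare(st, dem, scales=(1,), kept_variance=0.999)
        rng_field = st["rainfall"].max() - st["rainfall"].min()
        assert (out["rmse"] < 0.01 * rng_field).all()

    def test_single_method_one_row(self):
        dem = _plane_dem()
        st = _plane_stations(dem, n=15)
        st["rainfall"] = 1000.0
        out = jackknife_compare(st, dem, methods=("thin_plate_spline",))
        assert len(out) == 1 and out.loc[0, "method"] == "thin_plate_spline"

    def test_unknown_method_rejected(self):
        dem = _plane_dem()
        st = _plane_stations(dem, n=15)
        with pytest.raises(ValueError, match="unknown method"):
            jackknife_compare(st, dem, methods=("idw",))


class TestExtractAtPoints:
    def _stack(self):
        g = GridSpec(0, 0, 1000.0, 10, 10)
        xs, ys = g.cell_centers()
        mk = lambda v: Raster(v, g)
        return EnvLayerStack(
            mk(xs * 0.001), mk(np.full(g.shape, 5.0)), mk(np.full(g.shape, 2000.0)),
            mk(np.full(g.shape, 22.0)), mk(np.full(g.shape, 1.0)),
        )

    def test_cell_centre_returns_cell_values(self):
        stack = self._stack()
        out = extract_at_points(stack, pd.DataFrame({"x": [2500.0], "y": [3500.0]}))
        assert out.loc[0, "elevation"] == pytest.approx(2.5)

    def test_corner_point_resolves_to_east_north_cell(self):
        stack = self._stack()
        out = extract_at_points(stack, pd.DataFrame({"x": [3000.0], "y": [3000.0]}))
        assert out.loc[0, "elevation"] == pytest.approx(3.5)  # cell ix=3 centre

    def test_nodata_points_flagged_invalid(self):
        stack = self._stack()
        stack.elevation.values[2, 2] = stack.elevation.nodata
        out = extract_at_points(stack, pd.DataFrame({"x": [2500.0, 4500.0], "y": [2500.0, 4500.0]}))
        assert not out.loc[0, "valid"] and out.loc[1, "valid"]

    def test_all_points_outside_rejected(self):
        stack = self._stack()
        with pytest.raises(ValueError, match="outside"):
            extract_at_points(stack, pd.DataFrame({"x": [-5000.0], "y": [-5000.0]}))
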