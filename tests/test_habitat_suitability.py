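import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from nes_atlas.habitat_suitability import (
    MaxentFeatures,
    MaxentParams,
    compare_hotspots_to_suitability,
    covariate_table,
    evaluate_auc,
    fit_group_model,
    fit_maxent,
    marginal_response,
    model_auc,
    predict_surface,
    presence_cells,
    split_presences,
    variable_importance,
)


def _plain_features(J):
    f = MaxentFeatures()
    f.names = [f"f{j}" for j in range(J)]
    f.covariate_of = [f"c{j}" for j in range(J)]
    return f


def _cov_frame(rng, n, geo_classes=(1.0, 2.0)):
    return pd.DataFrame(
        {
            "elevation": rng.uniform(0, 1500, n),
            "slope": rng.uniform(0, 30, n),
            "rainfall": rng.uniform(800, 4500, n),
            "temperature": rng.uniform(8, 25, n),
            "geology": rng.choice(geo_classes, n),
        }
    )


class TestFeatures:
    def test_constant_covariate_dropped(self):
        rng = np.random.default_rng(0)
        bg = _cov_frame(rng, 50)
        bg["slope"] = 5.0
        feats = MaxentFeatures.fit(bg)
        assert "slope" in feats.dropped
        assert not any(c == "slope" for c in feats.covariate_of)

    def test_background_max_scales_to_one(self):
        rng = np.random.default_rng(1)
        bg = _cov_frame(rng, 50)
        feats = MaxentFeatures.fit(bg)
        X = feats.transform(bg)
        j = feats.names.index("elevation:linear")
        assert X[:, j].max() == pytest.approx(1.0)
        assert X[:, j + 1].max() == pytest.approx(1.0)  # quadratic of the same row

    def test_geology_one_hot(self):
        rng = np.random.default_rng(2)
        bg = _cov_frame(rng, 50, geo_classes=(1.0, 2.0, 3.0))
        feats = MaxentFeatures.fit(bg)
        X = feats.transform(bg)
        cols = [j for j, c in enumerate(feats.covariate_of) if c == "geology"]
        np.testing.assert_allclose(X[:, cols].sum(axis=1), 1.0)

    def test_out_of_range_values_clamped_and_reported(self):
        rng = np.random.default_rng(3)
        bg = _cov_frame(rng, 50)
        feats = MaxentFeatures.fit(bg)
        far = bg.copy()
        far.loc[0, "elevation"] = 99999.0
        report = {}
        X = feats.transform(far, clamp_report=report)
        assert report["elevation"] == 1
        assert X[0, feats.names.index("elevation:linear")] == 1.0


class TestFit:
    def test_single_indicator_matches_1d_oracle(self):
        # half the background in class 1, all presences in class 1
        Xb = np.zeros((100, 1))
        Xb[:50, 0] = 1.0
        Xp = np.ones((40, 1))
        feats = _plain_features(1)
        model = fit_maxent(Xp, Xb, feats, MaxentParams(tol=1e-10, max_iter=2000))

        beta = model.beta[0]

        def neg(lam):
            return -(1.0 * lam - logsumexp(Xb[:, 0] * lam) + np.log(100) - beta * abs(lam))

        oracle = minimize_scalar(neg, bounds=(-10, 10), method="bounded",
                                 options={"xatol": 1e-10})
        assert model.lam[0] == pytest.approx(oracle.x, abs=1e-4)

    def test_duplicated_feature_column_same_predictions(self):
        rng = np.random.default_rng(4)
        Xb = rng.uniform(0, 1, (200, 1))
        Xp = rng.uniform(0.4, 1, (50, 1)) ** 0.5
        single = fit_maxent(Xp, Xb, _plain_features(1), MaxentParams(tol=1e-9, max_iter=2000))
        dup = fit_maxent(
            np.hstack([Xp, Xp]), np.hstack([Xb, Xb]), _plain_features(2),
            MaxentParams(tol=1e-9, max_iter=2000),
        )
        pred1 = single.raw(Xb)
        pred2 = dup.raw(np.hstack([Xb, Xb]))
        np.testing.assert_allclose(pred1, pred2, atol=1e-6)

    def test_objective_non_decreasing(self):
        rng = np.random.default_rng(5)
        Xb = rng.uniform(0, 1, (300, 4))
        Xp = rng.uniform(0, 1, (60, 4)) ** 0.6
        model = fit_maxent(Xp, Xb, _plain_features(4), MaxentParams())
        trace = np.array(model.objective_trace)
        assert (np.diff(trace) >= -1e-9).all()

    def test_constraint_gap_bounded_by_beta(self):
        rng = np.random.default_rng(6)
        Xb = rng.uniform(0, 1, (400, 3))
        Xp = rng.uniform(0, 1, (80, 3)) ** 0.5
        model = fit_maxent(Xp, Xb, _plain_features(3), MaxentParams(tol=1e-9, max_iter=2000))
        w = model.raw(Xb)
        model_mean = w @ Xb
        gap = np.abs(model_mean - model.presence_mean)
        assert (gap <= model.beta + 1e-6).all()

    def test_null_presences_shrink_to_uniform(self):
        rng = np.random.default_rng(7)
        Xb = rng.uniform(0, 1, (1000, 6))
        Xp = Xb[rng.choice(1000, 500, replace=False)]
        model = fit_maxent(Xp, Xb, _plain_features(6), MaxentParams())
        assert np.abs(model.lam).max() < 0.1


class TestPredict:
    def test_uniform_model_logistic_is_default_prevalence(self):
        Xb = np.full((50, 1), 0.5)
        model = fit_maxent(np.full((20, 1), 0.5), Xb, _plain_features(1), MaxentParams())
        np.testing.assert_allclose(model.logistic(Xb), 0.5, atol=1e-6)

    def test_raw_normalised_over_background(self):
        rng = np.random.default_rng(8)
        Xb = rng.uniform(0, 1, (300, 3))
        Xp = rng.uniform(0, 1, (50, 3)) ** 0.7
        model = fit_maxent(Xp, Xb, _plain_features(3), MaxentParams())
        assert model.raw(Xb).sum() == pytest.approx(1.0, abs=1e-6)

    def test_suitability_monotone_in_weighted_feature(self):
        rng = np.random.default_rng(9)
        Xb = rng.uniform(0, 1, (200, 2))
        Xp = np.column_stack([rng.uniform(0.6, 1, 50), rng.uniform(0, 1, 50)])
        model = fit_maxent(Xp, Xb, _plain_features(2), MaxentParams())
        assert model.lam[0] > 0
        lo = model.logistic(np.array([[0.1, 0.5]]))[0]
        hi = model.logistic(np.array([[0.9, 0.5]]))[0]
        assert hi > lo


class TestAuc:
    def test_perfect_separation(self):
        assert evaluate_auc(np.array([5.0, 6.0]), np.zeros(10)) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(10)
        auc = evaluate_auc(rng.uniform(size=500), rng.uniform(size=500))
        assert abs(auc - 0.5) < 0.05

    def test_empty_presences_rejected(self):
        with pytest.raises(ValueError):
            evaluate_auc(np.array([]), np.zeros(5))

    def test_split_is_disjoint_and_seeded(self):
        cells = np.arange(40).reshape(20, 2)
        tr1, te1 = split_presences(cells, 0.25, seed=3)
        tr2, te2 = split_presences(cells, 0.25, seed=3)
        np.testing.assert_array_equal(te1, te2)
        assert len(te1) == 5
        trs = {tuple(c) for c in tr1}
        tes = {tuple(c) for c in te1}
        assert not (trs & tes)


class TestImportance:
    def test_single_active_covariate_gets_full_contribution(self):
        rng = np.random.default_rng(11)
        bg = _cov_frame(rng, 300)
        for c in ("slope", "rainfall", "temperature"):
            bg[c] = bg[c].mean()  # constants -> dropped
        bg["geology"] = 1.0
        pres = bg.iloc[rng.choice(300, 60)].copy()
        pres["elevation"] = rng.uniform(1000, 1500, 60)
        feats = MaxentFeatures.fit(bg)
        model = fit_maxent(feats.transform(pres), feats.transform(bg), feats, MaxentParams())
        contrib = model.percent_contribution()
        assert contrib["elevation"] == pytest.approx(100.0)

    def test_zero_weight_covariate_zero_permutation_importance(self):
        rng = np.random.default_rng(12)
        bg = _cov_frame(rng, 300)
        pres = bg.iloc[rng.choice(300, 60)].copy()
        pres["elevation"] = rng.uniform(1200, 1500, 60)
        feats = MaxentFeatures.fit(bg)
        model = fit_maxent(feats.transform(pres), feats.transform(bg), feats, MaxentParams())
        inert = [c for c in feats.covariates
                 if all(model.lam[j] == 0 for j, cc in enumerate(feats.covariate_of) if cc == c)]
        vi = variable_importance(model, pres, bg, n_permutations=3, seed=0)
        for c in inert:
            assert vi.set_index("covariate").loc[c, "auc_drop"] == pytest.approx(0.0, abs=1e-9)


class TestMarginalResponse:
    def test_monotone_effect_recovered_as_increasing(self):
        rng = np.random.default_rng(13)
        bg = _cov_frame(rng, 400)
        pres = bg.iloc[rng.choice(400, 80)].copy()
        pres["elevation"] = rng.uniform(1100, 1500, 80)
        out = marginal_response(pres, bg, "elevation")
        assert out["direction"] == "increasing"

    def test_null_covariate_flat(self):
        rng = np.random.default_rng(14)
        bg = _cov_frame(rng, 400)
        pres = bg.copy()  # exact null: presences distributed as the background
        out = marginal_response(pres, bg, "slope")
        assert out["direction"] == "flat"
        assert out["suitability"].max() - out["suitability"].min() < 0.05

    def test_interior_optimum_recovered_as_unimodal(self):
        rng = np.random.default_rng(15)
        bg = _cov_frame(rng, 400)
        pres = bg.iloc[rng.choice(400, 80)].copy()
        pres["rainfall"] = rng.normal(2600, 150, 80)
        out = marginal_response(pres, bg, "rainfall")
        assert out["direction"] == "unimodal"


class TestPipeline:
    def test_group_model_end_to_end(self, stack, world):
        g3 = world.species_truth[world.species_truth["group_id"] == 3]["species_id"]
        recs = world.records[world.records["species_id"].isin(g3)]
        model, info = fit_group_model(stack, recs, MaxentParams(seed=0, n_background=3000))
        assert model.converged
        auc = model_auc(model, info["X_test"], info["X_bg"])
        assert auc > 0.8
        surf, mask, report = predict_surface(model, stack)
        vals = surf.values[np.isfinite(surf.values)]
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_binary_mode_surface_strongly_correlated(self, stack, world):
        g3 = world.species_truth[world.species_truth["group_id"] == 3]["species_id"]
        recs = world.records[world.records["species_id"].isin(g3)]
        params = MaxentParams(seed=0, n_background=3000)
        m1, _ = fit_group_model(stack, recs, params)
        m2, _ = fit_group_model(stack, recs, params, binary=True)
        s1, _, _ = predict_surface(m1, stack)
        s2, _, _ = predict_surface(m2, stack)
        ok = np.isfinite(s1.values) & np.isfinite(s2.values)
        r = np.corrcoef(s1.values[ok], s2.values[ok])[0, 1]
        assert r > 0.8


class TestHotspotComparison:
    def test_zero_surface_leaves_hotspots_unmatched(self, world):
        from nes_atlas.grids import GridSpec, Raster
        from nes_atlas.hotspot_grid import count_nes_per_cell
        from nes_atlas.nes_classification import build_species_profiles

        prof = build_species_profiles(world.records)
        hgrid = GridSpec(0, 0, 2000.0, 50, 50)
        hg = count_nes_per_cell(prof, world.records, hgrid)
        flat = Raster(np.zeros(world.grid.shape), world.grid)
        out = compare_hotspots_to_suitability(flat, hg)
        assert (out[out["hotspot"]]["class"] == "hotspot_only").all()
        assert not (out["class"] == "suitable_only").any()

    def test_suitable_unsampled_area_listed_as_candidate(self, world):
        from nes_atlas.grids import GridSpec, Raster
        from nes_atlas.hotspot_grid import count_nes_per_cell
        from nes_atlas.nes_classification import build_species_profiles

        prof = build_species_profiles(world.records)
        hgrid = GridSpec(0, 0, 2000.0, 50, 50)
        hg = count_nes_per_cell(prof, world.records, hgrid)
        vals = np.zeros(world.grid.shape)
        vals[0:6, 0:6] = 0.9  # suitable corner far from any planted hotspot
        surf = Raster(vals, world.grid)
        out = compare_hotspots_to_suitability(surf, hg)
        assert (out["class"] == "suitable_only").any()

    def test_bad_cutoff_rejected(self, world):
        from nes_atlas.grids import GridSpec, Raster
        from nes_atlas.hotspot_grid import count_nes_per_cell
        from nes_atlas.nes_classification import build_species_profiles

        prof = build_species_profiles(world.records.head(200))
        hg = count_nes_per_cell(prof, world.records.head(200), GridSpec(0, 0, 2000.0, 50, 50))
        surf = Raster(np.zeros(world.grid.shape), world.grid)
        with pytest.raises(ValueError):
            compare_hotspots_to_suitability(surf, hg, cutoff=1.5)
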