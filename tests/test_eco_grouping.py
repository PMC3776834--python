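import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from nes_atlas.eco_grouping import (
    classical_mds,
    cophenetic_distances,
    gower_matrix,
    hierarchical_cluster,
    nmds_embed,
    pam_cluster,
    pam_medoids,
    partition_isolation,
    run_grouping,
    select_groups,
    summarize_species_env,
)


def _summary(rows):
    return pd.DataFrame(
        rows, columns=["species_id", "elevation", "slope", "rainfall", "temperature", "geology"]
    )


class TestSummaries:
    def test_modal_geology_and_means(self, stack, world):
        recs = world.records.head(400)
        summ, report = summarize_species_env(recs, stack)
        assert report["n_species"] == summ.shape[0]
        one = summ.iloc[0]
        sp_recs = recs[recs["species_id"] == one["species_id"]]
        from nes_atlas.environment import extract_at_points

        ext = extract_at_points(stack, sp_recs)
        assert one["elevation"] == pytest.approx(ext[ext["valid"]]["elevation"].mean())

    def test_single_record_summary_is_point_values(self, stack, world):
        sp = world.records["species_id"].iloc[0]
        recs = world.records[world.records["species_id"] == sp].head(1)
        summ, _ = summarize_species_env(recs, stack)
        from nes_atlas.environment import extract_at_points

        ext = extract_at_points(stack, recs)
        assert summ.loc[0, "rainfall"] == pytest.approx(ext.loc[ext.index[0], "rainfall"])

    def test_mode_tie_breaks_by_documented_order(self, stack, world):
        # two records on different substrates: tie resolves U < V < L < R
        recs = pd.DataFrame(
            {"species_id": ["t", "t"], "x": [0.0, 0.0], "y": [0.0, 0.0]}
        )
        # place one record on a U cell and one on a V cell
        geo = world.geology.values
        uy, ux = np.argwhere(geo == 1.0)[0]
        vy, vx = np.argwhere(geo == 2.0)[0]
        g = world.grid
        recs.loc[0, ["x", "y"]] = (g.x0 + (ux + 0.5) * g.cell, g.y0 + (uy + 0.5) * g.cell)
        recs.loc[1, ["x", "y"]] = (g.x0 + (vx + 0.5) * g.cell, g.y0 + (vy + 0.5) * g.cell)
        summ, _ = summarize_species_env(recs, stack)
        assert summ.loc[0, "geology"] == "U"


class TestGower:
    def test_identical_rows_zero_distance(self):
        s = _summary([["a", 100, 5, 2000, 22, "U"], ["b", 100, 5, 2000, 22, "U"],
                      ["c", 900, 15, 3000, 15, "V"]])
        d = gower_matrix(s)
        assert d[0, 1] == 0.0

    def test_single_categorical_mismatch_is_one_fifth(self):
        s = _summary([["a", 100, 5, 2000, 22, "U"], ["b", 100, 5, 2000, 22, "V"],
                      ["c", 900, 15, 3000, 15, "U"]])
        d = gower_matrix(s)
        assert d[0, 1] == pytest.approx(0.2)

    def test_maximal_difference_on_every_variable_is_one(self):
        s = _summary([["a", 0, 0, 1000, 10, "U"], ["b", 1000, 30, 4000, 25, "V"]])
        assert gower_matrix(s)[0, 1] == pytest.approx(1.0)

    def test_matrix_properties(self):
        rng = np.random.default_rng(0)
        rows = [[f"s{i}", rng.uniform(0, 1500), rng.uniform(0, 30), rng.uniform(800, 4500),
                 rng.uniform(8, 25), rng.choice(["U", "V", "L", "R"])] for i in range(30)]
        d = gower_matrix(_summary(rows))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d.min() >= 0.0 and d.max() <= 1.0

    def test_zero_range_variable_dropped_with_warning(self):
        s = _summary([["a", 100, 5, 2000, 22, "U"], ["b", 900, 5, 3000, 15, "V"]])
        with pytest.warns(UserWarning, match="zero range"):
            d = gower_matrix(s)
        # slope dropped: mean over 3 continuous + 1 categorical contributions
        assert d[0, 1] == pytest.approx(1.0)

    def test_all_variables_degenerate_rejected(self):
        s = _summary([["a", 1, 1, 1, 1, "U"], ["b", 1, 1, 1, 1, "U"]])
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                gower_matrix(s)


class TestPam:
    def test_two_blobs_match_exhaustive_medoid_search(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.3, (5, 2)), rng.normal(6, 0.3, (5, 2))])
        d = squareform(pdist(pts))
        medoids, labels = pam_medoids(d, 2)
        cost = d[:, medoids].min(axis=1).sum()
        best = min(
            d[:, list(pair)].min(axis=1).sum() for pair in itertools.combinations(range(10), 2)
        )
        assert cost == pytest.approx(best)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_outlier_becomes_singleton(self):
        pts = np.zeros((8, 2))
        pts[-1] = (10.0, 10.0)
        pts[:7] += np.random.default_rng(2).normal(0, 1e-6, (7, 2))
        d = squareform(pdist(pts))
        _, labels = pam_medoids(d, 2)
        assert (labels == labels[-1]).sum() == 1

    def test_swap_never_worse_than_build(self):
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.uniform(0, 1, (25, 3))))
        from nes_atlas.eco_grouping import _pam_build, _pam_cost

        for k in (2, 3, 5):
            build_cost = _pam_cost(d, _pam_build(d, k))
            medoids, _ = pam_medoids(d, k)
            assert _pam_cost(d, medoids) <= build_cost + 1e-12

    def test_k_out_of_range_rejected(self):
        d = squareform(pdist(np.random.default_rng(0).uniform(size=(5, 2))))
        with pytest.raises(ValueError):
            pam_medoids(d, 5)

    def test_indices_reported_for_each_k(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(i * 5, 0.4, (8, 2)) for i in range(3)])
        d = squareform(pdist(pts))
        res = pam_cluster(d, range(2, 5))
        assert set(res) == {2, 3, 4}
        assert res[3]["silhouette"] > res[4]["silhouette"]


class TestHierarchical:
    def test_first_merge_is_closest_pair(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0.0]])
        tree = hierarchical_cluster(d)
        assert sorted(tree[0, :2]) == [0, 1]
        assert tree[0, 2] == pytest.approx(1.0)

    def test_two_items_single_merge_at_distance(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        tree = hierarchical_cluster(d)
        assert tree.shape == (1, 4) and tree[0, 2] == pytest.approx(3.0)

    def test_ultrametric_input_reproduced_by_cophenetic(self):
        d = np.array(
            [[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0.0]]
        )
        tree = hierarchical_cluster(d)
        np.testing.assert_allclose(cophenetic_distances(tree), d)


class TestNmds:
    def test_planar_config_embeds_with_near_zero_stress(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(25, 2))
        d = squareform(pdist(pts))
        _, stress = nmds_embed(d, dims=2, seed=0, n_restarts=2)
        assert stress < 0.01

    def test_stress_non_increasing_in_dimension(self):
        rng = np.random.default_rng(6)
        d = squareform(pdist(rng.normal(size=(15, 5))))
        _, s2 = nmds_embed(d, dims=2, seed=0, n_restarts=2)
        _, s4 = nmds_embed(d, dims=4, seed=0, n_restarts=2)
        assert s4 <= s2 + 1e-6

    def test_equal_distances_embed_as_simplex_with_tiny_stress(self):
        d = np.ones((4, 4))
        np.fill_diagonal(d, 0.0)
        _, stress = nmds_embed(d, dims=2, seed=0)
        assert stress < 0.01

    def test_classical_scaling_recovers_planar_distances(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        coords = classical_mds(d, 2)
        np.testing.assert_allclose(squareform(pdist(coords)), d, atol=1e-8)


class TestSelectGroups:
    def _three_isolated_one_gradient(self):
        # cluster A is a tight 1-D chain PAM likes to split; B and C compact
        coords = np.concatenate(
            [np.linspace(0.0, 0.4, 30), np.full(10, 2.0), np.full(10, 4.0)]
        )
        coords[30:] += np.linspace(0, 0.02, 20)
        d = squareform(pdist(coords[:, None]))
        return d, np.array([0] * 30 + [1] * 10 + [2] * 10)

    def test_gradient_split_rejected_three_groups_found(self):
        d, truth = self._three_isolated_one_gradient()
        pam = pam_cluster(d, range(2, 6))
        tree = hierarchical_cluster(d)
        k, labels, ari, note = select_groups(d, pam, tree)
        assert k == 3
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_isolation_score_separates_real_from_gradient_cuts(self):
        d, truth = self._three_isolated_one_gradient()
        assert partition_isolation(d, truth) > 4.0
        split = truth.copy()
        split[:15] = 3  # cut the chain in half
        assert partition_isolation(d, split) < 4.0

    def test_two_species_grouping_skipped(self):
        s = _summary([["a", 100, 5, 2000, 22, "U"], ["b", 900, 15, 3000, 15, "V"]])
        res = run_grouping(s)
        assert res.chosen_k == 1 and "skipped" in res.disagreement_note

    def test_three_group_world_recovered(self):
        import warnings

        from sklearn.metrics import adjusted_rand_score

        from nes_atlas.environment import EnvLayerStack, compute_slope
        from nes_atlas.synthetic_data import WorldConfig, generate_world

        cfg = WorldConfig(geology_shares=(0.35, 0.45, 0.20, 0.0))
        w = generate_world(cfg, seed=701)
        stack = EnvLayerStack(w.dem, compute_slope(w.dem), w.rainfall_true,
                              w.temperature, w.geology)
        truth = w.species_truth[w.species_truth["home_substrate"] != "planted"]
        recs = w.records[w.records["species_id"].isin(truth["species_id"])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ, _ = summarize_species_env(recs, stack)
            res = run_grouping(summ, k_range=range(2, 7), seed=0, subgroup_search=False)
        m = summ.merge(truth, on="species_id")
        assert res.chosen_k == 3
        assert adjusted_rand_score(m["group_id"].to_numpy(), res.labels) > 0.9
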