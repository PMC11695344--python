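"""Distance maps, neighborhood windows, and neighbor statistics against
brute-force oracles and geometric invariances."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import leadedge as le
from leadedge.errors import ConfigError, ValidationError
from tests.conftest import truth_labeled


def random_table(rng, n=120, n_rois=2, labels=("A", "B", "C")):
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:04d}" for i in range(n)],
            "roi_id": rng.choice([f"r{k}" for k in range(n_rois)], n),
            "x": rng.uniform(0, 100, n),
            "y": rng.uniform(0, 100, n),
            "cell_type": rng.choice(labels, n),
        }
    )


def brute_force_closest(t, target):
    out = np.full(len(t), np.nan)
    for _, idx in t.groupby("roi_id").indices.items():
        sub = t.iloc[idx]
        xy = sub[["x", "y"]].to_numpy()
        is_t = (sub["cell_type"] == target).to_numpy()
        for i in range(len(sub)):
            d = np.sqrt(((xy[is_t] - xy[i]) ** 2).sum(axis=1))
            if is_t[i]:
                d = np.delete(d, int(is_t[:i].sum()))
            if len(d):
                out[idx[i]] = d.min()
    return out


def brute_force_knn(t, k):
    windows = [None] * len(t)
    for _, idx in t.groupby("roi_id").indices.items():
        sub = t.iloc[idx]
        xy = sub[["x", "y"]].to_numpy()
        ids = sub["cell_id"].to_numpy()
        for i in range(len(sub)):
            d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
            order = sorted(
                (j for j in range(len(sub)) if j != i),
                key=lambda j: (d[j], ids[j]),
            )
            windows[idx[i]] = idx[order[: k - 1]]
    return windows


class TestClosestDistance:
    def test_three_four_five(self):
        t = pd.DataFrame(
            {
                "cell_id": ["a", "b", "c"],
                "roi_id": ["r"] * 3,
                "x": [0.0, 3.0, 6.0],
                "y": [0.0, 4.0, 8.0],
                "cell_type": ["src", "tgt", "tgt"],
            }
        )
        d = le.closest_distance_map(t, "tgt")
        assert d.iloc[0] == pytest.approx(5.0)

    def test_roi_without_targets_is_missing(self):
        t = pd.DataFrame(
            {
                "cell_id": ["a", "b", "c"],
                "roi_id": ["r1", "r1", "r2"],
                "x": [0.0, 1.0, 2.0],
                "y": [0.0, 1.0, 2.0],
                "cell_type": ["src", "tgt", "src"],
            }
        )
        d = le.closest_distance_map(t, "tgt")
        assert np.isnan(d.iloc[2]) and not np.isnan(d.iloc[0])

    def test_unknown_label_rejected(self):
        t = random_table(np.random.default_rng(0))
        with pytest.raises(ValidationError):
            le.closest_distance_map(t, "NOPE")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        t = random_table(np.random.default_rng(seed), n=200)
        for target in ("A", "B"):
            got = le.closest_distance_map(t, target).to_numpy()
            np.testing.assert_allclose(
                got, brute_force_closest(t, target), rtol=1e-12, equal_nan=True
            )


class TestRoiMeanDistances:
    def test_simple_mean(self):
        t = pd.DataFrame(
            {
                "cell_id": list("abcd"),
                "roi_id": ["r"] * 4,
                "x": [0.0, 0.0, 5.0, 7.0],
                "y": [0.0, 12.0, 0.0, 12.0],
                "cell_type": ["s", "s", "t", "t"],
            }
        )
        d = le.roi_mean_distances(t)
        row = d[(d["source"] == "s") & (d["target"] == "t")]
        assert row["mean_distance"].iloc[0] == pytest.approx(6.0)

    def test_asymmetry(self):
        # one A far from the B cluster: mean(A->B) >> mean(B->A)
        rng = np.random.default_rng(3)
        t = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(12)],
                "roi_id": ["r"] * 12,
                "x": np.concatenate([[0.0, 100.0], rng.uniform(0, 1, 10)]),
                "y": np.concatenate([[0.0, 0.0], 1 + rng.uniform(0, 1, 10)]),
                "cell_type": ["A", "A"] + ["B"] * 10,
            }
        )
        d = le.roi_mean_distances(t).set_index(["source", "target"])
        ab = d.loc[("A", "B"), "mean_distance"]
        ba = d.loc[("B", "A"), "mean_distance"]
        assert ab > 10 * ba
        oracle = brute_force_closest(t, "B")
        assert ab == pytest.approx(np.mean(oracle[:2]))
        oracle_a = brute_force_closest(t, "A")
        assert ba == pytest.approx(np.mean(oracle_a[2:]))

    def test_planted_proximity_orders_subtypes(self):
        cfg = le.ImcSimConfig(n_rois=4, cells_per_roi=600, proximity_on=True,
                              proximity_radius=20.0)
        table, truth = le.gen_imc_rois(cfg, seed=11)
        t = truth_labeled(table, truth)
        d = le.roi_mean_distances(t, source_field="fb_subtype")
        endo = d[d["target"] == "endothelial"]
        means = endo.groupby("source")["mean_distance"].mean()
        assert means["S3"] < means[["S1", "S2", "S4"]].min()


class TestKnnWindows:
    def test_roi_with_exactly_k_cells(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, n=8, n_rois=1)
        w = le.knn_windows(t, k=8)
        for i, nb in enumerate(w.neighbors):
            assert len(nb) == 7 and i not in nb

    def test_tie_broken_by_cell_id(self):
        t = pd.DataFrame(
            {
                "cell_id": ["center", "far_a", "near_b", "near_a"],
                "roi_id": ["r"] * 4,
                "x": [0.0, 10.0, 1.0, -1.0],
                "y": [0.0, 0.0, 0.0, 0.0],
                "cell_type": ["A"] * 4,
            }
        )
        w = le.knn_windows(t, k=2)
        # near_a and near_b both at distance 1; 'near_a' < 'near_b'
        assert list(t.loc[w.neighbors[0], "cell_id"]) == ["near_a"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        t = random_table(np.random.default_rng(seed), n=150)
        w = le.knn_windows(t, k=10)
        expected = brute_force_knn(t, 10)
        for got, exp in zip(w.neighbors, expected):
            np.testing.assert_array_equal(got, exp)

    def test_k_below_two_rejected(self):
        with pytest.raises(ConfigError):
            le.knn_windows(random_table(np.random.default_rng(0)), k=1)

    def test_small_roi_truncated_with_warning(self, caplog):
        t = random_table(np.random.default_rng(1), n=5, n_rois=1)
        with caplog.at_level("WARNING"):
            w = le.knn_windows(t, k=26)
        assert all(len(nb) == 4 for nb in w.neighbors)
        assert "truncated" in caplog.text


class TestWindowComposition:
    def test_rows_sum_to_one_and_homogeneous_roi(self):
        t = random_table(np.random.default_rng(2), n=60, n_rois=1,
                         labels=("A",))
        w = le.knn_windows(t, k=10)
        comp = le.window_composition(w, t)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0)
        np.testing.assert_allclose(comp["A"], 1.0)

    def test_half_half_window(self):
        # 13 A at the origin cluster, 13 B nearby: every window is 13/13
        t = pd.DataFrame(
            {
                "cell_id": [f"c{i:02d}" for i in range(26)],
                "roi_id": ["r"] * 26,
                "x": np.arange(26) * 0.01,
                "y": np.zeros(26),
                "cell_type": ["A", "B"] * 13,
            }
        )
        w = le.knn_windows(t, k=26)
        comp = le.window_composition(w, t)
        np.testing.assert_allclose(comp["A"], 0.5)
        np.testing.assert_allclose(comp["B"], 0.5)

    def test_unset_labels_rejected(self):
        t = random_table(np.random.default_rng(3), n=30)
        t.loc[0, "cell_type"] = None
        w = le.knn_windows(t, k=5)
        with pytest.raises(ValidationError):
            le.window_composition(w, t)


class TestClusterNeighborhoods:
    def test_recovers_planted_niches(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.dirichlet([50, 2, 2], 100)
            b = rng.dirichlet([2, 2, 50], 100)
            comp = pd.DataFrame(np.vstack([a, b]), columns=list("XYZ"))
            model = le.cluster_neighborhoods(comp, 2, seed=seed)
            truth = np.repeat([0, 1], 100)
            assert adjusted_rand_score(truth, model.assignments) >= 0.9

    def test_determinism_and_bounds(self):
        comp = pd.DataFrame(
            np.random.default_rng(0).dirichlet([1, 1, 1], 50),
            columns=list("XYZ"),
        )
        m1 = le.cluster_neighborhoods(comp, 3, seed=4)
        m2 = le.cluster_neighborhoods(comp, 3, seed=4)
        np.testing.assert_array_equal(m1.assignments, m2.assignments)
        assert set(m1.assignments) <= {1, 2, 3}
        np.testing.assert_allclose(m1.centroids.sum(axis=1), 1.0, atol=1e-6)

    def test_invalid_cluster_counts(self):
        comp = pd.DataFrame(np.eye(3), columns=list("XYZ"))
        with pytest.raises(ConfigError):
            le.cluster_neighborhoods(comp, 1)
        with pytest.raises(ConfigError):
            le.cluster_neighborhoods(comp, 4)


class TestNeighborFraction:
    def test_arithmetic(self):
        # star layout: one S3 center, 2 endothelial + 3 tumor neighbors
        t = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(6)],
                "roi_id": ["r"] * 6,
                "x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
                "y": [0.0] * 6,
                "cell_type": ["stromal", "endothelial", "endothelial",
                               "tumor", "tumor", "tumor"],
                "fb_subtype": ["S3"] + ["unassigned"] * 5,
            }
        )
        w = le.knn_windows(t, k=6)
        frac = le.neighbor_fraction(w, t, "S3", "endothelial")
        assert frac == pytest.approx(2 / 5)

    def test_missing_source_gives_nan(self):
        t = random_table(np.random.default_rng(1), n=30)
        t["fb_subtype"] = "unassigned"
        w = le.knn_windows(t, k=5)
        assert np.isnan(le.neighbor_fraction(w, t, "S3", "A"))


class TestGeometricInvariance:
    def test_rigid_transform_leaves_results_unchanged(self):
        t = random_table(np.random.default_rng(9), n=150)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        xy = t[["x", "y"]].to_numpy() @ rot.T + np.array([55.0, -20.0])
        t2 = t.assign(x=xy[:, 0], y=xy[:, 1])
        d1 = le.roi_mean_distances(t)
        d2 = le.roi_mean_distances(t2)
        pd.testing.assert_frame_equal(d1, d2, check_exact=False, atol=1e-9)
        w1 = le.knn_windows(t, k=8)
        w2 = le.knn_windows(t2, k=8)
        for a, b in zip(w1.neighbors, w2.neighbors):
            assert set(a) == set(b)

    def test_label_shuffle_null_centers_distance_gap_at_zero(self):
        """Permuting subtype labels within ROI removes the planted S3 vs S1
        endothelial-distance gap (mean within 2 SE over 200 shuffles)."""
        cfg = le.ImcSimConfig(n_rois=2, cells_per_roi=500, proximity_on=True)
        table, truth = le.gen_imc_rois(cfg, seed=21)
        t = truth_labeled(table, truth)
        rng = np.random.default_rng(0)
        endo_dist = le.closest_distance_map(t, "endothelial").to_numpy()
        sub = t["fb_subtype"].to_numpy()
        gaps = []
        for _ in range(200):
            perm = sub.copy()
            for _, idx in t.groupby("roi_id").indices.items():
                perm[idx] = perm[rng.permutation(idx)]
            s3 = np.nanmean(endo_dist[perm == "S3"])
            s1 = np.nanmean(endo_dist[perm == "S1"])
            gaps.append(s3 - s1)
        gaps = np.array(gaps)
        se = gaps.std(ddof=1) / np.sqrt(len(gaps))
        assert abs(gaps.mean()) < 2 * se + 1e-9
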