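"""k-means / EM clustering of the feature table and per-cluster summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from corneasym import Algorithm, ClusterConfig, cluster_cases, summarize_clusters
from corneasym.cluster import format_report


def blob_table(rng, centers, n_per, sigma=0.1, n_features=4):
    rows, labels = [], []
    for ci, c in enumerate(centers):
        pts = rng.normal(c, sigma, (n_per, n_features))
        rows.append(pts)
        labels += [ci] * n_per
    X = np.vstack(rows)
    table = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    table.index = [f"c{i:04d}" for i in range(len(table))]
    table.index.name = "case_id"
    return table, np.array(labels)


def config(**kw):
    defaults = dict(selected_features=("f0", "f1", "f2", "f3"), seed=7)
    defaults.update(kw)
    return ClusterConfig(**defaults)


class TestKMeans:
    def test_single_case_k1(self, rng):
        table, _ = blob_table(rng, [[1.0, 2.0, 3.0, 4.0]], 1, sigma=0.0)
        res = cluster_cases(table, config(k=1, standardize=False))
        assert res.within_ss == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(res.centroids.iloc[0], [1.0, 2.0, 3.0, 4.0])

    def test_duplicated_points_k2(self, rng):
        table, _ = blob_table(rng, [[0.0] * 4, [5.0] * 4], 20, sigma=0.0)
        res = cluster_cases(table, config(k=2))
        assert res.within_ss == pytest.approx(0.0, abs=1e-12)
        assert sorted(res.sizes.tolist()) == [20, 20]

    def test_three_blob_recovery(self, rng):
        centers = [[0.0] * 4, [5.0] * 4, [0.0, 5.0, 0.0, 5.0]]
        table, truth = blob_table(rng, centers, 100, sigma=0.1)
        res = cluster_cases(table, config(k=3))
        assert adjusted_rand_score(truth, res.assignments.to_numpy()) == 1.0
        assert res.objective_history == sorted(res.objective_history, reverse=True)

    def test_agrees_with_sklearn_objective(self, rng):
        """Independent route: our Lloyd loop should reach the same optimum
        as sklearn's KMeans on well-separated data."""
        table, truth = blob_table(rng, [[0.0] * 4, [8.0] * 4], 50, sigma=0.2)
        res = cluster_cases(table, config(k=2, standardize=False))
        sk = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
            table.to_numpy(dtype=float)
        )
        assert res.within_ss == pytest.approx(sk.inertia_, rel=1e-6)
        assert adjusted_rand_score(sk.labels_, res.assignments.to_numpy()) == 1.0

    def test_row_permutation_invariance(self, rng):
        table, _ = blob_table(rng, [[0.0] * 4, [5.0] * 4, [9.0] * 4], 30)
        res1 = cluster_cases(table, config(k=3))
        shuffled = table.sample(frac=1.0, random_state=11)
        res2 = cluster_cases(shuffled, config(k=3))
        pd.testing.assert_series_equal(res1.assignments, res2.assignments)
        assert res1.within_ss == pytest.approx(res2.within_ss)

    def test_sizes_canonically_ordered(self, rng):
        table, _ = blob_table(rng, [[0.0] * 4] * 1 + [[6.0] * 4], 40)
        table = pd.concat([table.iloc[:50], table.iloc[40:45]])
        table = table[~table.index.duplicated()]
        res = cluster_cases(table, config(k=2))
        assert (np.diff(res.sizes) <= 0).all()
        assert res.sizes.sum() == len(table)

    def test_centroids_in_original_units(self, rng):
        centers = [[10.0, 200.0, 1.0, 50.0], [20.0, 400.0, 2.0, 100.0]]
        table, truth = blob_table(rng, centers, 50, sigma=0.01)
        res = cluster_cases(table, config(k=2, standardize=True))
        got = res.centroids.to_numpy()
        # each generating center appears as some cluster's centroid
        for c in centers:
            assert np.min(np.abs(got - np.array(c)).max(axis=1)) < 0.01

    def test_domain_errors(self, rng):
        table, _ = blob_table(rng, [[0.0] * 4], 3)
        with pytest.raises(ValueError):
            cluster_cases(table, config(k=5))
        with pytest.raises(KeyError):
            cluster_cases(table, config(selected_features=("nope",)))
        with pytest.raises(ValueError):
            cluster_cases(table.iloc[:0], config())

    def test_zero_variance_feature_dropped(self, rng):
        table, _ = blob_table(rng, [[0.0] * 4, [5.0] * 4], 20)
        table["f3"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cluster_cases(table, config(k=2))
        assert list(res.centroids.columns) == ["f0", "f1", "f2"]


class TestEM:
    def test_em_k1_recovers_mean(self):
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, mu, sigma = 200, 3.0, 1.0
            table, _ = blob_table(rng, [[mu] * 4], n, sigma=sigma)
            res = cluster_cases(
                table, config(algorithm=Algorithm.EM, k=1, standardize=False, seed=seed)
            )
            se = sigma / np.sqrt(n)
            errors.append(np.abs(res.centroids.iloc[0].to_numpy() - mu).max() / se)
        # mean recovery within 3 SE in essentially all runs
        assert np.mean(np.array(errors) < 3.0) >= 0.95

    def test_em_separated_blobs(self, rng):
        table, truth = blob_table(rng, [[0.0] * 4, [8.0] * 4], 60, sigma=0.3)
        res = cluster_cases(table, config(algorithm=Algorithm.EM, k=2))
        assert adjusted_rand_score(truth, res.assignments.to_numpy()) == 1.0

    def test_pca_reduction_path(self, rng):
        table, truth = blob_table(rng, [[0.0] * 4, [8.0] * 4], 40, sigma=0.2)
        res = cluster_cases(table, config(k=2, pca_components=2))
        assert adjusted_rand_score(truth, res.assignments.to_numpy()) == 1.0
        assert res.centroids.shape == (2, 4)  # reported in original feature space


class TestSummaries:
    def test_identical_cases_zero_sd(self, rng):
        table, _ = blob_table(rng, [[1.0] * 4], 10, sigma=0.0)
        assign = pd.Series([0] * 5 + [1] * 5, index=table.index, name="cluster")
        summary = summarize_clusters(table, assign)
        assert (summary[["sd_0", "sd_1"]].to_numpy() == 0.0).all()
        assert summary["degenerate"].all()

    def test_two_constant_clusters(self, rng):
        table, _ = blob_table(rng, [[0.0] * 4, [10.0] * 4], 5, sigma=0.0)
        assign = pd.Series([0] * 5 + [1] * 5, index=table.index, name="cluster")
        summary = summarize_clusters(table, assign)
        assert summary["mean_0"].to_numpy() == pytest.approx([0.0] * 4)
        assert summary["mean_1"].to_numpy() == pytest.approx([10.0] * 4)
        assert summary["degenerate"].all()
        assert summary["anova_p"].isna().all()

    def test_parameter_recovery_with_anova(self, rng):
        centers = [[0.0] * 4, [5.0] * 4, [10.0] * 4]
        table, truth = blob_table(rng, centers, 50, sigma=1.0)
        assign = pd.Series(truth, index=table.index, name="cluster")
        summary = summarize_clusters(table, assign)
        se = 1.0 / np.sqrt(50)
        for ci, c in enumerate(centers):
            assert np.abs(summary[f"mean_{ci}"].to_numpy() - np.array(c)).max() < 2 * se * 3
        assert (summary["anova_p"] < 1e-10).all()

    def test_singleton_cluster_sd_is_nan(self, rng):
        table, _ = blob_table(rng, [[0.0] * 4], 3)
        assign = pd.Series([0, 0, 1], index=table.index, name="cluster")
        summary = summarize_clusters(table, assign)
        assert summary["sd_1"].isna().all()

    def test_report_layout(self, rng):
        table, _ = blob_table(rng, [[0.0] * 4, [5.0] * 4], 20)
        res = cluster_cases(table, config(k=2))
        text = format_report(res)
        assert "Within cluster sum of squared errors" in text
        assert "Number of iterations" in text
        assert "Cluster 1" in text and "Cluster 2" in text
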