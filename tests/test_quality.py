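"""Quality index construction, K-means++ seeding law, Lloyd
monotonicity, SC/DBI against brute force and an independent reference,
cluster-count selection and level ordering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import davies_bouldin_score, silhouette_score

import residuecast as rc
from residuecast.quality import ClusterModel

# printed two-component cluster centers (observed, predicted-mean), mg/kg
PRINTED_DIMETHOATE_CENTERS = np.array([
    [0.03950035, 0.03341637],
    [0.04434314, 0.03039072],
    [0.04900005, 0.04175411],
])


class TestBuildQualityIndex:
    def test_perfect_forecaster_constant_series(self):
        obs = np.full(6, 2.5)
        forecasts = {i: np.full(3, 2.5) for i in range(6)}
        table = rc.build_quality_index(obs, forecasts, n=3)
        assert np.all(table["d"] == 2.5) and np.all(table["dbar"] == 2.5)

    def test_n_one_uses_single_next_day(self):
        obs = np.array([1.0, 2.0, 3.0])
        forecasts = {0: np.array([9.0, 0.0]), 1: np.array([7.0])}
        table = rc.build_quality_index(obs, forecasts, n=1)
        assert list(table["dbar"]) == [9.0, 7.0]

    def test_hand_averaged_pairs(self):
        obs = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        forecasts = {0: np.array([4.2, 3.1]), 1: np.array([3.0, 2.2]),
                     2: np.array([2.1, 1.0])}
        table = rc.build_quality_index(obs, forecasts, n=2)
        assert np.allclose(table["dbar"], [(4.2 + 3.1) / 2, 2.6, 1.55])
        assert list(table["day"]) == [0, 1, 2]  # days 3,4 lack full windows

    def test_n_exceeding_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            rc.build_quality_index(np.ones(3), {0: np.ones(2)}, n=5)


class TestKmeansppSeed:
    POINTS = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [5.0, 5.0]])

    def test_chosen_point_never_reselected(self):
        for seed in range(200):
            centers = rc.kmeanspp_seed(self.POINTS, 2, seed, first_index=3)
            assert not np.array_equal(centers[1], self.POINTS[3])

    def test_k_one_uniform(self):
        counts = np.zeros(4)
        for seed in range(2000):
            c = rc.kmeanspp_seed(self.POINTS, 1, seed)
            counts[np.argmin(np.abs(self.POINTS - c[0]).sum(1))] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_collinear_d2_frequency(self):
        """P(next = far point) = 100^2/(1 + 100^2) given first center at 0."""
        pts = np.array([[0.0], [1.0], [100.0]])
        p_far = 100.0 ** 2 / (1 + 100.0 ** 2)
        hits = sum(
            rc.kmeanspp_seed(pts, 2, seed, first_index=0)[1, 0] == 100.0
            for seed in range(4000))
        sd = np.sqrt(4000 * p_far * (1 - p_far))
        assert abs(hits - 4000 * p_far) < 3 * sd

    def test_d2_law_chi_squared(self):
        """Empirical next-center frequencies match D^2 probabilities."""
        draws = 10000
        counts = np.zeros(4)
        for seed in range(draws):
            c = rc.kmeanspp_seed(self.POINTS, 2, seed, first_index=0)[1]
            counts[np.argmin(np.abs(self.POINTS - c).sum(1))] += 1
        d2 = (self.POINTS ** 2).sum(axis=1)
        expected = draws * d2 / d2.sum()
        stat = ((counts[1:] - expected[1:]) ** 2 / expected[1:]).sum()
        assert counts[0] == 0
        assert stat < stats.chi2.ppf(0.99, df=2)

    def test_k_exceeding_distinct_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rc.kmeanspp_seed(np.array([[0.0], [0.0], [1.0]]), 3, 0)


class TestKmeansFit:
    def test_centers_on_points_converge_immediately(self):
        pts = np.array([[0.0, 0], [10, 0], [0, 10]])
        model = rc.kmeans_fit(pts, pts.copy())
        assert model.inertia == 0.0 and model.n_iter == 1

    def test_two_pairs_find_midpoints(self):
        pts = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
        model = rc.kmeans_fit(pts, np.array([[1.0, 0.0], [9.0, 1.0]]))
        assert np.allclose(np.sort(model.centers[:, 0]), [0, 10])
        assert np.allclose(model.centers[:, 1], 0.5)

    def test_wcss_nonincreasing_every_iteration(self, rng):
        pts = rng.normal(size=(120, 2))
        init = rc.kmeanspp_seed(pts, 4, 0)
        model = rc.kmeans_fit(pts, init)
        trace = np.array(model.wcss_trace)
        assert np.all(np.diff(trace) <= 1e-9)
        assert model.inertia <= trace[0]

    def test_duplicate_initial_centers_rejected(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="distinct"):
            rc.kmeans_fit(pts, np.array([[0.5], [0.5]]))


def brute_force_silhouette(points, labels):
    n = len(points)
    total = 0.0
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = (np.mean([np.linalg.norm(points[i] - points[j]) for j in same])
             if same else 0.0)
        b = min(np.mean([np.linalg.norm(points[i] - points[j])
                         for j in range(n) if labels[j] == lab])
                for lab in set(labels) if lab != labels[i])
        total += 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return total / n


def brute_force_dbi(points, labels, centers):
    k = len(centers)
    s = [np.mean([np.linalg.norm(p - centers[j]) for p in points[labels == j]])
         for j in range(k)]
    total = 0.0
    for i in range(k):
        total += max((s[i] + s[j]) / np.linalg.norm(centers[i] - centers[j])
                     for j in range(k) if j != i)
    return total / k


class TestClusterIndices:
    def test_tight_distant_clusters_high_silhouette(self, rng):
        pts = np.vstack([rng.normal(0, 0.01, (20, 2)),
                         rng.normal(100, 0.01, (20, 2))])
        labels = np.repeat([0, 1], 20)
        assert rc.silhouette(pts, labels) > 0.9

    def test_rectangle_hand_computation(self):
        # corners of a 10 x 1 rectangle split along the long axis
        pts = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
        labels = np.array([0, 0, 1, 1])
        expected = brute_force_silhouette(pts, labels)
        assert np.isclose(rc.silhouette(pts, labels), expected, rtol=1e-12)
        # by symmetry: a = 1, b = mean(10, sqrt(101)) for every point
        b = (10 + np.sqrt(101)) / 2
        assert np.isclose(expected, (b - 1) / b)

    def test_two_singleton_clusters_dbi_zero(self):
        pts = np.array([[0.0, 0], [5, 5]])
        assert rc.davies_bouldin(pts, np.array([0, 1]), pts) == 0.0

    def test_symmetric_pairs_dbi(self):
        # two 2-point clusters, spread s=1, center distance D=20 -> 2s/D
        pts = np.array([[-1.0, 0], [1, 0], [19, 0], [21, 0]])
        labels = np.array([0, 0, 1, 1])
        centers = np.array([[0.0, 0], [20, 0]])
        assert np.isclose(rc.davies_bouldin(pts, labels, centers), 2 / 20)

    def test_coincident_centers_rejected(self):
        pts = np.array([[0.0], [1.0]])
        with pytest.raises(ValueError, match="coincident"):
            rc.davies_bouldin(pts, np.array([0, 1]), np.array([[0.5], [0.5]]))

    def test_single_cluster_silhouette_rejected(self):
        with pytest.raises(ValueError):
            rc.silhouette(np.zeros((3, 2)), np.zeros(3, dtype=int))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(40, 2))
        init = rc.kmeanspp_seed(pts, 3, seed)
        model = rc.kmeans_fit(pts, init)
        assert np.isclose(rc.silhouette(pts, model.assignments),
                          silhouette_score(pts, model.assignments), rtol=1e-9)
        assert np.isclose(
            rc.davies_bouldin(pts, model.assignments, model.centers),
            davies_bouldin_score(pts, model.assignments), rtol=1e-9)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force_loops(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, 30)
        centers = np.array([pts[labels == j].mean(axis=0) for j in range(3)])
        assert np.isclose(rc.silhouette(pts, labels),
                          brute_force_silhouette(pts, labels), rtol=1e-9)
        assert np.isclose(rc.davies_bouldin(pts, labels, centers),
                          brute_force_dbi(pts, labels, centers), rtol=1e-9)


class TestSelectK:
    @staticmethod
    def _blobs(rng, means=((0, 0), (10, 0), (0, 10))):
        return np.vstack([rng.normal(m, 0.5, (30, 2)) for m in means])

    def test_three_blobs_recovered_by_both_criteria(self, rng):
        evaluation, _ = rc.select_k(self._blobs(rng), range(2, 8), seeds=5)
        assert evaluation.chosen_k == 3
        assert evaluation.dbi_k == 3
        assert evaluation.criteria_agree

    def test_singleton_range_trivial(self, rng):
        evaluation, models = rc.select_k(self._blobs(rng), [4], seeds=3)
        assert evaluation.chosen_k == 4 and set(models) == {4}

    def test_deterministic_given_seed_list(self, rng):
        pts = self._blobs(rng)
        e1, _ = rc.select_k(pts, range(2, 6), seeds=[1, 2, 3])
        e2, _ = rc.select_k(pts, range(2, 6), seeds=[1, 2, 3])
        pd.testing.assert_frame_equal(e1.table, e2.table)


class TestAssignQualityLevels:
    @staticmethod
    def _model(centers):
        centers = np.asarray(centers, dtype=float)
        return ClusterModel(k=len(centers), centers=centers,
                            assignments=np.zeros(1, dtype=int),
                            sizes=np.ones(len(centers), dtype=int),
                            inertia=0.0, n_iter=1)

    def test_sorted_by_observed_concentration(self):
        levels = rc.assign_quality_levels(
            self._model([[0.1, 0.9], [0.3, 0.1], [0.2, 0.5]]))
        assert list(levels) == [1, 3, 2]

    def test_printed_centers_rank_in_row_order(self):
        levels = rc.assign_quality_levels(self._model(PRINTED_DIMETHOATE_CENTERS))
        assert list(levels) == [1, 2, 3]

    def test_single_cluster(self):
        assert list(rc.assign_quality_levels(self._model([[0.5, 0.5]]))) == [1]

    def test_tie_broken_by_second_coordinate(self):
        levels = rc.assign_quality_levels(self._model([[0.1, 0.9], [0.1, 0.2]]))
        assert list(levels) == [2, 1]


class TestQualityKMeans:
    def test_estimator_interface(self, rng):
        pts = np.vstack([rng.normal(0, 0.3, (25, 2)), rng.normal(5, 0.3, (25, 2)),
                         rng.normal(10, 0.3, (25, 2))])
        est = rc.QualityKMeans(n_clusters=3, random_state=1)
        assert est.get_params()["n_clusters"] == 3
        est.set_params(n_restarts=5)
        labels = est.fit_predict(pts)
        assert sorted(np.unique(labels)) == [0, 1, 2]
        assert est.cluster_centers_.shape == (3, 2)
        assert np.array_equal(np.sort(est.quality_levels_), [1, 2, 3])
        assert est.model_.sizes.sum() == len(pts)
        # levels rank the centers by concentration
        order = np.argsort(est.cluster_centers_[:, 0])
        assert list(est.quality_levels_[order]) == [1, 2, 3]
        assert np.array_equal(est.predict(pts), labels)

    def test_unknown_param_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            rc.QualityKMeans().set_params(bogus=1)

    def test_standardize_flag_reports_original_units(self, rng):
        pts = np.vstack([rng.normal((0, 0), (1, 100), (30, 2)),
                         rng.normal((5, 500), (1, 100), (30, 2))])
        est = rc.QualityKMeans(n_clusters=2, standardize=True, random_state=0).fit(pts)
        assert est.cluster_centers_[:, 1].max() > 50  # back in raw units
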