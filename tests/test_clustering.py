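"""K-means, SSE scan, elbow suggestion and fingerprints.

The small-n clustering checks use brute-force partition enumeration
and an independent library implementation as oracles.
"""

import itertools
import warnings

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import phenoprint as pp
from phenoprint.clustering import InfeasibleKError, SSECurve, kmeans_fit, sse_scan, suggest_elbow


def _partition_sse(X, labels):
    return sum(
        ((X[labels == lab] - X[labels == lab].mean(axis=0)) ** 2).sum()
        for lab in np.unique(labels)
    )


class TestKMeansFit:
    def test_k1_sse_is_total_deviation_from_grand_mean(self, rng):
        X = rng.random((20, 6))
        model = kmeans_fit(X, k=1, seed=0)
        assert model.sse == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())
        assert set(model.labels) == {1}

    def test_k_equals_n_gives_zero_sse(self, rng):
        X = rng.random((7, 4))
        model = kmeans_fit(X, k=7, seed=0)
        assert model.sse == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_k_rejected(self):
        X = np.ones((5, 3))
        with pytest.raises(InfeasibleKError):
            kmeans_fit(X, k=2, seed=0)

    def test_identical_points_k1(self):
        X = np.ones((5, 3))
        assert kmeans_fit(X, k=1, seed=0).sse == 0.0

    def test_matches_brute_force_on_two_planted_clouds(self, rng):
        # 10 points, two tight clouds far apart: enumerate all 2-partitions
        X = np.vstack([rng.normal(0, 0.1, (5, 3)), rng.normal(8, 0.1, (5, 3))])
        best_sse, best_assign = np.inf, None
        for bits in itertools.product([0, 1], repeat=9):  # fix point 0 in group 0
            labels = np.array((0,) + bits)
            if labels.min() == labels.max():
                continue
            sse = _partition_sse(X, labels)
            if sse < best_sse:
                best_sse, best_assign = sse, labels
        model = kmeans_fit(X, k=2, seed=3)
        assert model.sse == pytest.approx(best_sse, rel=1e-10)
        assert adjusted_rand_score(best_assign, model.labels) == 1.0

    def test_agrees_with_library_kmeans_on_separated_blobs(self, rng):
        centers = rng.normal(0, 10, (4, 8))
        X = np.vstack([c + rng.normal(0, 0.3, (15, 8)) for c in centers])
        ours = kmeans_fit(X, k=4, seed=0, n_restarts=10)
        ref = KMeans(n_clusters=4, n_init=10, random_state=0).fit(X)
        assert ours.sse == pytest.approx(ref.inertia_, rel=1e-9)
        assert adjusted_rand_score(ref.labels_, ours.labels) == 1.0

    def test_deterministic_under_seed(self, rng):
        X = rng.random((40, 5))
        a = kmeans_fit(X, k=3, seed=9)
        b = kmeans_fit(X, k=3, seed=9)
        assert a.sse == b.sse
        assert np.array_equal(a.labels, b.labels)

    def test_sse_path_non_increasing_within_fit(self, rng):
        X = rng.random((200, 10))
        model = kmeans_fit(X, k=6, seed=2, n_restarts=3)
        path = model.sse_path
        assert len(path) >= 1
        assert all(b <= a + 1e-9 for a, b in zip(path, path[1:]))

    def test_labels_ordered_by_centroid_mass(self, rng):
        X = np.vstack([np.full((10, 4), 0.0), np.full((10, 4), 1.0)]) + rng.normal(0, 0.01, (20, 4))
        model = kmeans_fit(X, k=2, seed=0)
        mass = [model.centroids[i].mean() for i in range(2)]
        assert mass[0] < mass[1]
        assert set(model.labels[:10]) == {1} and set(model.labels[10:]) == {2}


class TestSSEScan:
    def test_scan_consistent_with_single_fits(self, rng):
        X = rng.random((30, 4))
        curve = sse_scan(X, k_min=2, k_max=5, seed=4, n_restarts=5)
        assert curve.ks == [2, 3, 4, 5]
        for k, sse in curve.points:
            assert sse == pytest.approx(kmeans_fit(X, k, seed=4, n_restarts=5).sse)

    def test_k_max_larger_than_n_rejected(self, rng):
        with pytest.raises(InfeasibleKError):
            sse_scan(rng.random((5, 3)), k_min=2, k_max=6)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            SSECurve([(2, 5.0), (2, 4.0)])
        with pytest.raises(ValueError):
            SSECurve([(2, -1.0)])


class TestSuggestElbow:
    def test_sharp_bend_is_bracketed(self):
        ks = list(range(2, 13))
        sses = [100.0 - 15.0 * (k - 2) if k <= 6 else 40.0 - 1.0 * (k - 6) for k in ks]
        lo, hi = suggest_elbow(SSECurve(list(zip(ks, sses))))
        assert lo <= 6 <= hi

    def test_linear_curve_returns_full_range_with_warning(self):
        curve = SSECurve([(k, 100.0 - 3.0 * k) for k in range(2, 10)])
        with pytest.warns(UserWarning, match="no discernible elbow"):
            assert suggest_elbow(curve) == (2, 9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            suggest_elbow(SSECurve([(2, 3.0), (3, 2.0), (4, 1.0)]))


class TestFingerprints:
    def test_identical_members_reproduce_image(self, rng):
        img = rng.random((4, 6))
        arr = np.stack([img, img, img])
        fps = pp.fingerprints(arr, {"0": 1, "1": 1, "2": 1})
        assert len(fps) == 1
        np.testing.assert_allclose(fps[0].mean_image, img)
        assert fps[0].n_patients == 3

    def test_mean_of_zero_and_one(self):
        arr = np.zeros((2, 1, 1))
        arr[1, 0, 0] = 1.0
        fps = pp.fingerprints(arr, {"0": 1, "1": 1})
        assert fps[0].mean_image[0, 0] == 0.5

    def test_unassigned_patient_rejected(self, rng):
        with pytest.raises(ValueError, match="no cluster assignment"):
            pp.fingerprints(rng.random((3, 2, 2)), {"0": 1, "1": 1})

    def test_weighted_mean_identity_and_range(self, stack100, model8):
        fps = pp.fingerprints(stack100, model8)
        total = sum(f.n_patients for f in fps)
        assert total == len(stack100)
        weighted = sum(f.n_patients * f.mean_image for f in fps) / total
        np.testing.assert_allclose(weighted, stack100.array.mean(axis=0), atol=1e-12)
        for f in fps:
            assert f.mean_image.min() >= 0.0 and f.mean_image.max() <= 1.0
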