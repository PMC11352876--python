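import numpy as np
import pytest

from szdetect import data, fuzzyfeat as ff
from szdetect.errors import ConfigurationError


def brute_force_fcm(X, c, m, tol, max_iter):
    """Independently coded naive FCM mirroring the package's update order:
    quantile-initialized centers, membership update, center update, objective."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    qs = (np.arange(c) + 0.5) / c
    centers = np.quantile(X, qs, axis=0)
    eps = 1e-12

    def memberships(centers):
        u = np.zeros((n, c))
        for i in range(n):
            d2 = np.array([np.sum((X[i] - centers[k]) ** 2) for k in range(c)])
            zero = d2 <= eps
            if zero.any():
                u[i, zero] = 1.0 / zero.sum()
            else:
                for k in range(c):
                    u[i, k] = 1.0 / np.sum((d2[k] / d2) ** (1.0 / (m - 1.0)))
        return u

    prev = np.inf
    for _ in range(max_iter):
        u = memberships(centers)
        um = u**m
        centers = np.zeros((c, d))
        for k in range(c):
            centers[k] = (um[:, k] @ X) / (um[:, k].sum() + eps)
        obj = 0.0
        for i in range(n):
            for k in range(c):
                obj += um[i, k] * np.sum((X[i] - centers[k]) ** 2)
        if abs(prev - obj) < tol:
            break
        prev = obj
    return centers, memberships(centers)


class TestWindowSegments:
    def test_single_full_window(self, rng):
        rec = data.EEGRecord(rng.normal(size=300), fs=100.0)
        segs = ff.window_segments(rec, 300, 0.0)
        assert len(segs) == 1
        np.testing.assert_array_equal(segs[0], rec.samples)

    def test_bonn_geometry_31_segments(self, rng):
        # floor((4097 - 256) / 128) + 1 = 31 by hand
        rec = data.EEGRecord(rng.normal(size=4097), fs=data.BONN_FS)
        assert len(ff.window_segments(rec, 256, 0.5)) == 31

    def test_extreme_overlap_guarded(self, rng):
        rec = data.EEGRecord(rng.normal(size=1024), fs=100.0)
        segs = ff.window_segments(rec, 256, 0.99)
        assert all(len(s) == 256 for s in segs)
        assert len(segs) == len(range(0, 1024 - 256 + 1, 3))

    def test_window_too_large_rejected(self, rng):
        rec = data.EEGRecord(rng.normal(size=100), fs=100.0)
        with pytest.raises(ConfigurationError):
            ff.window_segments(rec, 101)


class TestStatFeatures:
    def test_constant_segment_conventions(self):
        fv = ff.stat_features(np.full(100, 7.0))
        assert fv.variance == 0.0
        assert fv.shannon_entropy == 0.0
        assert fv.skewness == 0.0
        assert fv.kurtosis == 0.0

    def test_hand_arithmetic_population_moments(self):
        fv = ff.stat_features([1.0, 2.0, 3.0, 4.0])
        assert fv.mean == pytest.approx(2.5)
        assert fv.variance == pytest.approx(1.25)  # population variance
        assert fv.standard_deviation == pytest.approx(np.sqrt(1.25))

    def test_sixteen_equal_bins_entropy_4_bits(self):
        x = np.repeat(np.arange(16) + 0.5, 100)
        fv = ff.stat_features(x)
        assert fv.shannon_entropy == pytest.approx(4.0)

    def test_std_is_sqrt_variance(self, rng):
        fv = ff.stat_features(rng.normal(size=500))
        assert fv.standard_deviation == pytest.approx(np.sqrt(fv.variance), abs=1e-12)

    def test_gaussian_kurtosis_non_excess(self, rng):
        fv = ff.stat_features(rng.normal(size=200_00))
        assert fv.kurtosis == pytest.approx(3.0, abs=0.2)

    def test_too_short_rejected(self):
        with pytest.raises(ConfigurationError):
            ff.stat_features([1.0])


class TestFCM:
    def test_c1_closed_form(self, rng):
        X = rng.normal(size=(30, 4))
        res = ff.fcm_fit(X, ff.FCMConfig(n_clusters=1))
        np.testing.assert_array_equal(res.memberships, np.ones((30, 1)))
        np.testing.assert_allclose(res.centers[0], X.mean(axis=0))

    def test_two_separated_clouds(self, rng):
        a = rng.normal(0.0, 1.0, size=(20, 2))
        b = rng.normal(10.0, 1.0, size=(20, 2))
        X = np.vstack([a, b])
        res = ff.fcm_fit(X, ff.FCMConfig(n_clusters=2))
        u = res.memberships
        # cluster owning the first cloud
        own = np.argmax(u[:20].mean(axis=0))
        assert np.all(u[:20, own] >= 0.9)
        assert np.all(u[20:, 1 - own] >= 0.9)

    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(40, 3)) + np.repeat([[0.0], [4.0]], 20, axis=0)
        cfg = ff.FCMConfig(n_clusters=2, m=2.0, tolerance=1e-7, max_iter=200)
        res = ff.fcm_fit(X, cfg)
        centers, u = brute_force_fcm(X, 2, 2.0, 1e-7, 200)
        np.testing.assert_allclose(res.centers, centers, atol=1e-6)
        np.testing.assert_allclose(res.memberships, u, atol=1e-6)

    def test_memberships_row_stochastic(self, rng):
        X = rng.normal(size=(25, 5))
        res = ff.fcm_fit(X, ff.FCMConfig(n_clusters=3))
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.memberships >= 0) and np.all(res.memberships <= 1)

    def test_objective_non_increasing(self, rng):
        X = rng.normal(size=(30, 3))
        res = ff.fcm_fit(X, ff.FCMConfig(n_clusters=2))
        traj = np.array(res.objective_trajectory)
        assert np.all(np.diff(traj) <= 1e-8 * max(1.0, traj[0]))

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(30, 3))
        perm = rng.permutation(30)
        res = ff.fcm_fit(X, ff.FCMConfig(n_clusters=2))
        res_p = ff.fcm_fit(X[perm], ff.FCMConfig(n_clusters=2))
        np.testing.assert_allclose(res_p.memberships, res.memberships[perm], atol=1e-9)

    def test_coincident_point_full_membership(self):
        X = np.array([[0.0, 0.0], [10.0, 10.0], [0.0, 0.0], [10.0, 10.0]])
        res = ff.fcm_fit(X, ff.FCMConfig(n_clusters=2, max_iter=50))
        # points sitting exactly on a center get membership 1 there
        assert np.allclose(np.sort(res.memberships.max(axis=1)), 1.0)

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            ff.fcm_fit(rng.normal(size=(3, 2)), ff.FCMConfig(n_clusters=4))


class TestSelectFeatures:
    def _toy(self, rng, n=40):
        # column 0 separates two clouds, column 1 is pure noise
        signal = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(8, 1, n // 2)])
        noise = rng.normal(0, 1, n)
        X = ff.FeatureMatrix(np.column_stack([signal, noise]), ("signal", "noise"))
        res = ff.fcm_fit(X.values, ff.FCMConfig(n_clusters=2))
        return X, res

    def test_informative_column_selected(self, rng):
        X, res = self._toy(rng)
        out = ff.select_features(res, X, k=1)
        assert out.column_names[0] == "signal"
        assert out.n_cols == 1 + 2  # k columns + c membership columns

    def test_all_columns_plus_memberships(self, rng):
        X, res = self._toy(rng)
        out = ff.select_features(res, X, k=2)
        assert out.column_names[:2] == ("signal", "noise")
        assert out.column_names[2:] == ("membership_0", "membership_1")
        np.testing.assert_array_equal(out.values[:, :2], X.values)

    def test_constant_column_ranked_last(self, rng):
        n = 40
        signal = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(8, 1, n // 2)])
        const = np.zeros(n)
        X = ff.FeatureMatrix(np.column_stack([const, signal]), ("const", "signal"))
        res = ff.fcm_fit(X.values, ff.FCMConfig(n_clusters=2))
        scores = ff.feature_scores(res, X)
        assert scores[0] == pytest.approx(0.0, abs=1e-9)
        assert scores[1] > scores[0]

    def test_score_matches_direct_computation(self, rng):
        X, res = self._toy(rng)
        scores = ff.feature_scores(res, X)
        # direct oracle for c=2
        um = res.memberships**res.m
        sep = np.abs(res.centers[0] - res.centers[1])
        sq = um[:, 0] @ (X.values - res.centers[0]) ** 2 + \
            um[:, 1] @ (X.values - res.centers[1]) ** 2
        spread = np.sqrt(sq / um.sum())
        np.testing.assert_allclose(scores, sep / (spread + 1e-12), rtol=1e-9)

    def test_k_zero_rejected(self, rng):
        X, res = self._toy(rng)
        with pytest.raises(ConfigurationError):
            ff.select_features(res, X, k=0)

    def test_export_round_trip_header(self, tmp_path, rng):
        X, res = self._toy(rng)
        out = ff.select_features(res, X, k=2)
        path = ff.export_features(out, tmp_path / "features.tsv")
        header = path.read_text().splitlines()[0]
        assert header.split("\t") == list(out.column_names)
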