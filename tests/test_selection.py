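"""Feature-ranking behaviour: planted signals, symmetries, path order."""

from __future__ import annotations

import numpy as np
import pytest

from ppgvitals.selection import (FeatureRanking, rank_gp_ard, rank_laplacian,
                                 rank_lasso, rank_relieff, select_top)


def _names(p):
    return [f"f{i}" for i in range(p)]


class TestGpArd:
    def test_single_signal_feature_ranked_first(self):
        """y = 3 x1 + noise among 9 noise features."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(200, 10))
            y = 3.0 * X[:, 0] + 0.3 * rng.normal(size=200)
            r = rank_gp_ard(X, y, names=_names(10))
            hits += r.names[0] == "f0"
        assert hits >= 9

    def test_constant_feature_ranked_last_with_tiny_importance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 6))
        X[:, 4] = 2.0          # constant after bad scaling
        y = X[:, 0] + 0.1 * rng.normal(size=120)
        r = rank_gp_ard(X, y, names=_names(6))
        scores = dict(zip(r.names, r.scores))
        assert scores["f4"] == min(scores.values())   # ties only with other
        assert scores["f4"] < 1e-6                    # ignored features
        assert scores["f4"] > 0

    def test_importances_strictly_positive_and_sorted(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 5))
        y = X[:, 1] - X[:, 3] + 0.2 * rng.normal(size=80)
        r = rank_gp_ard(X, y, names=_names(5))
        assert np.all(r.scores > 0)
        assert np.all(np.diff(r.scores) <= 1e-12)

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="30"):
            rank_gp_ard(rng.normal(size=(20, 3)), rng.normal(size=20))


class TestRelieff:
    def test_identical_feature_gets_max_weight(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 8))
        y = X[:, 2].copy()
        r = rank_relieff(X, y, names=_names(8))
        assert r.names[0] == "f2"

    def test_independent_feature_within_permutation_null(self):
        """Weight of a feature independent of y lies inside +/-3 SD of its
        permutation-null distribution."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 5))
        y = X[:, 0] + 0.2 * rng.normal(size=150)
        w_obs = dict(zip(*[rank_relieff(X, y, names=_names(5)).names,
                           rank_relieff(X, y, names=_names(5)).scores]))["f3"]
        null = []
        for s in range(30):
            yp = np.random.default_rng(50 + s).permutation(y)
            r = rank_relieff(X, yp, names=_names(5))
            null.append(dict(zip(r.names, r.scores))["f3"])
        mu, sd = np.mean(null), np.std(null)
        assert abs(w_obs - mu) <= 3 * sd

    def test_duplicated_feature_weights_equal(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 4))
        X[:, 3] = X[:, 0]
        y = X[:, 0] + 0.1 * rng.normal(size=100)
        r = rank_relieff(X, y, names=_names(4))
        scores = dict(zip(r.names, r.scores))
        assert scores["f0"] == pytest.approx(scores["f3"], abs=1e-9)

    def test_k_reduced_with_warning_when_too_large(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        with pytest.warns(UserWarning, match="reducing"):
            rank_relieff(X, y, k=20, names=_names(3))


class TestLasso:
    def test_strong_feature_enters_path_first(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(500, 6))
        y = 5.0 * X[:, 0] + 0.1 * X[:, 1] + 0.1 * rng.normal(size=500)
        r = rank_lasso(X, y, names=_names(6))
        assert r.names[0] == "f0"
        assert list(r.names).index("f1") < 5

    def test_huge_lambda_shrinks_everything_to_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 4))
        y = X[:, 0] + 0.1 * rng.normal(size=100)
        from sklearn.linear_model import Lasso
        model = Lasso(alpha=1e6).fit(X, y - y.mean())
        assert np.allclose(model.coef_, 0.0)
        # and the ranking still emits all features, scores >= 0
        r = rank_lasso(X, y, lambda_grid=np.array([1e6, 2e6]), names=_names(4))
        assert np.allclose(r.scores, 0.0)

    def test_orthonormal_design_entry_order_is_correlation_order(self):
        """With X'X = n I the path activates features in |X'y| order (the
        soft-threshold closed form)."""
        rng = np.random.default_rng(9)
        A = rng.normal(size=(400, 5))
        Q, _ = np.linalg.qr(A)
        X = Q * np.sqrt(400)            # columns orthonormal scaled to var 1
        beta = np.array([3.0, -2.0, 1.0, 0.5, 0.0])
        y = X @ beta + 0.01 * rng.normal(size=400)
        r = rank_lasso(X, y, names=_names(5))
        corr_order = np.argsort(-np.abs(X.T @ (y - y.mean())))
        assert [int(n[1:]) for n in r.names] == corr_order.tolist()

    def test_zero_variance_column_ranked_last(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(100, 4))
        X[:, 2] = 0.0
        y = X[:, 0] + 0.05 * rng.normal(size=100)
        r = rank_lasso(X, y, names=_names(4))
        assert r.names[-1] == "f2"


class TestLaplacian:
    def _clustered(self, seed=11):
        rng = np.random.default_rng(seed)
        n = 120
        labels = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 6))
        X[:, 0] = labels * 4.0 + 0.05 * rng.normal(size=n)   # cluster indicator
        return X

    def test_cluster_feature_beats_noise_features(self):
        X = self._clustered()
        r = rank_laplacian(X, names=_names(6))
        assert r.names[0] == "f0"

    def test_row_permutation_leaves_scores_unchanged(self):
        X = self._clustered()
        r1 = rank_laplacian(X, names=_names(6))
        perm = np.random.default_rng(12).permutation(X.shape[0])
        r2 = rank_laplacian(X[perm], names=_names(6))
        assert r1.names == r2.names
        assert np.allclose(r1.scores, r2.scores, atol=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="k_neighbors"):
            rank_laplacian(np.zeros((4, 3)), k_neighbors=5)


class TestSelectTopAndInvariance:
    def test_select_top_sizes(self):
        r = FeatureRanking("gp_ard", [f"f{i}" for i in range(107)],
                           np.linspace(1.0, 0.0, 107))
        assert len(select_top(r, 8)) == 8
        assert len(select_top(r, 11)) == 11
        assert select_top(r, 107) == r.names
        with pytest.raises(ValueError):
            select_top(r, 0)
        with pytest.raises(ValueError):
            select_top(r, 108)

    @pytest.mark.parametrize("method", ["gp_ard", "relieff", "lasso"])
    def test_row_permutation_consistency(self, method):
        """Shuffling rows must not change any supervised ranking."""
        from ppgvitals.selection import RANKERS
        rng = np.random.default_rng(13)
        X = rng.normal(size=(80, 6))
        y = 2.0 * X[:, 1] - X[:, 4] + 0.1 * rng.normal(size=80)
        perm = rng.permutation(80)
        r1 = RANKERS[method](X, y, names=_names(6))
        r2 = RANKERS[method](X[perm], y[perm], names=_names(6))
        assert r1.names == r2.names
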