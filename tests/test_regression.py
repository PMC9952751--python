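"""CV-plan arithmetic, model-zoo behaviour, grid determinism, leakage audit."""

from __future__ import annotations

import numpy as np
import pytest

from ppgvitals._gp import ArdGpRegressor
from ppgvitals.regression import (MODEL_ZOO, N_VARIANTS, ModelSpec,
                                  audit_no_leakage, make_cv_plan,
                                  make_grouped_cv_plan, run_grid, train_model)


class TestCvPlan:
    def test_1400_rows_give_280_test_840_train(self):
        plan = make_cv_plan(1400, seed=0)
        for fold in plan.folds:
            assert len(fold["test"]) == 280
            assert len(fold["val"]) == 280
            assert len(fold["train"]) == 840

    def test_test_sets_partition_rows(self):
        plan = make_cv_plan(103, seed=1)
        all_test = np.concatenate([f["test"] for f in plan.folds])
        assert np.array_equal(np.sort(all_test), np.arange(103))
        for f in plan.folds:
            union = np.concatenate([f["train"], f["val"], f["test"]])
            assert np.array_equal(np.sort(union), np.arange(103))

    def test_same_seed_same_plan(self):
        p1, p2 = make_cv_plan(200, seed=5), make_cv_plan(200, seed=5)
        for f1, f2 in zip(p1.folds, p2.folds):
            assert np.array_equal(f1["test"], f2["test"])
            assert np.array_equal(f1["val"], f2["val"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(9)

    def test_grouped_plan_keeps_groups_intact(self):
        groups = np.repeat(np.arange(10), 7)
        plan = make_grouped_cv_plan(groups, seed=2)
        for f in plan.folds:
            test_groups = set(groups[f["test"]])
            train_groups = set(groups[f["train"]])
            assert not (test_groups & train_groups)


class TestModels:
    def test_zoo_has_19_named_variants_in_5_families(self):
        assert set(MODEL_ZOO) == {"gpr", "svr", "ensemble_tree",
                                  "decision_tree", "linear"}
        assert N_VARIANTS == 19

    def test_ols_recovers_exact_line(self):
        X = np.linspace(0, 1, 50).reshape(-1, 1)
        y = 2.0 * X[:, 0] + 1.0
        m = train_model(ModelSpec("linear", "ols"), X, y)
        assert m.model.coef_[0] == pytest.approx(2.0, abs=1e-8)
        assert m.model.intercept_ == pytest.approx(1.0, abs=1e-8)

    def test_deep_tree_fits_step_function_exactly(self):
        X = np.linspace(0, 1, 200).reshape(-1, 1)
        y = (X[:, 0] > 0.5).astype(float) * 3.0
        m = train_model(ModelSpec("decision_tree", "depth16"), X, y)
        assert np.mean((m.predict(X) - y) ** 2) == pytest.approx(0.0, abs=1e-12)

    def test_gpr_beats_mean_baseline(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + 0.1 * rng.normal(size=200)
        tr, va = np.arange(140), np.arange(140, 200)
        m = train_model(ModelSpec("gpr", "ard_se"), X[tr], y[tr])
        pred = m.predict(X[va])
        rmse_gp = np.sqrt(np.mean((pred - y[va]) ** 2))
        rmse_mean = np.sqrt(np.mean((y[tr].mean() - y[va]) ** 2))
        assert rmse_gp < rmse_mean

    def test_variant_chosen_on_validation_only(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 2))
        y = X[:, 0] ** 2 + 0.05 * rng.normal(size=120)
        tr, va = np.arange(80), np.arange(80, 120)
        m = train_model(ModelSpec("decision_tree", None), X[tr], y[tr],
                        X[va], y[va])
        assert m.spec.variant in MODEL_ZOO["decision_tree"]
        assert m.val_rmse is not None

    def test_unknown_family_or_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("neural_net").validate()
        with pytest.raises(ValueError):
            ModelSpec("gpr", "matern52").validate()

    def test_custom_gp_agrees_with_sklearn_gp(self):
        """Independent cross-check: with the same learned kernel, sklearn's
        GP posterior mean matches our implementation."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, WhiteKernel
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 2))
        y = np.sin(X[:, 0]) + 0.3 * X[:, 1] + 0.05 * rng.normal(size=80)
        ours = ArdGpRegressor(ard=True).fit(X, y)
        kernel = (ours.signal_sd_ ** 2
                  * RBF(length_scale=ours.length_scales_, length_scale_bounds="fixed")
                  + WhiteKernel(ours.noise_sd_ ** 2, noise_level_bounds="fixed"))
        sk = GaussianProcessRegressor(kernel=kernel, optimizer=None,
                                      normalize_y=False, alpha=0.0)
        sk.fit(X, y - np.mean(y))
        Xq = rng.normal(size=(20, 2))
        assert np.allclose(ours.predict(Xq),
                           sk.predict(Xq) + np.mean(y), atol=1e-6)

    def test_sklearn_gp_finds_similar_hyperparameters(self):
        """Letting sklearn optimize its own ARD kernel lands near our optimum
        (same marginal-likelihood surface)."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, WhiteKernel
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 2))
        y = np.sin(1.5 * X[:, 0]) + 0.1 * rng.normal(size=100)
        ours = ArdGpRegressor(ard=True).fit(X, y)
        kernel = 1.0 * RBF([1.0, 1.0]) + WhiteKernel(0.1)
        sk = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      random_state=0).fit(X, y)
        sk_ls = sk.kernel_.k1.k2.length_scale
        # relevant dimension: close agreement; irrelevant: both very large
        assert ours.length_scales_[0] == pytest.approx(sk_ls[0], rel=0.5)
        assert ours.length_scales_[1] > 5 * ours.length_scales_[0]


class TestGrid:
    @pytest.fixture(scope="class")
    def toy(self):
        rng = np.random.default_rng(4)
        n, p = 150, 12
        X = rng.normal(size=(n, p))
        y = 10 + 3 * X[:, 0] + np.sin(2 * X[:, 1]) + 0.2 * rng.normal(size=n)
        return X, y

    def test_grid_shape_is_cartesian(self, toy):
        X, y = toy
        plan = make_cv_plan(X.shape[0], seed=0)
        table, details = run_grid(X, y, plan, selectors=("all", "relieff"),
                                  top_n=4, families=("linear", "decision_tree"),
                                  variant={"linear": "ols",
                                           "decision_tree": "depth8"})
        assert len(table) == 4
        assert set(details) == {("all", "linear"), ("all", "decision_tree"),
                                ("relieff", "linear"),
                                ("relieff", "decision_tree")}

    def test_rerun_same_seed_identical_table(self, toy):
        X, y = toy
        plan = make_cv_plan(X.shape[0], seed=0)
        kw = dict(selectors=("relieff",), top_n=4, families=("linear",),
                  variant="ols")
        t1, _ = run_grid(X, y, plan, **kw)
        t2, _ = run_grid(X, y, plan, **kw)
        assert t1.equals(t2)

    def test_failed_cell_recorded_grid_continues(self, toy):
        X, y = toy
        Xbad = X.copy()
        plan = make_cv_plan(X.shape[0], seed=0)
        table, _ = run_grid(Xbad, y, plan, selectors=("gp_ard",), top_n=200,
                            families=("linear",), variant="ols")
        assert table.iloc[0]["n_folds_ok"] == 0
        assert table.iloc[0]["error"] is not None


class TestLeakage:
    def test_audit_passes_for_fold_local_pipeline(self):
        rng = np.random.default_rng(5)
        n, p = 120, 10
        X = rng.normal(size=(n, p))
        X[rng.random(size=(n, p)) < 0.05] = np.nan   # exercise imputation
        y = 2 * np.nan_to_num(X[:, 0]) + 0.3 * rng.normal(size=n)
        plan = make_cv_plan(n, seed=3)
        assert audit_no_leakage(X, y, plan, selector="relieff", top_n=4,
                                family="linear", variant="ols")

    def test_audit_with_variant_choice_and_gp(self):
        rng = np.random.default_rng(6)
        n, p = 100, 6
        X = rng.normal(size=(n, p))
        y = X[:, 0] + 0.1 * rng.normal(size=n)
        plan = make_cv_plan(n, seed=4)
        assert audit_no_leakage(X, y, plan, selector="gp_ard", top_n=3,
                                family="decision_tree", variant=None)

    def test_audit_detects_a_leaky_scaler(self, monkeypatch):
        """Sanity check on the audit itself: a scaler fit on all rows fails."""
        import ppgvitals.regression as reg
        from ppgvitals.features import FeatureScaler

        class LeakyScaler(FeatureScaler):
            def fit(self, X_ignored):
                return super().fit(self._all_rows)

        rng = np.random.default_rng(7)
        n = 60
        X = rng.normal(size=(n, 4))
        y = X[:, 0]
        plan = make_cv_plan(n, seed=5)

        def leaky_fit_fold(X_, y_, fold, *args, **kwargs):
            scaler = LeakyScaler()
            scaler._all_rows = X_
            scaler.fit(None)
            cols = np.arange(X_.shape[1])
            model = train_model(ModelSpec("linear", "ols"),
                                scaler.transform(X_[fold["train"]]), y_[fold["train"]])
            return scaler, cols, None, model

        monkeypatch.setattr(reg, "_fit_fold", leaky_fit_fold)
        with pytest.raises(AssertionError, match="leaked"):
            reg.audit_no_leakage(X, y, plan, selector="all", top_n=None,
                                 family="linear", variant="ols")
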