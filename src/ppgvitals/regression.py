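"""Model training and evaluation under the 5-fold 60/20/20 protocol.

Rows are shuffled once by seed and split into 5 contiguous blocks.  Fold i
uses block i as its test set, block (i+1 mod 5) as validation, and the
remaining three blocks (60 %) for training, so the five test sets partition
the data.  Imputation, standardization, feature ranking and variant choice
are all computed inside each fold from training rows only (validation rows
are used only to pick a model variant); :func:`audit_no_leakage` verifies
mechanically that test rows never influence fitted state.

The model zoo covers five families — Gaussian process regression (ARD
squared-exponential, the headline model), support vector regression,
ensemble trees, single decision trees and linear models — with 19 named
variant presets in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (BaggingRegressor, GradientBoostingRegressor,
                              RandomForestRegressor)
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from ._gp import ArdGpRegressor
from .evaluation import evaluate
from .features import FeatureScaler
from .selection import RANKERS

__all__ = [
    "CVPlan",
    "ModelSpec",
    "TrainedModel",
    "MODEL_ZOO",
    "make_cv_plan",
    "train_model",
    "run_grid",
    "audit_no_leakage",
]

MODEL_ZOO_VERSION = "1.0"


# ---------------------------------------------------------------------------
# Cross-validation plan
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    n_rows: int
    seed: int
    folds: list[dict]   # each: {"train": idx, "val": idx, "test": idx}

    def validate(self) -> None:
        all_test = np.concatenate([f["test"] for f in self.folds])
        if len(np.unique(all_test)) != self.n_rows or all_test.size != self.n_rows:
            raise ValueError("test sets must partition all rows")
        for f in self.folds:
            parts = np.concatenate([f["train"], f["val"], f["test"]])
            if len(np.unique(parts)) != self.n_rows:
                raise ValueError("train/val/test must be disjoint and cover all rows")


def make_cv_plan(n: int, seed: int = 0) -> CVPlan:
    """Shuffle once, split into 5 blocks; fold i tests on block i, validates
    on block (i+1) mod 5, trains on the rest (a 60/20/20 split)."""
    if n < 10:
        raise ValueError(f"need at least 10 rows for a 5-fold 60/20/20 plan, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    blocks = np.array_split(perm, 5)
    folds = []
    for i in range(5):
        test = blocks[i]
        val = blocks[(i + 1) % 5]
        train = np.concatenate([blocks[j] for j in range(5) if j not in (i, (i + 1) % 5)])
        folds.append({"train": np.sort(train), "val": np.sort(val), "test": np.sort(test)})
    plan = CVPlan(n_rows=n, seed=seed, folds=folds)
    plan.validate()
    return plan


def make_grouped_cv_plan(groups: Sequence, seed: int = 0) -> CVPlan:
    """Subject-grouped variant: blocks are unions of whole groups, so
    overlapping windows from one record never straddle folds.  Provided
    because segment-level splitting is a known optimism source."""
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if uniq.size < 5:
        raise ValueError("need at least 5 groups for a grouped 5-fold plan")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq.size)
    gblocks = np.array_split(uniq[order], 5)
    folds = []
    for i in range(5):
        test = np.flatnonzero(np.isin(groups, gblocks[i]))
        val = np.flatnonzero(np.isin(groups, gblocks[(i + 1) % 5]))
        rest = [gblocks[j] for j in range(5) if j not in (i, (i + 1) % 5)]
        train = np.flatnonzero(np.isin(groups, np.concatenate(rest)))
        folds.append({"train": train, "val": val, "test": test})
    plan = CVPlan(n_rows=groups.size, seed=seed, folds=folds)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# Model zoo
# ---------------------------------------------------------------------------

def _zoo() -> dict[str, dict[str, Callable[[], object]]]:
    return {
        "gpr": {
            "ard_se": lambda: ArdGpRegressor(ard=True, random_state=0),
            "iso_se": lambda: ArdGpRegressor(ard=False, random_state=0),
            "iso_se_smooth": lambda: ArdGpRegressor(ard=False, noise_floor=0.1,
                                                    random_state=0),
        },
        "svr": {
            "rbf_c1": lambda: SVR(kernel="rbf", C=1.0, epsilon=0.1),
            "rbf_c10": lambda: SVR(kernel="rbf", C=10.0, epsilon=0.1),
            "linear_c1": lambda: SVR(kernel="linear", C=1.0, epsilon=0.1),
            "linear_c10": lambda: SVR(kernel="linear", C=10.0, epsilon=0.1),
        },
        "ensemble_tree": {
            "random_forest": lambda: RandomForestRegressor(
                n_estimators=200, random_state=0, n_jobs=1),
            "random_forest_small": lambda: RandomForestRegressor(
                n_estimators=50, random_state=0, n_jobs=1),
            "gradient_boosting": lambda: GradientBoostingRegressor(random_state=0),
            "bagged_trees": lambda: BaggingRegressor(
                DecisionTreeRegressor(random_state=0), n_estimators=30, random_state=0),
        },
        "decision_tree": {
            "depth4": lambda: DecisionTreeRegressor(max_depth=4, random_state=0),
            "depth8": lambda: DecisionTreeRegressor(max_depth=8, random_state=0),
            "depth16": lambda: DecisionTreeRegressor(max_depth=16, random_state=0),
            "min_leaf5": lambda: DecisionTreeRegressor(min_samples_leaf=5,
                                                       random_state=0),
        },
        "linear": {
            "ols": lambda: LinearRegression(),
            "ridge": lambda: Ridge(alpha=1.0),
            "lasso": lambda: Lasso(alpha=0.01, max_iter=10000),
            "elastic_net": lambda: ElasticNet(alpha=0.01, max_iter=10000),
        },
    }


MODEL_ZOO = _zoo()
N_VARIANTS = sum(len(v) for v in MODEL_ZOO.values())   # 19 named presets


@dataclass(frozen=True)
class ModelSpec:
    family: str
    variant: str | None = None   # None: choose by validation RMSE

    def validate(self) -> None:
        if self.family not in MODEL_ZOO:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {sorted(MODEL_ZOO)}")
        if self.variant is not None and self.variant not in MODEL_ZOO[self.family]:
            raise ValueError(f"unknown variant {self.variant!r} for {self.family}; "
                             f"choose from {sorted(MODEL_ZOO[self.family])}")


@dataclass
class TrainedModel:
    spec: ModelSpec
    model: object
    target: str = ""
    val_rmse: float | None = None

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.model.predict(np.asarray(X, dtype=float)), dtype=float)


def train_model(spec: ModelSpec, X_train, y_train, X_val=None, y_val=None,
                target: str = "") -> TrainedModel:
    """Fit one family on standardized features.

    With ``spec.variant`` set, that preset is fit on the training rows.  With
    ``variant=None`` every preset of the family is fit on the training rows
    and the one with the lowest validation RMSE is kept — the validation set
    is used for this choice only.
    """
    spec.validate()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if not np.all(np.isfinite(y_train)):
        raise ValueError("training labels must be finite")
    if spec.family == "linear" and np.linalg.matrix_rank(X_train) < X_train.shape[1]:
        warnings.warn("singular design: least-norm linear solution", stacklevel=2)

    if spec.variant is not None:
        model = MODEL_ZOO[spec.family][spec.variant]()
        model.fit(X_train, y_train)
        return TrainedModel(spec=spec, model=model, target=target)

    if X_val is None or y_val is None:
        raise ValueError("variant=None requires a validation set")
    best = None
    for name in MODEL_ZOO[spec.family]:
        model = MODEL_ZOO[spec.family][name]()
        model.fit(X_train, y_train)
        resid = np.asarray(model.predict(np.asarray(X_val, float))) - np.asarray(y_val)
        v_rmse = float(np.sqrt(np.mean(resid ** 2)))
        if best is None or v_rmse < best.val_rmse:
            best = TrainedModel(spec=ModelSpec(spec.family, name), model=model,
                                target=target, val_rmse=v_rmse)
    return best


# ---------------------------------------------------------------------------
# Per-fold pipeline (the only path that touches raw rows)
# ---------------------------------------------------------------------------

def _fit_fold(X: np.ndarray, y: np.ndarray, fold: dict, selector: str,
              top_n: int | None, family: str, variant: str | None,
              feature_names_list: list[str] | None = None,
              cache: dict | None = None, fold_key: int | None = None):
    """Fit scaler, ranking and model for one fold using train(+val) rows only.

    Returns (scaler, selected column indices, ranking or None, trained model).
    Test rows are, by construction, never read here.  ``cache`` (keyed by fold
    and selector) lets a grid reuse the scaler/ranking across model families;
    the cached objects are produced by this same code path.
    """
    tr, va = fold["train"], fold["val"]
    if cache is not None and ("scaler", fold_key) in cache:
        scaler = cache[("scaler", fold_key)]
    else:
        scaler = FeatureScaler().fit(X[tr])
        if cache is not None:
            cache[("scaler", fold_key)] = scaler
    Xtr = scaler.transform(X[tr])
    Xva = scaler.transform(X[va])
    names = feature_names_list or [f"f{i}" for i in range(X.shape[1])]

    ranking = None
    if selector == "all" or top_n is None:
        cols = np.arange(X.shape[1])
    else:
        if cache is not None and ("ranking", fold_key, selector) in cache:
            ranking = cache[("ranking", fold_key, selector)]
        else:
            ranker = RANKERS[selector]
            if selector == "laplacian":
                ranking = ranker(Xtr, names=names)
            else:
                ranking = ranker(Xtr, y[tr], names=names)
            if cache is not None:
                cache[("ranking", fold_key, selector)] = ranking
        chosen = ranking.top(top_n)
        index = {nm: i for i, nm in enumerate(names)}
        cols = np.array([index[nm] for nm in chosen])

    model = train_model(ModelSpec(family, variant), Xtr[:, cols], y[tr],
                        Xva[:, cols], y[va])
    return scaler, cols, ranking, model


def run_grid(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    plan: CVPlan,
    *,
    selectors: Sequence[str] = ("all", "gp_ard", "relieff"),
    top_n: int | dict[str, int] = 8,
    families: Sequence[str] = ("gpr", "linear"),
    variant: str | dict[str, str] | None = None,
    target: str = "",
    feature_names_list: list[str] | None = None,
    units: str = "",
) -> tuple[pd.DataFrame, dict]:
    """Evaluate every (selector, top-n, family) cell under the CV plan.

    Returns a results table (one row per cell: fold-mean MAE, RMSE, R,
    Pearson r, 2SD, bias and LOA) and a details dict keyed by
    ``(selector, family)`` holding the pooled test-set predictions for plots.
    Failures in a cell are recorded and the grid continues.
    """
    if isinstance(X, pd.DataFrame):
        feature_names_list = feature_names_list or list(X.columns)
        X = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rows, details = [], {}
    cache: dict = {}
    for selector in selectors:
        n_sel = (top_n.get(selector) if isinstance(top_n, dict) else top_n) \
            if selector != "all" else None
        for family in families:
            fam_variant = (variant.get(family) if isinstance(variant, dict)
                           else variant)
            fold_reports, pooled_pred, pooled_truth = [], [], []
            error = None
            for fi, fold in enumerate(plan.folds):
                try:
                    scaler, cols, _, model = _fit_fold(
                        X, y, fold, selector, n_sel, family, fam_variant,
                        feature_names_list, cache=cache, fold_key=fi)
                    te = fold["test"]
                    pred = model.predict(scaler.transform(X[te])[:, cols])
                    fold_reports.append(evaluate(pred, y[te], units=units))
                    pooled_pred.append(pred)
                    pooled_truth.append(y[te])
                except Exception as exc:   # record and continue the grid
                    error = f"{type(exc).__name__}: {exc}"
            row = {"target": target, "selector": selector,
                   "top_n": n_sel if n_sel is not None else X.shape[1],
                   "family": family, "n_folds_ok": len(fold_reports),
                   "error": error}
            if fold_reports:
                for metric in ("mae", "rmse", "r_skill", "pearson_r", "two_sd",
                               "bias", "loa_low", "loa_high"):
                    row[metric] = float(np.mean([getattr(r, metric)
                                                 for r in fold_reports]))
                details[(selector, family)] = {
                    "pred": np.concatenate(pooled_pred),
                    "truth": np.concatenate(pooled_truth),
                }
            rows.append(row)
    return pd.DataFrame(rows), details


# ---------------------------------------------------------------------------
# Leakage audit
# ---------------------------------------------------------------------------

def audit_no_leakage(X, y, plan: CVPlan, *, selector: str = "gp_ard",
                     top_n: int = 8, family: str = "gpr",
                     variant: str | None = "ard_se",
                     feature_names_list: list[str] | None = None,
                     rng_seed: int = 12345) -> bool:
    """Verify that test rows never influence fitted state.

    For every fold, the fold pipeline (imputation, standardization, ranking,
    variant choice, model fit) is run twice: once on the original matrix and
    once with the fold's test rows overwritten by random garbage.  Scaler
    parameters, selected features, chosen variant and predictions on a fixed
    probe grid must be identical.  Raises AssertionError on any mismatch.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(rng_seed)
    probe = rng.normal(size=(8, X.shape[1]))
    for i, fold in enumerate(plan.folds):
        Xg, yg = X.copy(), y.copy()
        te = fold["test"]
        Xg[te] = rng.normal(scale=100.0, size=(te.size, X.shape[1]))
        yg[te] = rng.normal(scale=100.0, size=te.size)
        s1, c1, _, m1 = _fit_fold(X, y, fold, selector, top_n, family, variant,
                                  feature_names_list)
        s2, c2, _, m2 = _fit_fold(Xg, yg, fold, selector, top_n, family, variant,
                                  feature_names_list)
        assert np.array_equal(c1, c2), f"fold {i}: feature selection leaked test rows"
        assert np.array_equal(s1.means_, s2.means_) and np.array_equal(
            s1.sds_, s2.sds_) and np.array_equal(s1.medians_, s2.medians_), \
            f"fold {i}: standardization leaked test rows"
        assert m1.spec == m2.spec, f"fold {i}: variant choice leaked test rows"
        p1 = m1.predict(s1.transform(probe)[:, c1])
        p2 = m2.predict(s2.transform(probe)[:, c2])
        assert np.array_equal(p1, p2), f"fold {i}: fitted model leaked test rows"
    return True
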