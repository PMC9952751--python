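"""Feature ranking: GP-ARD relevance, RReliefF, LASSO path order, and the
Laplacian score.

All rankers expect a standardized feature matrix (see
:class:`ppgvitals.features.FeatureScaler`) and return a
:class:`FeatureRanking` with scores sorted non-increasing.  The two headline
rankers for this pipeline are GP-ARD (relevance = exp of the negative learned
length scale) and the regression variant of ReliefF; LASSO entry order and
the unsupervised Laplacian score are provided for comparison sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import lasso_path

from ._gp import ArdGpRegressor
from .features import feature_names

__all__ = [
    "FeatureRanking",
    "rank_gp_ard",
    "rank_relieff",
    "rank_lasso",
    "rank_laplacian",
    "select_top",
]


@dataclass
class FeatureRanking:
    """Ordered feature names with method-specific importance scores."""

    method: str
    names: list[str]
    scores: np.ndarray
    n_selected: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.names) != self.scores.size:
            raise ValueError("names/scores length mismatch")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be sorted non-increasing")

    def top(self, n: int) -> list[str]:
        return select_top(self, n)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "rank": np.arange(1, len(self.names) + 1),
            "name": self.names,
            "score": self.scores,
            "method": self.method,
        })


def _resolve_names(X: np.ndarray, names) -> list[str]:
    if names is not None:
        return list(names)
    if X.shape[1] == 107:
        return feature_names()
    return [f"f{i}" for i in range(X.shape[1])]


def _order_by_score(scores: np.ndarray, names: list[str], method: str,
                    tiebreak: np.ndarray | None = None) -> FeatureRanking:
    """Stable descending sort by score, then tie-break value, then position."""
    tb = np.zeros_like(scores) if tiebreak is None else np.asarray(tiebreak, float)
    order = sorted(range(len(names)), key=lambda i: (-scores[i], -tb[i], i))
    return FeatureRanking(method=method,
                          names=[names[i] for i in order],
                          scores=scores[np.array(order)])


# ---------------------------------------------------------------------------
# GP-ARD ("fitrgp"-style) relevance
# ---------------------------------------------------------------------------

def rank_gp_ard(X: np.ndarray, y: np.ndarray, *, names=None,
                n_restarts: int = 3, max_iter: int = 100,
                random_state: int = 0) -> FeatureRanking:
    """Rank by exp(-length scale) of an ARD squared-exponential GP.

    A feature the GP learns to ignore acquires a very large length scale,
    hence an importance near (but strictly above) zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 30:
        raise ValueError("GP-ARD ranking needs at least 30 rows")
    # a constant column leaves the likelihood flat in its length scale (the
    # optimizer would just keep the init), so exclude it from the fit and pin
    # its importance strictly below any fitted feature's floor
    variable = X.std(axis=0) > 0
    gp = ArdGpRegressor(ard=True, n_restarts=n_restarts, max_iter=max_iter,
                        random_state=random_state)
    gp.fit(X[:, variable], y)
    imp = np.full(X.shape[1], float(np.exp(-500.0)) / 2.0)
    imp[variable] = gp.feature_importances()
    return _order_by_score(imp, _resolve_names(X, names), "gp_ard")


# ---------------------------------------------------------------------------
# RReliefF (regression ReliefF)
# ---------------------------------------------------------------------------

def rank_relieff(X: np.ndarray, y: np.ndarray, k: int = 10, sigma: float = 50.0,
                 *, names=None) -> FeatureRanking:
    """RReliefF weights for a continuous target.

    Every instance is used (no subsampling, for determinism).  For instance i
    with k nearest neighbors j (Euclidean distance, rank-decayed influence
    d_j ~ exp(-(rank_j / sigma)^2), normalized per instance), accumulate

        N_dY      += dy(i,j) * w_ij
        N_dF[f]   += dx_f(i,j) * w_ij
        N_dYdF[f] += dy(i,j) * dx_f(i,j) * w_ij

    with dy and dx_f range-normalized absolute differences, and score

        W_f = N_dYdF[f] / N_dY - (N_dF[f] - N_dYdF[f]) / (m - N_dY).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if k >= n:
        warnings.warn(f"k={k} >= n={n}; reducing to n-1", stacklevel=2)
        k = n - 1
    if k < 1:
        raise ValueError("need at least 2 rows for RReliefF")

    y_range = float(np.ptp(y)) or 1.0
    x_range = np.ptp(X, axis=0)
    x_range[x_range == 0] = 1.0

    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    nn = np.argsort(dist, axis=1, kind="stable")[:, :k]     # (n, k)

    ranks = np.arange(1, k + 1, dtype=float)
    w = np.exp(-((ranks / sigma) ** 2))
    w = w / w.sum()                                          # per-instance weights

    dy = np.abs(y[:, None] - y[nn]) / y_range                # (n, k)
    n_dy = float(np.sum(dy * w))
    dX = np.abs(X[:, None, :] - X[nn]) / x_range             # (n, k, p)
    wk = w[None, :, None]
    n_df = np.sum(dX * wk, axis=(0, 1))                      # (p,)
    n_dydf = np.sum(dX * (dy[:, :, None] * wk), axis=(0, 1))

    m = float(n)   # per-instance weights sum to 1
    if n_dy <= 0 or m - n_dy <= 0:
        scores = np.zeros(p)
    else:
        scores = n_dydf / n_dy - (n_df - n_dydf) / (m - n_dy)
    return _order_by_score(scores, _resolve_names(X, names), "relieff")


# ---------------------------------------------------------------------------
# LASSO regularization-path order
# ---------------------------------------------------------------------------

def rank_lasso(X: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray | None = None,
               *, n_lambdas: int = 100, eps: float = 1e-3,
               names=None) -> FeatureRanking:
    """Rank features by the penalty at which they first enter the LASSO path.

    The score is the largest lambda at which a feature's coefficient is
    nonzero (earlier entry = higher rank); ties are broken by |coefficient| at
    the smallest lambda.  Features never entering the path (including
    zero-variance columns) score 0 and rank last.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    yc = y - np.mean(y)
    if lambda_grid is None:
        # standard path grid: from the smallest lambda shrinking all
        # coefficients to zero down to eps times that
        alpha_max = float(np.max(np.abs(X.T @ yc)) / X.shape[0])
        if alpha_max <= 0:
            alpha_max = 1.0
        lambda_grid = np.logspace(np.log10(alpha_max),
                                  np.log10(alpha_max * eps), n_lambdas)
    alphas, coefs, _ = lasso_path(X, yc,
                                  alphas=np.sort(np.asarray(lambda_grid, float))[::-1])
    # alphas are descending; entry alpha = largest alpha with nonzero coef
    active = np.abs(coefs) > 1e-12                           # (p, n_alphas)
    entry = np.zeros(X.shape[1])
    for f in range(X.shape[1]):
        hits = np.flatnonzero(active[f])
        if hits.size:
            entry[f] = alphas[hits[0]]
    final = np.abs(coefs[:, -1])
    return _order_by_score(entry, _resolve_names(X, names), "lasso", tiebreak=final)


# ---------------------------------------------------------------------------
# Laplacian score (unsupervised)
# ---------------------------------------------------------------------------

def rank_laplacian(X: np.ndarray, k_neighbors: int = 5, *, names=None,
                   heat_t: float | None = None) -> FeatureRanking:
    """Laplacian score: prefer features that vary smoothly on the k-NN graph.

    A heat-kernel weighted symmetric k-NN graph is built on the rows; for each
    feature f (D-centered as f~), the score L_f = f~' L f~ / f~' D f~ is
    computed and mapped to importance -L_f (lower score = more locality-
    preserving = more important).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= k_neighbors:
        raise ValueError(f"need more rows ({n}) than k_neighbors ({k_neighbors})")
    d2 = cdist(X, X, "sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]
    if heat_t is None:
        heat_t = float(np.mean(np.take_along_axis(d2, nn, axis=1))) or 1.0
    S = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k_neighbors)
    cols = nn.ravel()
    S[rows, cols] = np.exp(-d2[rows, cols] / heat_t)
    S = np.maximum(S, S.T)                                   # symmetric kNN graph
    d = S.sum(axis=1)
    ones = np.ones(n)
    scores = np.empty(p)
    for f in range(p):
        fv = X[:, f]
        fc = fv - (fv @ d) / (ones @ d)
        num = fc @ (d * fc) - fc @ (S @ fc)                  # f~' (D - S) f~
        den = fc @ (d * fc)
        scores[f] = num / den if den > 1e-12 else np.inf
    imp = -scores
    imp[~np.isfinite(imp)] = -np.inf
    # replace -inf (degenerate columns) with just below the worst finite score
    finite = imp[np.isfinite(imp)]
    floor = (finite.min() - 1.0) if finite.size else -1.0
    imp[~np.isfinite(imp)] = floor
    return _order_by_score(imp, _resolve_names(X, names), "laplacian")


# ---------------------------------------------------------------------------

def select_top(ranking: FeatureRanking, n: int) -> list[str]:
    """First n names by rank; deterministic given the ranking."""
    if not (1 <= n <= len(ranking.names)):
        raise ValueError(f"n must be in [1, {len(ranking.names)}], got {n}")
    return list(ranking.names[:n])


RANKERS = {
    "gp_ard": rank_gp_ard,
    "relieff": rank_relieff,
    "lasso": rank_lasso,
    "laplacian": rank_laplacian,
}
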