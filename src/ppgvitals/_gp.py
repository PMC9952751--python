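"""Gaussian process regression with an ARD squared-exponential kernel.

    k(x, x') = sf^2 * exp(-0.5 * sum_d (x_d - x'_d)^2 / l_d^2) + sn^2 * 1[x = x']

Hyperparameters (per-dimension length scales l_d, signal SD sf, noise SD sn)
are chosen by maximizing the log marginal likelihood with L-BFGS-B on log
parameters.  The gradient over all length scales is assembled in O(n^2 p)
via matrix products, which keeps ARD tractable at p ~ 100 where generic
per-hyperparameter gradient tensors are prohibitively slow.

Learned length scales double as relevance indicators: a feature the GP can
ignore is driven to a huge length scale, so exp(-l_d) ~ 0.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla
from scipy import optimize as sopt

__all__ = ["ArdGpRegressor", "GpFitError"]

_LOG2PI = float(np.log(2.0 * np.pi))


class GpFitError(RuntimeError):
    """Marginal-likelihood optimization failed after all restarts."""


class ArdGpRegressor:
    """GP regressor with ARD (or isotropic) squared-exponential kernel.

    Parameters
    ----------
    ard : one length scale per feature if True, a single shared one otherwise.
    n_restarts : extra optimizer starts attempted only if the first fails.
    max_iter : L-BFGS-B iteration cap per start.
    noise_floor : lower bound on the noise SD, as a fraction of SD(y).
    """

    #: bounds on the log length scale; the cap l <= 500 keeps the relevance
    #: statistic exp(-l) tiny for ignored features yet strictly positive
    _LOG_L_BOUNDS = (np.log(1e-3), np.log(500.0))

    def __init__(self, ard: bool = True, n_restarts: int = 3, max_iter: int = 200,
                 noise_floor: float = 1e-3, jitter: float = 1e-10,
                 random_state: int = 0) -> None:
        self.ard = ard
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.noise_floor = noise_floor
        self.jitter = jitter
        self.random_state = random_state

    # -- likelihood and gradient -------------------------------------------

    def _nll_and_grad(self, theta: np.ndarray, X: np.ndarray, y: np.ndarray):
        n, p = X.shape
        n_l = p if self.ard else 1
        log_l, log_sf, log_sn = theta[:n_l], theta[n_l], theta[n_l + 1]
        ell = np.exp(log_l)
        sf2 = np.exp(2.0 * log_sf)
        sn2 = np.exp(2.0 * log_sn)

        Z = X / ell if self.ard else X / ell[0]
        sq = np.sum(Z * Z, axis=1)
        D = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
        np.maximum(D, 0.0, out=D)
        Kse = sf2 * np.exp(-0.5 * D)
        K = Kse + (sn2 + self.jitter * sf2) * np.eye(n)
        try:
            L = sla.cholesky(K, lower=True)
        except sla.LinAlgError:
            return np.inf, np.zeros_like(theta)
        alpha = sla.cho_solve((L, True), y)
        nll = 0.5 * float(y @ alpha) + float(np.sum(np.log(np.diag(L)))) + 0.5 * n * _LOG2PI

        Kinv = sla.cho_solve((L, True), np.eye(n))
        A = np.outer(alpha, alpha) - Kinv
        B = A * Kse
        grad = np.empty_like(theta)
        if self.ard:
            s = B.sum(axis=0)
            BX = B @ X
            quad = np.einsum("nd,nd->d", X, BX)
            num = (s @ (X * X)) - quad          # 0.5 * sum_ab B_ab (x_ad - x_bd)^2
            grad[:p] = -(num / ell) / ell       # -0.5 * 2 * num / l^2
        else:
            # d(D)/dlog l = -2 D  =>  dK/dlog l = Kse * D
            grad[0] = -0.5 * float(np.sum(B * D))
        grad[n_l] = -float(np.sum(B))            # dK/dlog sf = 2 Kse
        grad[n_l + 1] = -sn2 * float(np.trace(A))
        return nll, grad

    # -- fitting ------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ArdGpRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n, p) with matching y")
        n, p = X.shape
        self._X = X
        self._y_mean = float(np.mean(y))
        yc = y - self._y_mean
        y_sd = float(np.std(yc))
        if y_sd == 0.0:
            # constant target: trivial mean predictor
            self.length_scales_ = np.full(p, np.exp(self._LOG_L_BOUNDS[1]))
            self.signal_sd_ = 0.0
            self.noise_sd_ = 1e-8
            self._alpha = np.zeros(n)
            self.nll_ = 0.0
            self.converged_ = True
            return self

        n_l = p if self.ard else 1
        l0 = np.full(n_l, np.log(max(1.0, np.sqrt(p))))
        theta0 = np.concatenate([l0, [np.log(y_sd)], [np.log(0.3 * y_sd)]])
        lb = np.concatenate([np.full(n_l, self._LOG_L_BOUNDS[0]),
                             [np.log(1e-6 * y_sd)], [np.log(self.noise_floor * y_sd)]])
        ub = np.concatenate([np.full(n_l, self._LOG_L_BOUNDS[1]),
                             [np.log(1e3 * y_sd)], [np.log(10.0 * y_sd)]])
        bounds = list(zip(lb, ub))

        rng = np.random.default_rng(self.random_state)
        best = None
        last_err = None
        for attempt in range(1 + self.n_restarts):
            start = theta0 if attempt == 0 else np.clip(
                theta0 + rng.normal(0.0, 1.0, size=theta0.size), lb, ub)
            res = sopt.minimize(self._nll_and_grad, start, args=(X, yc),
                                jac=True, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": self.max_iter})
            if np.isfinite(res.fun):
                best = res
                break        # restarts are a failure-recovery path, not a sweep
            last_err = res.message
        if best is None:
            raise GpFitError(f"GP optimization failed after "
                             f"{1 + self.n_restarts} starts: {last_err}")

        theta = best.x
        ell = np.exp(theta[:n_l])
        self.length_scales_ = ell if self.ard else np.full(p, ell[0])
        self.signal_sd_ = float(np.exp(theta[n_l]))
        self.noise_sd_ = float(np.exp(theta[n_l + 1]))
        self.nll_ = float(best.fun)
        self.converged_ = bool(best.success)

        sf2 = self.signal_sd_ ** 2
        sn2 = self.noise_sd_ ** 2
        Z = X / self.length_scales_
        sq = np.sum(Z * Z, axis=1)
        D = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
        np.maximum(D, 0.0, out=D)
        K = sf2 * np.exp(-0.5 * D) + (sn2 + self.jitter * sf2) * np.eye(n)
        L = sla.cholesky(K, lower=True)
        self._alpha = sla.cho_solve((L, True), yc)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = np.asarray(X, dtype=float)
        if self.signal_sd_ == 0.0:
            return np.full(Xs.shape[0], self._y_mean)
        Z = Xs / self.length_scales_
        Zt = self._X / self.length_scales_
        D = (np.sum(Z * Z, axis=1)[:, None] + np.sum(Zt * Zt, axis=1)[None, :]
             - 2.0 * (Z @ Zt.T))
        np.maximum(D, 0.0, out=D)
        Kstar = self.signal_sd_ ** 2 * np.exp(-0.5 * D)
        return Kstar @ self._alpha + self._y_mean

    def feature_importances(self) -> np.ndarray:
        """exp(-length scale) per feature: irrelevant features score ~0."""
        return np.exp(-self.length_scales_)
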