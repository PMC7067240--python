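"""Gaussian-process surrogate for the latent-space objective.

A squared-exponential (RBF) kernel GP with a scalar lengthscale, signal
variance and observation-noise variance, all optimized by maximizing the
exact log marginal likelihood (multi-start L-BFGS on log-parameters with
analytic gradients).  An optional inducing-point mode uses the deterministic
training conditional (DTC) approximation; with the inducing set equal to the
full training set it reproduces the exact posterior, which the tests exploit.

Kriging-Believer batch proposal needs cheap conditioning on hallucinated
observations: :meth:`SurrogateGP.condition` appends one observation with a
rank-one Cholesky update (exact mode) or a refactorization of the small
inducing system (sparse mode), without re-optimizing hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize


class GPError(ValueError):
    pass


@dataclass
class GPConfig:
    n_inducing: int | None = None  # None = exact GP
    n_restarts: int = 2
    noise_floor: float = 1e-6
    jitter: float = 1e-8


def _adaptive_cholesky(K: np.ndarray, scale: float) -> np.ndarray:
    """Lower Cholesky of K + eps*I with the smallest workable jitter."""
    eps = 1e-12 * max(scale, 1.0)
    for _ in range(10):
        try:
            return cholesky(K + eps * np.eye(len(K)), lower=True)
        except np.linalg.LinAlgError:
            eps *= 100.0
    raise GPError("Cholesky factorization failed at maximum jitter")


def _sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.maximum(
        (A**2).sum(1)[:, None] + (B**2).sum(1)[None, :] - 2.0 * A @ B.T, 0.0
    )


class SurrogateGP:
    """RBF-kernel GP posterior over latent points (internal minimization scale)."""

    def __init__(self, X: np.ndarray, y: np.ndarray, config: GPConfig,
                 log_params: np.ndarray):
        self.config = config
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.log_params = np.asarray(log_params, dtype=float)
        self._inducing: np.ndarray | None = None
        if config.n_inducing is not None and config.n_inducing < len(self.X):
            # deterministic subset: first n_inducing rows of the training set
            self._inducing = self.X[: config.n_inducing].copy()
        elif config.n_inducing is not None:
            self._inducing = self.X.copy()
        self._factorize()

    # hyperparameters ------------------------------------------------------

    @property
    def lengthscale(self) -> float:
        return float(np.exp(self.log_params[0]))

    @property
    def signal_var(self) -> float:
        return float(np.exp(self.log_params[1]))

    @property
    def noise_var(self) -> float:
        return float(np.exp(self.log_params[2]) + self.config.noise_floor)

    def _k(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        return self.signal_var * np.exp(-0.5 * _sqdist(A, B) / self.lengthscale**2)

    # factorization --------------------------------------------------------

    def _factorize(self) -> None:
        if self._inducing is None:
            K = self._k(self.X, self.X)
            Ky = K + (self.noise_var + self.config.jitter) * np.eye(len(self.X))
            self._L = cholesky(Ky, lower=True)
            self._alpha = cho_solve((self._L, True), self.y)
        else:
            # whitened DTC: Sigma = Luu (I + A A^T) Luu^T with A = Luu^-1 Kuf / sigma
            Z = self._inducing
            Kuf = self._k(Z, self.X)
            sn = np.sqrt(self.noise_var)
            self._Luu = _adaptive_cholesky(self._k(Z, Z), self.signal_var)
            A = solve_triangular(self._Luu, Kuf, lower=True) / sn
            B = np.eye(len(Z)) + A @ A.T
            self._LB = cholesky(B, lower=True)
            self._w = cho_solve((self._LB, True), A @ self.y) / sn

    # posterior ------------------------------------------------------------

    def posterior(self, Zq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and standard deviation at query points (n, d)."""
        Zq = np.atleast_2d(np.asarray(Zq, dtype=float))
        if self._inducing is None:
            Ks = self._k(Zq, self.X)
            mean = Ks @ self._alpha
            v = solve_triangular(self._L, Ks.T, lower=True)
            var = self.signal_var - (v**2).sum(axis=0)
        else:
            Ksu = self._k(Zq, self._inducing)
            a = solve_triangular(self._Luu, Ksu.T, lower=True)
            mean = a.T @ self._w
            b = solve_triangular(self._LB, a, lower=True)
            var = self.signal_var - (a**2).sum(axis=0) + (b**2).sum(axis=0)
        return mean, np.sqrt(np.maximum(var, 0.0))

    def posterior_mean(self, z: np.ndarray) -> float:
        return float(self.posterior(z)[0][0])

    # Kriging-Believer conditioning ---------------------------------------

    def condition(self, x_new: np.ndarray, y_new: float) -> "SurrogateGP":
        """Return a GP conditioned on one extra observation, hyperparameters
        fixed (rank-one Cholesky update in exact mode)."""
        gp = object.__new__(SurrogateGP)
        gp.config = self.config
        gp.X = np.vstack([self.X, np.atleast_2d(x_new)])
        gp.y = np.append(self.y, y_new)
        gp.log_params = self.log_params
        gp._inducing = self._inducing
        if self._inducing is None:
            k = self._k(self.X, np.atleast_2d(x_new)).ravel()
            kss = self.signal_var + self.noise_var + self.config.jitter
            l_vec = solve_triangular(self._L, k, lower=True)
            d = np.sqrt(max(kss - l_vec @ l_vec, self.config.jitter))
            n = len(self.X)
            L = np.zeros((n + 1, n + 1))
            L[:n, :n] = self._L
            L[n, :n] = l_vec
            L[n, n] = d
            gp._L = L
            gp._alpha = cho_solve((L, True), gp.y)
        else:
            gp._factorize()
        return gp

    # marginal likelihood --------------------------------------------------

    @staticmethod
    def _nll_and_grad(log_params, X, y, config):
        ell2 = np.exp(2 * log_params[0])
        s2 = np.exp(log_params[1])
        sn2 = np.exp(log_params[2]) + config.noise_floor
        D = _sqdist(X, X)
        K = s2 * np.exp(-0.5 * D / ell2)
        Ky = K + (sn2 + config.jitter) * np.eye(len(X))
        try:
            L = cholesky(Ky, lower=True)
        except np.linalg.LinAlgError:
            return 1e25, np.zeros(3)
        alpha = cho_solve((L, True), y)
        nll = 0.5 * y @ alpha + np.log(np.diag(L)).sum() + 0.5 * len(y) * np.log(2 * np.pi)
        Kinv = cho_solve((L, True), np.eye(len(X)))
        W = np.outer(alpha, alpha) - Kinv  # d nll/dθ = -0.5 tr(W dK/dθ)
        dK_dlogell = K * (D / ell2)
        dK_dlogs2 = K
        dK_dlogsn = np.exp(log_params[2]) * np.eye(len(X))
        grad = -0.5 * np.array(
            [(W * dK_dlogell).sum(), (W * dK_dlogs2).sum(), (W * dK_dlogsn).sum()]
        )
        return float(nll), grad


def fit_surrogate(
    X: np.ndarray, y: np.ndarray, config: GPConfig | None = None, seed: int = 0
) -> SurrogateGP:
    """Fit the GP by maximum marginal likelihood; deterministic under seed."""
    config = config or GPConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) < 2:
        raise GPError("need at least 2 observations to fit the surrogate")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise GPError("non-finite inputs to the surrogate")

    med = np.median(_sqdist(X, X)[np.triu_indices(len(X), 1)])
    ell0 = np.log(np.sqrt(med) + 1e-3)
    var0 = np.log(max(y.var(), 1e-4))
    starts = [np.array([ell0, var0, var0 - 4.0])]
    rng = np.random.default_rng(seed)
    for _ in range(max(config.n_restarts - 1, 0)):
        starts.append(starts[0] + rng.normal(scale=0.7, size=3))

    best, best_nll = None, np.inf
    for s in starts:
        res = minimize(
            SurrogateGP._nll_and_grad,
            s,
            args=(X, y, config),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-5, 5), (-5, 5), (-12, 5)],
        )
        if res.fun < best_nll:
            best, best_nll = res.x, res.fun
    return SurrogateGP(X, y, config, best)
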