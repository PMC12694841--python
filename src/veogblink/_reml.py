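"""Random-intercept linear mixed model fit by REML.

Specialized to a single grouping factor with a random intercept, which keeps
everything analytic: each group's covariance block is
``sigma2_e * I + sigma2_u * J``, whose inverse and determinant are closed
form, so the profiled REML criterion is a 1-D optimization in the variance
ratio.  Fixed-effect tests use Wald F statistics with Satterthwaite
denominator degrees of freedom obtained from the observed information of the
variance components (finite differences on the REML criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["FTestResult", "RandomInterceptResult", "fit_reml"]


class SingularFitError(RuntimeError):
    """The design or grouping structure does not permit a fit."""


@dataclass(frozen=True)
class FTestResult:
    fvalue: float
    df_num: float
    df_den: float
    pvalue: float


class _Workspace:
    """Per-fit sufficient statistics; every REML evaluation is O(G p^2)."""

    def __init__(self, y: np.ndarray, X: np.ndarray, group_idx: np.ndarray):
        self.N, self.p = X.shape
        self.G = int(group_idx.max()) + 1
        self.nj = np.bincount(group_idx, minlength=self.G).astype(np.float64)
        if np.any(self.nj == 0):
            raise SingularFitError("grouping factor contains empty levels")
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.SX = np.zeros((self.G, self.p))
        for k in range(self.p):
            self.SX[:, k] = np.bincount(group_idx, weights=X[:, k], minlength=self.G)
        self.Sy = np.bincount(group_idx, weights=y, minlength=self.G)

    def gls(self, lam: float):
        """GLS pieces for V0 = I + lam * Z Z' (unscaled covariance)."""
        c = lam / (1.0 + self.nj * lam)
        A0 = self.XtX - (self.SX.T * c) @ self.SX
        b0 = self.Xty - self.SX.T @ (c * self.Sy)
        q0 = self.yty - float(c @ self.Sy**2)
        beta = np.linalg.solve(A0, b0)
        rss0 = q0 - float(beta @ b0)
        return A0, beta, rss0

    def profiled_m2ll(self, lam: float) -> float:
        A0, _, rss0 = self.gls(lam)
        sigma2 = rss0 / (self.N - self.p)
        sign, logdet = np.linalg.slogdet(A0)
        if sign <= 0 or sigma2 <= 0:
            return np.inf
        return (
            (self.N - self.p) * np.log(sigma2)
            + float(np.sum(np.log1p(self.nj * lam)))
            + logdet
        )

    def m2ll(self, sigma2_u: float, sigma2_e: float) -> float:
        """Unprofiled REML criterion (up to constants) at given components."""
        if sigma2_e <= 0 or sigma2_u < 0:
            return np.inf
        lam = sigma2_u / sigma2_e
        A0, _, rss0 = self.gls(lam)
        sign, logdet = np.linalg.slogdet(A0)
        if sign <= 0:
            return np.inf
        return (
            (self.N - self.p) * np.log(sigma2_e)
            + float(np.sum(np.log1p(self.nj * lam)))
            + logdet
            + rss0 / sigma2_e
        )

    def beta_var(self, c: np.ndarray, sigma2_u: float, sigma2_e: float) -> float:
        """Var(c' beta_hat) = sigma2_e * c' A0(lam)^-1 c."""
        lam = sigma2_u / sigma2_e
        cc = lam / (1.0 + self.nj * lam)
        A0 = self.XtX - (self.SX.T * cc) @ self.SX
        return sigma2_e * float(c @ np.linalg.solve(A0, c))


@dataclass
class RandomInterceptResult:
    params: np.ndarray
    cov_params: np.ndarray
    sigma2_u: float
    sigma2_e: float
    exog_names: list[str]
    n_obs: int
    n_groups: int
    m2ll: float
    _ws: _Workspace

    @property
    def fe_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def _vc_cov(self) -> np.ndarray:
        """Covariance of (sigma2_u, sigma2_e) from the observed information."""
        theta = np.array([max(self.sigma2_u, 0.0), self.sigma2_e])
        h = np.maximum(theta, 1e-3 * self.sigma2_e) * 1e-4
        H = np.empty((2, 2))
        f0 = self._ws.m2ll(*theta)
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                if i == j:
                    fp = self._ws.m2ll(*(theta + ei))
                    fm = self._ws.m2ll(*np.maximum(theta - ei, [0.0, 1e-12]))
                    H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
                else:
                    fpp = self._ws.m2ll(*(theta + ei + ej))
                    fpm = self._ws.m2ll(*np.maximum(theta + ei - ej, [0.0, 1e-12]))
                    fmp = self._ws.m2ll(*np.maximum(theta - ei + ej, [0.0, 1e-12]))
                    fmm = self._ws.m2ll(*np.maximum(theta - ei - ej, [0.0, 1e-12]))
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.full((2, 2), np.nan)
        return cov

    def satterthwaite_df(self, contrast: np.ndarray) -> float:
        """Denominator df for a single fixed-effect contrast."""
        c = np.asarray(contrast, dtype=np.float64)
        theta = np.array([max(self.sigma2_u, 0.0), self.sigma2_e])
        g0 = self._ws.beta_var(c, *theta)
        h = np.maximum(theta, 1e-3 * self.sigma2_e) * 1e-4
        grad = np.empty(2)
        for i in range(2):
            ei = np.zeros(2); ei[i] = h[i]
            lo = np.maximum(theta - ei, [0.0, 1e-12])
            grad[i] = (self._ws.beta_var(c, *(theta + ei)) - self._ws.beta_var(c, *lo)) / (
                theta[i] + ei[i] - lo[i]
            )
        cov_vc = self._vc_cov()
        denom = float(grad @ cov_vc @ grad)
        resid_df = float(self.n_obs - len(self.params))
        if not np.isfinite(denom) or denom <= 0:
            return resid_df
        df = 2.0 * g0**2 / denom
        return float(np.clip(df, 1.0, resid_df))

    def f_test(self, L: np.ndarray) -> FTestResult:
        """Wald F test of ``L beta = 0`` with Satterthwaite denominator df.

        Multi-row hypotheses use the eigencontrast averaging scheme: the
        contrast covariance is diagonalized and single-contrast Satterthwaite
        dfs are pooled through their expected inverse-chi-square moments.
        """
        L = np.atleast_2d(np.asarray(L, dtype=np.float64))
        q = L.shape[0]
        M = L @ self.cov_params @ L.T
        Lb = L @ self.params
        F = float(Lb @ np.linalg.solve(M, Lb)) / q
        if q == 1:
            df2 = self.satterthwaite_df(L[0])
        else:
            vals, vecs = np.linalg.eigh(M)
            dfs = []
            for i in range(q):
                if vals[i] <= 0:
                    continue
                dfs.append(self.satterthwaite_df(vecs[:, i] @ L))
            e_sum = sum(d / (d - 2.0) for d in dfs if d > 2.0)
            df2 = 2.0 * e_sum / (e_sum - q) if e_sum > q else float(self.n_obs)
        p = float(stats.f.sf(F, q, df2))
        return FTestResult(F, float(q), float(df2), p)


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    exog_names: list[str] | None = None,
) -> RandomInterceptResult:
    """Fit ``y = X beta + u[group] + e`` by REML (profiled 1-D search)."""
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    group_idx = np.asarray(group_idx)
    N, p = X.shape
    if y.size != N or group_idx.size != N:
        raise ValueError("y, X and groups must align")
    levels, group_idx = np.unique(group_idx, return_inverse=True)
    G = len(levels)
    if G < 2:
        raise SingularFitError("at least two groups are required")
    if N - p <= 0 or np.linalg.matrix_rank(X) < p:
        raise SingularFitError("fixed-effect design is rank deficient")

    ws = _Workspace(y, X, group_idx)

    res = optimize.minimize_scalar(
        lambda u: ws.profiled_m2ll(np.exp(u)),
        bounds=(-14.0, 14.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    # the boundary (no between-group variance) is a legal optimum
    if ws.profiled_m2ll(0.0) <= res.fun:
        lam = 0.0

    A0, beta, rss0 = ws.gls(lam)
    sigma2_e = rss0 / (N - p)
    sigma2_u = lam * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(A0)
    return RandomInterceptResult(
        params=beta,
        cov_params=cov_beta,
        sigma2_u=float(sigma2_u),
        sigma2_e=float(sigma2_e),
        exog_names=exog_names or [f"x{k}" for k in range(p)],
        n_obs=N,
        n_groups=G,
        m2ll=float(ws.profiled_m2ll(lam)),
        _ws=ws,
    )
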