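"""Statistical layer: correlation matrices, random-intercept mixed models
with Satterthwaite F tests and marginal R-squared, mediation (Sobel +
percentile bootstrap), and Welch's t.

Declared defaults (the source analyses do not document them): REML
estimation, Satterthwaite denominator df, fixed-effect variance-share
marginal R-squared, sample-SD coefficients of variation upstream, raw
(uncorrected) p-values at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from veogblink._reml import FTestResult, RandomInterceptResult, SingularFitError, fit_reml

__all__ = [
    "CorrelationMatrix",
    "MixedModelFit",
    "MediationResult",
    "pearson_matrix",
    "fit_random_intercept",
    "fit_type_interaction",
    "mediation",
    "welch_t",
]


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson matrix with two-sided p-values."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    df: pd.DataFrame  # per-pair n - 2

    def to_frame(self) -> pd.DataFrame:
        """Long-format (var_a, var_b, r, p, df) for the upper triangle."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1 :]:
                rows.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "df": self.df.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def pearson_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlations with t-transform p-values (df = n - 2).

    Pairs are complete-case; a zero-variance column yields NaN entries for
    its pairs rather than an error.
    """
    cols = columns or list(table.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    dof = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            n = len(pair)
            dof[i, j] = dof[j, i] = n - 2
            if n < 3:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = sstats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(
        variables=cols,
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        df=pd.DataFrame(dof, index=cols, columns=cols),
    )


# ---------------------------------------------------------------------------
# mixed models


@dataclass
class MixedModelFit:
    params: dict[str, float]
    se: dict[str, float]
    u0_var: float
    resid_var: float
    f_tests: dict[str, FTestResult]
    r2_marginal: float
    n_obs: int
    n_groups: int
    method: str = "REML"
    df_approximation: str = "satterthwaite"

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "se": self.se,
            "u0_var": self.u0_var,
            "resid_var": self.resid_var,
            "f_tests": {
                term: {
                    "F": t.fvalue,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "p": t.pvalue,
                }
                for term, t in self.f_tests.items()
            },
            "r2_marginal": self.r2_marginal,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "method": self.method,
            "df_approximation": self.df_approximation,
        }


def _marginal_r2(X: np.ndarray, beta: np.ndarray, u0_var: float, resid_var: float) -> float:
    """Fixed-effect variance share of the total outcome variance."""
    fixed = X @ beta
    var_fixed = float(np.var(fixed))
    return var_fixed / (var_fixed + u0_var + resid_var)


def _package_fit(res: RandomInterceptResult, X: np.ndarray, terms: dict[str, list[int]]) -> MixedModelFit:
    names = res.exog_names
    f_tests = {}
    for term, idx in terms.items():
        L = np.zeros((len(idx), len(names)))
        for row, col in enumerate(idx):
            L[row, col] = 1.0
        f_tests[term] = res.f_test(L)
    return MixedModelFit(
        params=dict(zip(names, map(float, res.params))),
        se=dict(zip(names, map(float, res.fe_se))),
        u0_var=res.sigma2_u,
        resid_var=res.sigma2_e,
        f_tests=f_tests,
        r2_marginal=_marginal_r2(X, res.params, res.sigma2_u, res.sigma2_e),
        n_obs=res.n_obs,
        n_groups=res.n_groups,
    )


def fit_random_intercept(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    group: str = "subject",
) -> MixedModelFit:
    """Random-intercept model: outcome ~ predictor + (1 | group), REML.

    The predictor F test uses Satterthwaite denominator df; for a balanced
    design with a between-subject predictor this lands at n_subjects - 2.
    """
    frame = data[[outcome, predictor, group]].dropna()
    counts = frame.groupby(group).size()
    if len(counts) < 2 or (counts < 2).all():
        raise SingularFitError("need >= 2 subjects with repeated observations")
    y = frame[outcome].to_numpy(dtype=float)
    x = frame[predictor].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    res = fit_reml(y, X, frame[group].to_numpy(), ["intercept", predictor])
    return _package_fit(res, X, {predictor: [1]})


def fit_type_interaction(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    type_col: str = "condition",
    group: str = "subject",
    reference: str | None = None,
    levels: list[str] | None = None,
) -> MixedModelFit:
    """Adds a categorical type main effect and a type-by-predictor interaction.

    ``reference`` picks the dummy-coding baseline (default: ``neutral`` if
    present, else the first sorted level).  The predictor is mean-centered so
    the type main effect is evaluated at the average predictor value rather
    than extrapolated to zero (the interaction test is unaffected).  With a
    single observed level the model collapses to
    :func:`fit_random_intercept`.
    """
    frame = data[[outcome, predictor, type_col, group]].dropna()
    observed = sorted(frame[type_col].astype(str).unique())
    if levels is not None:
        empty = sorted(set(levels) - set(observed))
        if empty:
            raise ValueError(f"film-type level(s) without observations: {empty}")
        observed = sorted(levels)
    if len(observed) < 2:
        return fit_random_intercept(frame, outcome, predictor, group)
    if reference is None:
        reference = "neutral" if "neutral" in observed else observed[0]
    if reference not in observed:
        raise ValueError(f"reference level {reference!r} not among {observed}")

    non_ref = [lev for lev in observed if lev != reference]
    y = frame[outcome].to_numpy(dtype=float)
    x = frame[predictor].to_numpy(dtype=float)
    x = x - x.mean()
    cols = [np.ones_like(x), x]
    names = ["intercept", predictor]
    tvals = frame[type_col].astype(str).to_numpy()
    for lev in non_ref:
        cols.append((tvals == lev).astype(float))
        names.append(f"{type_col}[{lev}]")
    for lev in non_ref:
        cols.append((tvals == lev).astype(float) * x)
        names.append(f"{type_col}[{lev}]:{predictor}")
    X = np.column_stack(cols)
    res = fit_reml(y, X, frame[group].to_numpy(), names)
    q = len(non_ref)
    terms = {
        predictor: [1],
        type_col: list(range(2, 2 + q)),
        f"{type_col}:{predictor}": list(range(2 + q, 2 + 2 * q)),
    }
    return _package_fit(res, X, terms)


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    a_path: float
    a_se: float
    b_path: float
    b_se: float
    c_prime: float
    c_prime_se: float
    c_prime_p: float
    indirect: float
    sobel_z: float
    sobel_p: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_boot: int
    seed: int | None
    n: int

    def to_dict(self) -> dict:
        return {
            "a_path": self.a_path,
            "a_se": self.a_se,
            "b_path": self.b_path,
            "b_se": self.b_se,
            "c_prime": self.c_prime,
            "c_prime_se": self.c_prime_se,
            "c_prime_p": self.c_prime_p,
            "indirect": self.indirect,
            "sobel_z": self.sobel_z,
            "sobel_p": self.sobel_p,
            "bootstrap_ci": [self.ci_low, self.ci_high],
            "ci_level": self.ci_level,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n": self.n,
        }


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and classic standard errors."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


def _sobel(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    se = math.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
    z = a * b / se
    return z, 2.0 * sstats.norm.sf(abs(z))


def mediation(
    x,
    m,
    y,
    n_boot: int = 5000,
    seed: int | None = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Single-mediator model x -> m -> y with Sobel test and bootstrap CI.

    a is the slope of m ~ x; b and the direct effect c' come from
    y ~ x + m.  The indirect effect is a*b; its Sobel z uses the
    delta-method SE, and a seeded percentile bootstrap provides the CI.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if not (m.size == n and y.size == n):
        raise ValueError("x, m, y must have equal length")
    if n < 10:
        raise ValueError("mediation requires n >= 10 complete triples")
    if abs(np.corrcoef(x, m)[0, 1]) > 1 - 1e-12:
        raise ValueError("x and m are collinear; mediation model is degenerate")

    ones = np.ones(n)

    def paths(xv, mv, yv):
        beta_a, se_a_ = _ols(mv, np.column_stack([ones[: len(xv)], xv]))
        beta_y, se_y_ = _ols(yv, np.column_stack([ones[: len(xv)], xv, mv]))
        return beta_a[1], se_a_[1], beta_y[2], se_y_[2], beta_y[1], se_y_[1]

    a, se_a, b, se_b, c_prime, se_c = paths(x, m, y)
    sobel_z, sobel_p = _sobel(a, se_a, b, se_b)
    t_c = c_prime / se_c
    c_prime_p = 2.0 * sstats.t.sf(abs(t_c), n - 3)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for rep in range(n_boot):
            idx = rng.integers(0, n, size=n)
            ab, _, bb, _, _, _ = paths(x[idx], m[idx], y[idx])
            boots[rep] = ab * bb
        alpha = (1.0 - ci_level) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    else:  # Sobel-only mode for simulation studies
        lo = hi = float("nan")

    return MediationResult(
        a_path=float(a),
        a_se=float(se_a),
        b_path=float(b),
        b_se=float(se_b),
        c_prime=float(c_prime),
        c_prime_se=float(se_c),
        c_prime_p=float(c_prime_p),
        indirect=float(a * b),
        sobel_z=float(sobel_z),
        sobel_p=float(sobel_p),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        n_boot=n_boot,
        seed=seed,
        n=n,
    )


# ---------------------------------------------------------------------------
# group comparison


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t: returns (t, Welch-Satterthwaite df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance; Welch t is undefined")
    res = sstats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
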