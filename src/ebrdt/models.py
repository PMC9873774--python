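"""Correlation, hierarchical inverted-U regression, robust regression, power.

The central question is whether a divergent-thinking index relates to
sEBR through an inverted U: a hierarchical pair of OLS fits (step 1:
y ~ x; step 2: y ~ x + x^2) is compared through the R^2 increment, and an
MM-type robust refit guards the conclusion against outliers (flagged at
|standardized residual| > 3).  ``required_sample_size`` reproduces the
fixed-model noncentral-F power computation used to plan such studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


# --------------------------------------------------------------------------
# Correlations
# --------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    note: str = "pairwise-complete Pearson, two-sided p"


def correlation_matrix(scores: pd.DataFrame,
                       columns: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson r and two-sided p over the chosen columns.

    Pairs are evaluated on pairwise-complete cases.  A zero-variance
    column gets NaN entries (r undefined) rather than an error.
    """
    cols = columns or list(scores.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = scores[cols[i]].notna().sum()
        for j in range(i + 1, k):
            sub = scores[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(sub)
            if len(sub) < 3:
                raise ValueError("need at least 3 complete cases per pair")
            a, b = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            if a.std() == 0 or b.std() == 0:
                warnings.warn(f"zero variance in {cols[i]} or {cols[j]}; r undefined")
                r[i, j] = r[j, i] = p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(a, b)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(cols)
    return CorrelationMatrix(pd.DataFrame(r, idx, idx), pd.DataFrame(p, idx, idx),
                             pd.DataFrame(n, idx, idx))


# --------------------------------------------------------------------------
# Hierarchical linear/quadratic regression
# --------------------------------------------------------------------------

@dataclass
class RegressionResult:
    step1: pd.DataFrame
    step2: pd.DataFrame
    r2_step1: float
    r2_step2: float
    delta_r2: float
    n: int
    estimator: str
    outliers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator, "n": self.n,
            "r2_step1": self.r2_step1, "r2_step2": self.r2_step2,
            "delta_r2": self.delta_r2,
            "step1": self.step1.to_dict(orient="index"),
            "step2": self.step2.to_dict(orient="index"),
            "outliers": self.outliers.tolist(),
        }


def _coef_table(params, se, names, n) -> pd.DataFrame:
    t = np.asarray(params) / np.where(np.asarray(se) > 0, se, np.nan)
    dof = n - len(params)
    p = 2 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame({"estimate": params, "se": se, "t": t, "p": p}, index=names)


def _standardized(x_cols: list[np.ndarray], y: np.ndarray) -> np.ndarray:
    """Coefficients of the same fit on z-scored variables (betas)."""
    zs = [(c - c.mean()) / c.std(ddof=1) for c in x_cols]
    zy = (y - y.mean()) / y.std(ddof=1)
    X = sm.add_constant(np.column_stack(zs))
    return sm.OLS(zy, X).fit().params[1:]


def hierarchical_quadratic_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS y ~ x, then y ~ x + x^2; reports both steps and the R^2 increment.

    Coefficient tables carry raw-unit estimates plus a ``beta`` column of
    standardized coefficients.  Outliers are observations with internally
    studentized residuals beyond +/-3 in the step-2 fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n <= 4:
        raise ValueError("need n > 4")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: design is collinear")

    X1 = sm.add_constant(np.column_stack([x]))
    X2 = sm.add_constant(np.column_stack([x, x ** 2]))
    f1 = sm.OLS(y, X1).fit()
    f2 = sm.OLS(y, X2).fit()

    t1 = _coef_table(f1.params, f1.bse, ["intercept", "sebr"], n)
    t2 = _coef_table(f2.params, f2.bse, ["intercept", "sebr", "sebr2"], n)
    if y.std() > 0:
        t1["beta"] = np.concatenate([[np.nan], _standardized([x], y)])
        t2["beta"] = np.concatenate([[np.nan], _standardized([x, x ** 2], y)])
    else:
        t1["beta"] = np.nan
        t2["beta"] = np.nan

    resid_std = f2.get_influence().resid_studentized_internal
    outliers = np.flatnonzero(np.abs(resid_std) > 3)
    return RegressionResult(t1, t2, float(f1.rsquared), float(f2.rsquared),
                            float(f2.rsquared - f1.rsquared), n, "OLS", outliers)


# --------------------------------------------------------------------------
# MM-type robust regression
# --------------------------------------------------------------------------

_TUKEY_C = 4.685  # 95 % Gaussian efficiency


def _mm_fit(X: np.ndarray, y: np.ndarray, c: float = _TUKEY_C,
            maxiter: int = 200, tol: float = 1e-10):
    """MM-type fit: LAD start, fixed MAD scale, bisquare IRLS.

    Returns (params, se, scale, weights).  With a perfect initial fit
    (zero residual scale) the LAD solution is returned as-is.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design")
    if np.ptp(y) == 0:
        beta = np.zeros(p)
        beta[0] = y[0]
        return beta, np.zeros(p), 0.0, np.ones(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta = sm.QuantReg(y, X).fit(q=0.5).params
    resid = y - X @ beta
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if scale <= 0:
        return beta, np.zeros(p), 0.0, np.ones(n)
    for _ in range(maxiter):
        r = (y - X @ beta) / scale
        w = np.where(np.abs(r) < c, (1 - (r / c) ** 2) ** 2, 0.0)
        if w.sum() < p:  # pathological: everything downweighted
            break
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    else:
        raise RuntimeError(
            f"MM IRLS did not converge in {maxiter} iterations "
            f"(scale={scale:.3g})")
    # M-estimator sandwich standard errors
    r = (y - X @ beta) / scale
    psi = np.where(np.abs(r) < c, r * (1 - (r / c) ** 2) ** 2, 0.0)
    dpsi = np.where(np.abs(r) < c,
                    (1 - (r / c) ** 2) * (1 - 5 * (r / c) ** 2), 0.0)
    denom = dpsi.mean()
    kappa = (psi ** 2).mean() / denom ** 2 if denom > 0 else np.nan
    cov = kappa * scale ** 2 * np.linalg.inv(X.T @ X) * n / max(n - p, 1)
    se = np.sqrt(np.diag(cov))
    r_final = (y - X @ beta) / scale
    w = np.where(np.abs(r_final) < c, (1 - (r_final / c) ** 2) ** 2, 0.0)
    return beta, se, scale, w


def _robust_r2(X, y, beta, w) -> float:
    """Weighted R^2 analogue using the final bisquare weights."""
    if w.sum() == 0 or np.ptp(y) == 0:
        return 0.0
    ybar = np.average(y, weights=w)
    res = y - X @ beta
    tot = np.sum(w * (y - ybar) ** 2)
    return float(1 - np.sum(w * res ** 2) / tot) if tot > 0 else 0.0


def robust_quadratic_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """The two-step hierarchy with MM-type estimates (bisquare, 95 % eff.).

    The R^2 column is a weighted analogue and is labelled ``robust``;
    outliers are points with |residual/scale| > 3 in step 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n <= 10:
        raise ValueError("need n > 10 for a robust fit")
    X1 = sm.add_constant(np.column_stack([x]))
    X2 = sm.add_constant(np.column_stack([x, x ** 2]))
    b1, se1, s1, w1 = _mm_fit(X1, y)
    b2, se2, s2, w2 = _mm_fit(X2, y)
    t1 = _coef_table(b1, se1, ["intercept", "sebr"], n)
    t2 = _coef_table(b2, se2, ["intercept", "sebr", "sebr2"], n)
    r21 = _robust_r2(X1, y, b1, w1)
    r22 = _robust_r2(X2, y, b2, w2)
    if s2 > 0:
        outliers = np.flatnonzero(np.abs((y - X2 @ b2) / s2) > 3)
    else:
        outliers = np.array([], dtype=int)
    return RegressionResult(t1, t2, r21, r22, r22 - r21, n, "robust-MM", outliers)


# --------------------------------------------------------------------------
# Power / sample size (fixed-model multiple regression)
# --------------------------------------------------------------------------

@dataclass
class PowerSpec:
    f2: float = 0.15
    alpha: float = 0.05
    power: float = 0.80
    n_predictors: int = 3
    numerator_df: int = 1

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")
        if self.f2 <= 0:
            raise ValueError("f2 must be positive")
        if not 1 <= self.numerator_df <= self.n_predictors:
            raise ValueError("numerator_df must be in [1, n_predictors]")


def noncentral_f_power(f2: float, n: int, numerator_df: int,
                       n_predictors: int, alpha: float) -> float:
    """Power of the F test with noncentrality f2*n and dfd = n - p - 1."""
    dfd = n - n_predictors - 1
    if dfd < 1:
        return 0.0
    lam = f2 * n
    fcrit = stats.f.ppf(1 - alpha, numerator_df, dfd)
    return float(stats.ncf.sf(fcrit, numerator_df, dfd, lam))


def required_sample_size(spec: PowerSpec, max_n: int = 1_000_000) -> int:
    """Smallest N whose noncentral-F power reaches the target.

    Mirrors an a-priori fixed-model regression power analysis: testing a
    single coefficient in a 3-predictor model at f2 = 0.15, alpha = .05,
    power = .80 yields N = 55.
    """
    spec.validate()
    n = spec.n_predictors + 2  # smallest N with dfd >= 1
    while n <= max_n:
        if noncentral_f_power(spec.f2, n, spec.numerator_df,
                              spec.n_predictors, spec.alpha) >= spec.power:
            return n
        n += 1
    raise ValueError(f"target power unattainable below N = {max_n}")
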