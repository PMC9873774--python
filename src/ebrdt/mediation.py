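"""Curvilinear mediation with instantaneous indirect effects.

The model: a predictor X (sEBR) affects a mediator M (flexibility)
through a linear-or-quadratic path, M affects the outcome Y (originality)
linearly, and X keeps a linear-or-quadratic direct path to Y:

    M = i_M + a1 X + a2 X^2 + e_M
    Y = i_Y + c1 X + c2 X^2 + b M + e_Y

With a quadratic a-path the indirect effect is no longer a single
product: its strength depends on where you evaluate it.  The
instantaneous indirect effect is

    theta(x) = (a1 + 2 a2 x) * b

i.e. the rate at which a change in X changes Y through M at X = x,
conventionally reported at low/moderate/high predictor values
(mean -/+ 1 SD).  Percentile confidence intervals come from a
case-resampling bootstrap over participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class MediationSpec:
    x_to_m: str = "quadratic"           # "linear" | "quadratic"
    m_to_y: str = "linear"
    direct_x_to_y: str = "quadratic"    # "linear" | "quadratic"
    n_boot: int = 5000
    ci_level: float = 0.95
    seed: int = 0
    eval_points: tuple[float, float, float] | None = None  # None -> mean +/- 1 SD
    center_x: bool = False

    def validate(self) -> None:
        if self.x_to_m not in ("linear", "quadratic"):
            raise ValueError("x_to_m must be 'linear' or 'quadratic'")
        if self.m_to_y != "linear":
            raise ValueError("only a linear M->Y path is supported")
        if self.direct_x_to_y not in ("linear", "quadratic"):
            raise ValueError("direct_x_to_y must be 'linear' or 'quadratic'")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")


@dataclass
class PathCoefficients:
    a1: float
    a2: float     # exactly 0.0 under a linear a-path spec
    b: float
    c1: float
    c2: float
    i_m: float
    i_y: float
    se: dict = field(default_factory=dict)


@dataclass
class MediationResult:
    coefficients: PathCoefficients
    eval_points: tuple[float, float, float]
    theta: np.ndarray                   # point estimates at the 3 eval points
    ci: np.ndarray                      # (3, 2) lower/upper
    n_boot: int
    seed: int
    ci_level: float
    n_failed_resamples: int = 0

    def to_dict(self) -> dict:
        c = self.coefficients
        return {
            "coefficients": {"a1": c.a1, "a2": c.a2, "b": c.b,
                             "c1": c.c1, "c2": c.c2,
                             "i_m": c.i_m, "i_y": c.i_y, "se": c.se},
            "eval_points": list(self.eval_points),
            "theta": self.theta.tolist(),
            "ci": self.ci.tolist(),
            "n_boot": self.n_boot, "seed": self.seed,
            "ci_level": self.ci_level,
            "n_failed_resamples": self.n_failed_resamples,
        }


def _designs(x: np.ndarray, m: np.ndarray, spec: MediationSpec):
    cols_m = [np.ones_like(x), x]
    if spec.x_to_m == "quadratic":
        cols_m.append(x ** 2)
    cols_y = [np.ones_like(x), m, x]
    if spec.direct_x_to_y == "quadratic":
        cols_y.append(x ** 2)
    return np.column_stack(cols_m), np.column_stack(cols_y)


def fit_paths(data: pd.DataFrame, spec: MediationSpec | None = None,
              x: str = "sebr", m: str = "flexibility",
              y: str = "originality") -> PathCoefficients:
    """OLS fits of the two structural equations; returns paths with SEs."""
    spec = spec or MediationSpec()
    spec.validate()
    xv = data[x].to_numpy(dtype=float)
    mv = data[m].to_numpy(dtype=float)
    yv = data[y].to_numpy(dtype=float)
    n_par = 3 + (spec.x_to_m == "quadratic") + (spec.direct_x_to_y == "quadratic") + 2
    if xv.size <= n_par + 2:
        raise ValueError("too few observations for the requested paths")
    Xm, Xy = _designs(xv, mv, spec)
    if (np.linalg.matrix_rank(Xm) < Xm.shape[1]
            or np.linalg.matrix_rank(Xy) < Xy.shape[1]):
        raise ValueError("rank-deficient design")
    fm = sm.OLS(mv, Xm).fit()
    fy = sm.OLS(yv, Xy).fit()
    a2 = float(fm.params[2]) if spec.x_to_m == "quadratic" else 0.0
    c2 = float(fy.params[3]) if spec.direct_x_to_y == "quadratic" else 0.0
    se = {"a1": float(fm.bse[1]), "b": float(fy.bse[1]), "c1": float(fy.bse[2])}
    if spec.x_to_m == "quadratic":
        se["a2"] = float(fm.bse[2])
    if spec.direct_x_to_y == "quadratic":
        se["c2"] = float(fy.bse[3])
    return PathCoefficients(a1=float(fm.params[1]), a2=a2, b=float(fy.params[1]),
                            c1=float(fy.params[2]), c2=c2,
                            i_m=float(fm.params[0]), i_y=float(fy.params[0]),
                            se=se)


def instantaneous_indirect_effect(coefs: PathCoefficients, x_value) -> float:
    """theta(x) = (a1 + 2 a2 x) * b."""
    x_value = np.asarray(x_value, dtype=float)
    out = (coefs.a1 + 2.0 * coefs.a2 * x_value) * coefs.b
    return float(out) if out.ndim == 0 else out


def evaluation_points(x_sample: np.ndarray,
                      rule="mean_sd") -> tuple[float, float, float]:
    """Low/moderate/high predictor values.

    ``mean_sd`` returns (mean - SD, mean, mean + SD) with the n-1 sample
    SD; an explicit 3-sequence is passed through.  A zero-variance sample
    degenerates to three equal points with a warning.
    """
    if rule != "mean_sd":
        low, mod, high = (float(v) for v in rule)
        return low, mod, high
    x = np.asarray(x_sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations for mean +/- SD")
    mu, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0:
        warnings.warn("zero predictor variance: degenerate evaluation points")
    return mu - sd, mu, mu + sd


def _batched_ols(A: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Solve normal equations for a stack of designs: A is (B, n, p)."""
    G = np.einsum("bnp,bnq->bpq", A, A)
    h = np.einsum("bnp,bn->bp", A, yb)
    return np.linalg.solve(G, h[..., None])[..., 0]


def bootstrap_mediation(data: pd.DataFrame, spec: MediationSpec | None = None,
                        x: str = "sebr", m: str = "flexibility",
                        y: str = "originality") -> MediationResult:
    """Case-resampling bootstrap of theta at the sample's eval points.

    Participants are resampled with replacement ``n_boot`` times, both
    equations refit per resample (vectorised normal-equation solves), and
    percentile CIs taken at ``ci_level``.  Evaluation points are fixed at
    the original sample's mean -/+ 1 SD (or an explicit triple).  Under
    ``center_x`` the predictor is mean-centred before squaring; theta at
    the original-scale eval points is invariant to this.
    """
    spec = spec or MediationSpec()
    spec.validate()
    xv = data[x].to_numpy(dtype=float)
    mv = data[m].to_numpy(dtype=float)
    yv = data[y].to_numpy(dtype=float)
    n = xv.size
    if n < 20:
        raise ValueError("need n >= 20 for a bootstrap mediation")

    pts = (spec.eval_points if spec.eval_points is not None
           else evaluation_points(xv))
    shift = xv.mean() if spec.center_x else 0.0
    xw = xv - shift
    pts_w = np.asarray(pts, dtype=float) - shift

    work = pd.DataFrame({x: xw, m: mv, y: yv})
    coefs = fit_paths(work, spec, x, m, y)
    theta = np.asarray([instantaneous_indirect_effect(coefs, p) for p in pts_w])

    rng = np.random.default_rng(spec.seed)
    B = spec.n_boot
    idx = rng.integers(0, n, size=(B, n))
    n_failed = 0
    quad_a = spec.x_to_m == "quadratic"
    quad_c = spec.direct_x_to_y == "quadratic"

    def solve_batch(indices: np.ndarray):
        Xb, Mb, Yb = xw[indices], mv[indices], yv[indices]
        ones = np.ones_like(Xb)
        Am = np.stack([ones, Xb] + ([Xb ** 2] if quad_a else []), axis=-1)
        Ay = np.stack([ones, Mb, Xb] + ([Xb ** 2] if quad_c else []), axis=-1)
        bm = _batched_ols(Am, Mb)
        by = _batched_ols(Ay, Yb)
        a1_b, a2_b = bm[:, 1], (bm[:, 2] if quad_a else np.zeros(len(bm)))
        return a1_b, a2_b, by[:, 1]

    try:
        a1_b, a2_b, b_b = solve_batch(idx)
    except np.linalg.LinAlgError:
        # rare singular resamples: fall back to per-resample solves,
        # redrawing any degenerate resample
        a1_b = np.empty(B)
        a2_b = np.empty(B)
        b_b = np.empty(B)
        for i in range(B):
            row = idx[i:i + 1]
            for _ in range(100):
                try:
                    a1_b[i:i + 1], a2_b[i:i + 1], b_b[i:i + 1] = solve_batch(row)
                    break
                except np.linalg.LinAlgError:
                    n_failed += 1
                    row = rng.integers(0, n, size=(1, n))
            else:
                raise RuntimeError("could not draw a full-rank resample")

    theta_b = (a1_b[:, None] + 2.0 * a2_b[:, None] * pts_w[None, :]) * b_b[:, None]
    alpha = 1.0 - spec.ci_level
    ci = np.quantile(theta_b, [alpha / 2, 1 - alpha / 2], axis=0).T
    return MediationResult(coefficients=coefs, eval_points=tuple(float(p) for p in pts),
                           theta=theta, ci=ci, n_boot=B, seed=spec.seed,
                           ci_level=spec.ci_level, n_failed_resamples=n_failed)
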