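"""Inferential models for movement compositions and mental-health outcomes.

Four pieces:

* a compositional MANCOVA — Wilks' Lambda for a binary group effect on the
  two ilr coordinates, adjusting for covariates, with the exact F transform
  for two responses and one hypothesis degree of freedom;
* pivot-rotated compositional linear regression — OLS of an outcome t-score
  on (ilr1, ilr2) under a chosen pivot basis plus covariates.  The three
  pivot rotations span the same column space, so fitted values, residuals
  and R-squared are identical; only the coefficient labels rotate.  The
  coefficient of interest is the first (pivot) coordinate: time in one
  behavior relative to the geometric mean of the other two;
* Cook's-distance influence screening with the 4/n flagging rule;
* MM-type robust regression (high-breakdown S-estimate start, bisquare
  M-step at 95% Gaussian efficiency) to damp flagged observations.

The regression front-end is the scikit-learn style
:class:`CompositionalRegression` estimator; plain functions wrap it and the
other operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .cohort import INCOME_LEVELS
from .simplex import (
    DEFAULT_LABELS,
    SequentialBinaryPartition,
    ilr_forward,
    make_pivot_sbp,
)

DEFAULT_COVARIATES = ("group", "age", "sex", "income", "ethnicity", "bmi_score")
MANCOVA_COVARIATES = ("age", "sex", "income", "ethnicity")


class EstimationError(ValueError):
    pass


class ConvergenceError(EstimationError):
    def __init__(self, msg, last_coef=None, n_iter=None):
        super().__init__(msg)
        self.last_coef = last_coef
        self.n_iter = n_iter


def code_covariates(
    df: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Numeric design columns for the named covariates.

    Binary codings: group rDCD=1, sex male=1, ethnicity White=1.  Household
    income enters as three indicators against the lowest bracket — the coding
    under which the MANCOVA error degrees of freedom reproduce published
    values for this design (n - 8 = 581 at n = 589).
    """
    cols: dict[str, np.ndarray] = {}
    for c in covariates:
        if c == "group":
            cols["group_rdcd"] = (df["group"].astype(object) == "rDCD").to_numpy(float)
        elif c == "sex":
            cols["sex_male"] = (df["sex"].astype(object) == "male").to_numpy(float)
        elif c == "ethnicity":
            cols["ethnicity_white"] = (
                df["ethnicity"].astype(object) == "White"
            ).to_numpy(float)
        elif c == "income":
            vals = df["income"].astype(object)
            for lev in INCOME_LEVELS[1:]:
                cols[f"income_{lev}"] = (vals == lev).to_numpy(float)
        else:
            cols[c] = df[c].to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        R = np.linalg.qr(arr, mode="r")
        diag = np.abs(np.diag(R))
        bad = [X.columns[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise EstimationError(f"design is rank-deficient; collinear columns: {bad}")


@dataclass(frozen=True)
class MancovaResult:
    wilks_lambda: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n: int
    design_rank: int
    exact: bool = True  # exact F (p=2, 1 hypothesis df) vs Rao approximation

    def to_dict(self) -> dict:
        return {
            "wilks_lambda": self.wilks_lambda,
            "f_stat": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "n": self.n,
            "design_rank": self.design_rank,
            "exact_f": self.exact,
        }


def fit_compositional_mancova(
    ilr_pair: np.ndarray,
    group: Sequence,
    covariates: pd.DataFrame | None = None,
    covariate_names: Sequence[str] = MANCOVA_COVARIATES,
) -> MancovaResult:
    """Wilks' Lambda test of a binary group effect on the two ilr coordinates.

    The hypothesis SSCP is the difference between the error cross-products of
    the reduced (no group) and full models; Lambda = det(E)/det(E + H).  With
    two responses and one hypothesis degree of freedom the F transform is
    exact: F = ((ve - 1)/2) (1 - Lambda)/Lambda on (2, ve - 1) df, where
    ve = n - rank(full design).
    """
    Y = np.atleast_2d(np.asarray(ilr_pair, float))
    if Y.shape[1] != 2:
        raise EstimationError("expected exactly two ilr response columns")
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise EstimationError("group must be binary")
    gd = (g == levels[-1]).astype(float)
    n = Y.shape[0]
    blocks = [np.ones((n, 1))]
    names = ["const"]
    if covariates is not None:
        C = code_covariates(covariates, covariate_names)
        blocks.append(np.asarray(C, float))
        names += list(C.columns)
    X_red = np.column_stack(blocks)
    X_full = np.column_stack([X_red, gd])
    _check_full_rank(pd.DataFrame(X_full, columns=names + ["group"]))

    def err_sscp(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
        return R.T @ R

    E = err_sscp(X_full)
    E_red = err_sscp(X_red)
    det_red = float(np.linalg.det(E_red))
    if det_red <= 0:
        H = E_red - E
        if np.max(np.abs(H)) < 1e-10 * max(1.0, np.max(np.abs(E_red))):
            lam = 1.0  # no group effect and degenerate error geometry
        else:
            raise EstimationError("degenerate error cross-products")
    else:
        lam = float(np.linalg.det(E) / det_red)
    rank = X_full.shape[1]
    ve = n - rank
    p = 2
    df1, df2 = p, ve - p + 1
    if df2 <= 0:
        raise EstimationError("not enough error degrees of freedom")
    if lam <= 0:
        raise EstimationError("degenerate error cross-products")
    f = (df2 / df1) * (1.0 - lam) / lam
    pval = float(stats.f.sf(f, df1, df2))
    return MancovaResult(lam, float(f), df1, df2, pval, n, rank, exact=True)


@dataclass
class LinearFitResult:
    """One fitted linear model (OLS or MM-robust) on a compositional design.

    ``params`` is indexed by design column (const, ilr1, ilr2, covariates);
    ``ilr1`` is the pivot coordinate of ``basis``.  ``cov_params`` is the
    coefficient covariance used for Wald intervals and the isotemporal linear
    forms.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    resid: np.ndarray
    fittedvalues: np.ndarray
    leverage: np.ndarray
    resid_sd: float
    r2: float
    adj_r2: float
    nobs: int
    df_model: int  # predictors excluding the intercept
    method: str  # "ols" | "mm"
    pivot: str
    basis: SequentialBinaryPartition
    design_columns: tuple[str, ...]
    weights: np.ndarray | None = None
    outcome_name: str = "outcome"

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X = np.asarray(design[list(self.design_columns)], float)
        return X @ self.params.to_numpy()


@dataclass(frozen=True)
class InfluenceReport:
    cooks_d: np.ndarray
    threshold: float
    flagged: np.ndarray  # indices with D > 4/n (inf for perfect leverage)

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.size)


def influence_screen(fit: LinearFitResult) -> InfluenceReport:
    """Cook's distance per observation with the 4/n flagging rule.

    D_i = (standardized residual^2 / p) * h_i / (1 - h_i), with p the number
    of estimated coefficients.  Perfect-leverage points (h = 1) get infinite
    influence.
    """
    h = fit.leverage
    p = len(fit.params)
    s2 = fit.resid_sd**2
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (1.0 - h) ** 2
        d = fit.resid**2 * h / (p * s2 * denom)
    d = np.where(h >= 1 - 1e-10, np.inf, d)
    thr = 4.0 / fit.nobs
    return InfluenceReport(d, thr, np.flatnonzero(d > thr))


def adjusted_r2(r2: float, nobs: int, n_predictors: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1), p excluding the intercept."""
    if nobs <= n_predictors + 1:
        raise EstimationError("adjusted R^2 undefined: n <= p + 1")
    return 1.0 - (1.0 - r2) * (nobs - 1) / (nobs - n_predictors - 1)


# ---------------------------------------------------------------------------
# MM robust regression


def _rho_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    """Standardized bisquare rho, rho(inf) = 1."""
    v = np.clip(u / c, -1.0, 1.0)
    return 1.0 - (1.0 - v * v) ** 3


def _psi_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    w = np.where(np.abs(u) <= c, (1.0 - (u / c) ** 2) ** 2, 0.0)
    return u * w


def _w_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    return np.where(np.abs(u) <= c, (1.0 - (u / c) ** 2) ** 2, 0.0)


_C_S = 1.54764  # 50% breakdown bisquare tuning
_C_M = 4.685  # 95% Gaussian efficiency
_B_S = 0.5


def _mscale(resid: np.ndarray, c: float = _C_S, b: float = _B_S) -> float:
    """Solve mean(rho(r/s)) = b for s (bisection; the M-scale of residuals)."""
    r = np.abs(resid)
    if np.all(r < 1e-300):
        return 0.0
    s_lo = np.median(r[r > 0]) / c if np.any(r > 0) else 1e-300
    s_lo = max(s_lo * 1e-6, 1e-300)
    s_hi = r.max() / c * 2 + 1e-300
    f = lambda s: np.mean(_rho_bisquare(r / s, c)) - b
    if f(s_hi) > 0:  # more than b mass at infinity-like scale: widen
        s_hi *= 1e6
    for _ in range(200):
        s_mid = np.sqrt(s_lo * s_hi)
        if f(s_mid) > 0:
            s_lo = s_mid
        else:
            s_hi = s_mid
        if s_hi / s_lo < 1 + 1e-12:
            break
    return float(np.sqrt(s_lo * s_hi))


def _irls(y, X, beta, scale, c, max_iter=200, tol=1e-8, update_scale=False):
    for it in range(max_iter):
        r = y - X @ beta
        if update_scale:
            scale = _mscale(r, _C_S)
            if scale == 0:
                return beta, scale, it, True
        u = r / scale
        w = _w_bisquare(u, c)
        if w.sum() < X.shape[1]:  # degenerate weighting
            w = w + 1e-8
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(WX, w * y, rcond=None)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol * max(1.0, np.max(np.abs(beta))):
            return beta, scale, it + 1, True
    return beta, scale, max_iter, False


def _s_estimate(y, X, rng, n_subsets=50):
    """Fast-S: random elemental starts, short IRLS refinement, keep the best."""
    n, p = X.shape
    best = (np.inf, None)
    for _ in range(n_subsets):
        idx = rng.choice(n, size=p, replace=False)
        try:
            beta0 = np.linalg.solve(X[idx], y[idx])
        except np.linalg.LinAlgError:
            continue
        r = y - X @ beta0
        s = _mscale(r)
        if s == 0:  # exact fit of a subsample extending to all data
            if np.max(np.abs(r)) < 1e-10 * max(1.0, np.max(np.abs(y))):
                return beta0, 0.0
            continue
        beta1, s1, *_ = _irls(y, X, beta0, s, _C_S, max_iter=3, update_scale=True)
        s1 = _mscale(y - X @ beta1)
        if s1 < best[0]:
            best = (s1, beta1)
    if best[1] is None:
        raise EstimationError("S-estimate failed: all elemental subsets singular")
    beta, scale, *_ = _irls(
        y, X, best[1], best[0], _C_S, max_iter=100, update_scale=True
    )
    scale = _mscale(y - X @ beta)
    return beta, scale


def fit_mm(
    y: np.ndarray,
    X: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_subsets: int = 50,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """MM-type robust fit: S-estimate start, bisquare M-step at fixed scale.

    Returns (coefficients, scale, final weights, coefficient covariance).
    The covariance is the standard MM sandwich
    ``s^2 * [n/(n-p)] * mean(psi^2)/mean(psi')^2 * (X'X)^{-1}``.
    """
    Xa = np.asarray(X, float)
    ya = np.asarray(y, float)
    n, p = Xa.shape
    rng = np.random.default_rng(seed)
    beta_s, scale = _s_estimate(ya, Xa, rng, n_subsets)
    if scale < 1e-10 * max(1.0, float(np.std(ya))):  # noiseless: LS is exact
        beta, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
        return beta, 0.0, np.ones(n), np.zeros((p, p))
    beta, _, n_iter, converged = _irls(
        ya, Xa, beta_s, scale, _C_M, max_iter=max_iter, tol=tol
    )
    if not converged:
        raise ConvergenceError(
            f"MM step did not converge in {max_iter} iterations",
            last_coef=beta,
            n_iter=n_iter,
        )
    u = (ya - Xa @ beta) / scale
    w = _w_bisquare(u, _C_M)
    psi = _psi_bisquare(u, _C_M)
    dpsi = np.where(
        np.abs(u) <= _C_M,
        (1 - (u / _C_M) ** 2) * (1 - 5 * (u / _C_M) ** 2),
        0.0,
    )
    k = np.mean(psi**2) / np.mean(dpsi) ** 2
    cov = scale**2 * k * (n / (n - p)) * np.linalg.inv(Xa.T @ Xa)
    return beta, scale, w, cov


# ---------------------------------------------------------------------------
# Regression estimator


def _result_from_arrays(
    params, cov, resid, fitted, leverage, scale, y, method, pivot, basis,
    columns, weights=None, outcome_name="outcome",
) -> LinearFitResult:
    n, k = len(y), len(params)
    bse = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = params / bse
    pvals = 2 * stats.t.sf(np.abs(t), n - k)
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    idx = pd.Index(columns)
    return LinearFitResult(
        params=pd.Series(params, index=idx),
        bse=pd.Series(bse, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
        resid=resid,
        fittedvalues=fitted,
        leverage=leverage,
        resid_sd=scale,
        r2=r2,
        adj_r2=adjusted_r2(r2, n, k - 1),
        nobs=n,
        df_model=k - 1,
        method=method,
        pivot=pivot,
        basis=basis,
        design_columns=tuple(columns),
        weights=weights,
        outcome_name=outcome_name,
    )


class CompositionalRegression(BaseEstimator, RegressorMixin):
    """Pivot-rotated compositional regression of an outcome t-score.

    The design is (const, ilr1, ilr2, covariates) where (ilr1, ilr2) are the
    ilr coordinates of the behavior composition under the basis whose first
    coordinate isolates ``pivot``.  OLS is fitted first; observations with
    Cook's distance above 4/n are screened, and when any are flagged (or
    ``robust=True``) an MM robust fit with bisquare weights becomes the
    headline result.  Both fits remain available as ``ols_`` / ``robust_``.

    Parameters
    ----------
    pivot : str
        Behavior isolated by the first ilr coordinate ("SB", "LPA", "MVPA").
    parts : tuple of str
        Columns of the analysis table holding the behavior minutes.
    covariates : tuple of str
        Covariates entering the adjustment set (see :func:`code_covariates`).
    robust : bool or "auto"
        "auto" refits robustly only when the influence screen fires.
    seed : int
        Seed for the robust S-estimate's subsampling.
    """

    def __init__(
        self,
        pivot: str = "SB",
        parts: tuple[str, ...] = ("sb_min", "lpa_min", "mvpa_min"),
        labels: tuple[str, ...] = DEFAULT_LABELS,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        robust: bool | str = "auto",
        alpha: float = 0.05,
        seed: int = 0,
    ):
        self.pivot = pivot
        self.parts = parts
        self.labels = labels
        self.covariates = covariates
        self.robust = robust
        self.alpha = alpha
        self.seed = seed

    # -- design -----------------------------------------------------------
    def _design(self, X: pd.DataFrame) -> pd.DataFrame:
        basis = make_pivot_sbp(tuple(self.labels), self.pivot)
        comp = X[list(self.parts)].to_numpy(float)
        z = ilr_forward(comp, basis)
        d = pd.DataFrame({"const": 1.0, "ilr1": z[:, 0], "ilr2": z[:, 1]},
                         index=X.index)
        if self.covariates:
            d = pd.concat([d, code_covariates(X, self.covariates)], axis=1)
        self._basis = basis
        return d

    def fit(self, X: pd.DataFrame, y):
        if isinstance(y, str):
            outcome_name, yv = y, X[y].to_numpy(float)
        else:
            outcome_name = getattr(y, "name", "outcome") or "outcome"
            yv = np.asarray(y, float)
        design = self._design(X)
        _check_full_rank(design)
        ols = sm.OLS(yv, design).fit()
        Xa = np.asarray(design, float)
        Q, _ = np.linalg.qr(Xa)
        leverage = np.sum(Q * Q, axis=1)
        self.ols_ = _result_from_arrays(
            ols.params.to_numpy(),
            ols.cov_params().to_numpy(),
            ols.resid,
            ols.fittedvalues,
            leverage,
            float(np.sqrt(ols.mse_resid)),
            yv,
            "ols",
            self.pivot,
            self._basis,
            design.columns,
            outcome_name=outcome_name,
        )
        self.influence_ = influence_screen(self.ols_)
        want_robust = self.robust is True or (
            self.robust == "auto" and self.influence_.n_flagged > 0
        )
        self.robust_ = None
        if want_robust:
            beta, scale, w, cov = fit_mm(yv, design, seed=self.seed)
            self.robust_ = _result_from_arrays(
                beta, cov, yv - Xa @ beta, Xa @ beta, leverage, scale, yv,
                "mm", self.pivot, self._basis, design.columns, weights=w,
                outcome_name=outcome_name,
            )
        self.result_ = self.robust_ if self.robust_ is not None else self.ols_
        self.coef_ = self.result_.params
        self.se_ = self.result_.bse
        self.pvalues_ = self.result_.pvalues
        self.n_features_in_ = design.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        design = self._design(X)
        return self.result_.predict(design)


def fit_compositional_regression(
    outcome: str | Sequence[float],
    analysis_table: pd.DataFrame,
    pivot_behavior: str = "SB",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    robust: bool | str = "auto",
    seed: int = 0,
) -> CompositionalRegression:
    """Fit one pivot-rotated model; returns the fitted estimator."""
    est = CompositionalRegression(
        pivot=pivot_behavior, covariates=tuple(covariates), robust=robust, seed=seed
    )
    return est.fit(analysis_table, outcome)


def fit_robust_regression(
    outcome: np.ndarray, design: pd.DataFrame, seed: int = 0
) -> LinearFitResult:
    """MM robust fit on an explicit design matrix (columns incl. 'const')."""
    yv = np.asarray(outcome, float)
    beta, scale, w, cov = fit_mm(yv, design, seed=seed)
    Xa = np.asarray(design, float)
    Q, _ = np.linalg.qr(Xa)
    leverage = np.sum(Q * Q, axis=1)
    basis = make_pivot_sbp(DEFAULT_LABELS, "SB")
    return _result_from_arrays(
        beta, cov, yv - Xa @ beta, Xa @ beta, leverage, scale, yv,
        "mm", "SB", basis, design.columns, weights=w,
    )
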