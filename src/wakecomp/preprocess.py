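"""Assembly of the analysis table: imputation and closure.

Missing cells are replaced by chained-equations imputation with stochastic
draws: each incomplete variable is regressed on all the others, linear models
with posterior-perturbed coefficients and residual noise for continuous
targets, logistic draws for binary targets and multinomial draws for the
four-level income bracket.  Several completed datasets are generated and one
is selected uniformly at random — single stochastic-regression imputation,
the workable alternative when the downstream compositional stack cannot pool
multiply imputed fits.  Observed cells are never altered.

Behavior minutes are imputed on the ilr scale by default (impute the two ilr
coordinates, back-transform, rescale to the participant's wear time), which
guarantees positive minutes; raw-scale imputation of the minute columns is
available as an option.

After imputation, :func:`build_analysis_table` closes every composition to
the analysis wake window (724 min), verifies the absence of zero parts, and
appends the canonical ilr coordinates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import ACCEL_COLS, INCOME_LEVELS, OUTCOME_COLS, WAKE_WINDOW_MIN
from .simplex import check_zeros, close, ilr_forward, make_default_sbp


class ImputationError(ValueError):
    pass


_BEHAVIOR_COLS = ("sb_min", "lpa_min", "mvpa_min")
_CONTINUOUS = ("age", "bmi_score", "wear_min") + OUTCOME_COLS
_BINARY = {"sex": "male", "ethnicity": "White", "group": "rDCD"}


class ChainedImputer(BaseEstimator, TransformerMixin):
    """MICE-style chained-equations imputer for the cohort schema.

    Parameters
    ----------
    n_imputations : int
        Completed datasets generated; one is picked uniformly at random.
    n_cycles : int
        Gibbs-style sweeps over the incomplete variables per dataset.
    composition_scale : {"ilr", "raw"}
        Impute behavior minutes via the two ilr coordinates (default;
        guarantees positivity) or directly on the minute columns.
    seed : int
        Drives every stochastic draw, including the dataset pick.

    Attributes
    ----------
    imputed_mask_ : DataFrame of bool
        True where the returned cell was imputed.
    chosen_index_ : int
        Which of the ``n_imputations`` completed datasets was returned.
    """

    def __init__(self, n_imputations: int = 5, n_cycles: int = 10,
                 composition_scale: str = "ilr", seed: int = 0):
        self.n_imputations = n_imputations
        self.n_cycles = n_cycles
        self.composition_scale = composition_scale
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        return self

    # -- helpers ----------------------------------------------------------
    def _to_working(self, X: pd.DataFrame) -> pd.DataFrame:
        w = pd.DataFrame(index=X.index)
        for c in _CONTINUOUS:
            if c in X.columns:
                w[c] = X[c].astype(float)
        for c, pos in _BINARY.items():
            if c in X.columns:
                vals = X[c].astype(object)
                w[c] = np.where(vals.isna(), np.nan, (vals == pos).astype(float))
        if "income" in X.columns:
            codes = pd.Categorical(
                X["income"].astype(object), categories=INCOME_LEVELS
            ).codes.astype(float)
            w["income"] = np.where(codes < 0, np.nan, codes)
        if self.composition_scale == "ilr":
            comp = X[list(_BEHAVIOR_COLS)].astype(float)
            ok = comp.notna().all(axis=1)
            z = np.full((len(X), 2), np.nan)
            if ok.any():
                z[ok.to_numpy()] = ilr_forward(
                    comp[ok].to_numpy(), make_default_sbp()
                )
            w["ilr1"], w["ilr2"] = z[:, 0], z[:, 1]
        else:
            for c in _BEHAVIOR_COLS:
                w[c] = X[c].astype(float)
        return w

    def _design(self, w: pd.DataFrame, target: str) -> np.ndarray:
        cols = [c for c in w.columns if c != target]
        blocks = [np.ones((len(w), 1))]
        for c in cols:
            if c == "income":  # expand the 4-level code into indicators
                v = w[c].to_numpy()
                for lev in range(1, len(INCOME_LEVELS)):
                    blocks.append((v == lev).astype(float)[:, None])
            else:
                blocks.append(w[c].to_numpy(float)[:, None])
        return np.hstack(blocks)

    def _impute_continuous(self, y_obs, X_obs, X_mis, rng):
        n, p = X_obs.shape
        beta, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
        resid = y_obs - X_obs @ beta
        dof = max(n - rank, 1)
        sigma = float(np.sqrt(resid @ resid / dof))
        XtX = X_obs.T @ X_obs
        cov = sigma**2 * np.linalg.pinv(XtX)
        # proper stochastic regression: perturb coefficients, then add noise
        try:
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
            beta_draw = beta + L @ rng.standard_normal(p)
        except np.linalg.LinAlgError:
            beta_draw = beta
        return X_mis @ beta_draw + sigma * rng.standard_normal(X_mis.shape[0])

    def _impute_binary(self, y_obs, X_obs, X_mis, rng):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y_obs, X_obs).fit(disp=0, maxiter=100)
            params = np.asarray(res.params, float)
            cov = np.asarray(res.cov_params(), float)
            try:
                L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(params)))
                params = params + L @ rng.standard_normal(len(params))
            except np.linalg.LinAlgError:
                pass
            p = 1.0 / (1.0 + np.exp(-(X_mis @ params)))
        except Exception:  # separation etc.: fall back to the marginal rate
            p = np.full(X_mis.shape[0], float(np.mean(y_obs)))
        return (rng.random(X_mis.shape[0]) < p).astype(float)

    def _impute_income(self, y_obs, X_obs, X_mis, rng):
        k = len(INCOME_LEVELS)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MNLogit(y_obs, X_obs).fit(disp=0, maxiter=100)
            probs = np.asarray(res.predict(X_mis), float)
            if probs.shape[1] != k:
                raise ValueError("level dropped from training data")
        except Exception:
            freq = np.bincount(y_obs.astype(int), minlength=k).astype(float)
            probs = np.tile(freq / freq.sum(), (X_mis.shape[0], 1))
        u = rng.random(X_mis.shape[0])
        return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(float)

    # -- main entry -------------------------------------------------------
    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X.reset_index(drop=True)
        work0 = self._to_working(X)
        mask = work0.isna()
        fully_missing = [c for c in work0.columns if mask[c].all()]
        if fully_missing:
            raise ImputationError(f"variables 100% missing: {fully_missing}")
        incomplete = [c for c in work0.columns if mask[c].any()]
        self.imputed_mask_ = X.isna()
        self.log_ = {
            "n_imputations": self.n_imputations,
            "n_cycles": self.n_cycles,
            "composition_scale": self.composition_scale,
            "incomplete_variables": incomplete,
            "n_missing_cells": int(mask.to_numpy().sum()),
        }
        if not incomplete:
            self.chosen_index_ = 0
            return X.copy()

        ss = np.random.SeedSequence(self.seed)
        pick_rng = np.random.default_rng(ss.spawn(1)[0])
        streams = [
            np.random.default_rng(s)
            for s in np.random.SeedSequence(self.seed + 1).spawn(self.n_imputations)
        ]
        order = sorted(incomplete, key=lambda c: int(mask[c].sum()))
        completed = []
        for rng in streams:
            w = work0.copy()
            for c in incomplete:  # initial fill: draws from the observed values
                obs = work0.loc[~mask[c], c].to_numpy()
                w.loc[mask[c], c] = rng.choice(obs, size=int(mask[c].sum()))
            for _ in range(self.n_cycles):
                for c in order:
                    miss = mask[c].to_numpy()
                    D = self._design(w, c)
                    y_obs = w.loc[~miss, c].to_numpy(float)
                    X_obs, X_mis = D[~miss], D[miss]
                    if c == "income":
                        draw = self._impute_income(y_obs, X_obs, X_mis, rng)
                    elif c in _BINARY:
                        draw = self._impute_binary(y_obs, X_obs, X_mis, rng)
                    else:
                        draw = self._impute_continuous(y_obs, X_obs, X_mis, rng)
                    w.loc[miss, c] = draw
            completed.append(w)

        self.chosen_index_ = int(pick_rng.integers(self.n_imputations))
        self.log_["chosen_index"] = self.chosen_index_
        return self._from_working(X, completed[self.chosen_index_], mask)

    def _from_working(
        self, X: pd.DataFrame, w: pd.DataFrame, mask: pd.DataFrame
    ) -> pd.DataFrame:
        out = X.copy()
        for c in _CONTINUOUS:
            if c in out.columns and c in w.columns:
                out[c] = w[c].to_numpy()
        for c, pos in _BINARY.items():
            if c in out.columns:
                neg = {"sex": "female", "ethnicity": "non-White", "group": "TD"}[c]
                filled = np.where(w[c].to_numpy() >= 0.5, pos, neg)
                out[c] = np.where(X[c].isna(), filled, X[c].astype(object))
        if "income" in out.columns:
            codes = w["income"].to_numpy().astype(int)
            filled = np.array(INCOME_LEVELS, dtype=object)[codes]
            vals = np.where(X["income"].isna(), filled, X["income"].astype(object))
            out["income"] = pd.Categorical(vals, categories=INCOME_LEVELS)
        if self.composition_scale == "ilr":
            z = w[["ilr1", "ilr2"]].to_numpy(float)
            props = np.exp(
                z @ make_default_sbp().contrast_matrix
            )
            props = props / props.sum(axis=1, keepdims=True)
            wear = out["wear_min"].to_numpy(float)
            minutes = props * wear[:, None]
            for j, c in enumerate(_BEHAVIOR_COLS):
                out[c] = np.where(X[c].isna(), minutes[:, j], X[c])
        else:
            for c in _BEHAVIOR_COLS:
                out[c] = np.where(X[c].isna(), w[c].to_numpy(float), X[c])
        return out


def impute_chained(
    table: pd.DataFrame,
    n_imputations: int = 5,
    n_cycles: int = 10,
    composition_scale: str = "ilr",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Impute missing cells; returns (completed table, imputation log)."""
    imp = ChainedImputer(n_imputations, n_cycles, composition_scale, seed)
    completed = imp.fit(table).transform(table)
    log = dict(imp.log_)
    log["imputed_cells"] = int(imp.imputed_mask_.to_numpy().sum())
    return completed, log


def build_analysis_table(
    cohort: pd.DataFrame,
    closed_kappa: float = WAKE_WINDOW_MIN,
    imputed_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Close each row's composition to the wake window and append ilr columns.

    Requires a complete table (run :func:`impute_chained` first).  Each row's
    behavior minutes are rescaled proportionally so they sum to
    ``closed_kappa``; a zero part anywhere is a hard error (no silent
    replacement).  The canonical (SB-pivot) ilr coordinates are appended, and
    per-block provenance flags are carried over from ``imputed_mask`` when
    given.
    """
    if cohort[list(_BEHAVIOR_COLS)].isna().any().any():
        raise ImputationError("behavior minutes contain missing values")
    out = cohort.reset_index(drop=True).copy()
    comp = out[list(_BEHAVIOR_COLS)].to_numpy(float)
    report = check_zeros(comp, labels=_BEHAVIOR_COLS)
    if report:
        raise ImputationError(
            f"zero behavior minutes at {report.entries[:5]}: ilr undefined"
        )
    totals = comp.sum(axis=1)
    closed = comp * (closed_kappa / totals)[:, None]
    out[list(_BEHAVIOR_COLS)] = closed
    z = ilr_forward(closed, make_default_sbp())
    out["ilr1"], out["ilr2"] = z[:, 0], z[:, 1]
    if imputed_mask is not None:
        m = imputed_mask.reset_index(drop=True)
        out["accel_imputed"] = m[list(ACCEL_COLS)].any(axis=1).to_numpy() \
            if set(ACCEL_COLS) <= set(m.columns) else False
        out["outcomes_imputed"] = m[list(OUTCOME_COLS)].any(axis=1).to_numpy() \
            if set(OUTCOME_COLS) <= set(m.columns) else False
    return out
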