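"""Compositional isotemporal substitution.

Given a fitted compositional regression, predict how an outcome changes when
a fixed number of minutes moves from one behavior to another while the wake
window (and the third behavior) stays fixed.  Because the model is linear in
the ilr coordinates, the predicted change for a reallocation is the linear
form ``b' (ilr(new) - ilr(base))`` over the two ilr coefficients: covariates
cancel.  Its variance follows from the coefficient covariance, giving exact
normal-theory confidence intervals for the change.

The reference ("base") composition defaults to the sample compositional
mean, the convention of standard time-use substitution software; any
feasible base may be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import LinearFitResult
from .simplex import (
    Composition,
    InfeasibleReallocationError,
    ilr_forward,
    reallocate,
)

DEFAULT_DELTAS = (5.0, 10.0, 15.0, 20.0, 25.0)


@dataclass(frozen=True)
class BaseComposition:
    """Reference composition (minutes) at which reallocations are anchored."""

    composition: Composition

    def __post_init__(self) -> None:
        if np.any(self.composition.parts <= 0):
            raise ValueError("base composition must be strictly positive")


def build_grid(
    fit: LinearFitResult,
    base: BaseComposition | Composition,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    pairs: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Predicted outcome change with 95% CI for every (pair, delta) cell.

    Columns: outcome, from_behavior, to_behavior, delta_minutes, predicted
    change, ci_low, ci_high, significant.  A reallocation that would exhaust
    the source behavior raises, naming the offending cell.
    """
    comp = base.composition if isinstance(base, BaseComposition) else base
    if pairs is None:
        pairs = list(permutations(comp.labels, 2))
    basis = fit.basis
    z0 = ilr_forward(comp, basis)
    b = fit.params[["ilr1", "ilr2"]].to_numpy()
    cov = fit.cov_params.loc[["ilr1", "ilr2"], ["ilr1", "ilr2"]].to_numpy()
    zcrit = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for frm, to in pairs:
        for d in deltas:
            try:
                new = reallocate(comp, frm, to, float(d))
            except InfeasibleReallocationError as e:
                raise InfeasibleReallocationError(
                    f"reallocation {frm}->{to} of {d} min infeasible at the "
                    f"base composition: {e}"
                ) from e
            dz = ilr_forward(new, basis) - z0
            est = float(dz @ b)
            se = float(np.sqrt(dz @ cov @ dz))
            lo, hi = est - zcrit * se, est + zcrit * se
            rows.append(
                {
                    "outcome": fit.outcome_name,
                    "from_behavior": frm,
                    "to_behavior": to,
                    "delta_minutes": float(d),
                    "predicted_change": est,
                    "ci_low": lo,
                    "ci_high": hi,
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)


def summarize_grid(grid: pd.DataFrame) -> pd.DataFrame:
    """Per-outcome count and listing of significant reallocations."""
    out = []
    for outcome, sub in grid.groupby("outcome", sort=True):
        sig = sub[sub["significant"]]
        out.append(
            {
                "outcome": outcome,
                "n_cells": len(sub),
                "n_significant": len(sig),
                "significant_cells": [
                    f"{r.from_behavior}->{r.to_behavior}@{r.delta_minutes:g}"
                    for r in sig.itertuples()
                ],
            }
        )
    return pd.DataFrame(out)
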