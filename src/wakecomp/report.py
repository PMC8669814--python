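"""Descriptive and model-output tables (markdown) and optional figures."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .models import CompositionalRegression, MancovaResult


def percent(count: int, total: int, dp: int = 1) -> float:
    """Sample-accounting percentage, rounded the way reports print it."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, dp)


def _mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.2f} ({x.std(ddof=1):.2f})"


def descriptives_table(analysis: pd.DataFrame) -> str:
    """Markdown descriptive table: covariates, absolute minutes, % composition.

    The percent rows are per-participant percentages of each participant's
    daily total; their mean/SD summarize the sample like a demographics
    table would.
    """
    n = len(analysis)
    groups = [("Total sample", analysis)]
    if "group" in analysis.columns:
        for gname, sub in analysis.groupby("group", sort=True, observed=True):
            groups.append((f"{gname} (n={len(sub)})", sub))
    lines = [
        "# Descriptive statistics",
        "",
        f"N = {n}",
        "",
        "| Variable | " + " | ".join(name for name, _ in groups) + " |",
        "|---" * (len(groups) + 1) + "|",
    ]

    def row(label, fn):
        lines.append(
            f"| {label} | " + " | ".join(fn(sub) for _, sub in groups) + " |"
        )

    if "age" in analysis.columns:
        row("Age (years)", lambda s: _mean_sd(s["age"]))
    if "sex" in analysis.columns:
        row("Sex (male)", lambda s: f"{(s['sex'] == 'male').sum()} "
            f"({percent((s['sex'] == 'male').sum(), len(s))})")
    if "bmi_score" in analysis.columns:
        row("BMI score", lambda s: _mean_sd(s["bmi_score"]))
    for col, label in [
        ("sb_min", "Sedentary time (min/day)"),
        ("lpa_min", "LPA (min/day)"),
        ("mvpa_min", "MVPA (min/day)"),
        ("wear_min", "Total wear time (min/day)"),
    ]:
        if col in analysis.columns:
            row(label, lambda s, c=col: _mean_sd(s[c]))
    total = analysis[["sb_min", "lpa_min", "mvpa_min"]].sum(axis=1)
    for col, label in [
        ("sb_min", "Sedentary behavior (% of wake window)"),
        ("lpa_min", "LPA (% of wake window)"),
        ("mvpa_min", "MVPA (% of wake window)"),
    ]:
        row(label, lambda s, c=col: _mean_sd(
            100.0 * s[c] / s[["sb_min", "lpa_min", "mvpa_min"]].sum(axis=1)
        ))
    for col, label in [
        ("internalizing_t", "Internalizing problems (t)"),
        ("externalizing_t", "Externalizing problems (t)"),
    ]:
        if col in analysis.columns:
            row(label, lambda s, c=col: _mean_sd(s[c]))
    del total
    return "\n".join(lines) + "\n"


def composition_percent_means(analysis: pd.DataFrame) -> np.ndarray:
    """Mean per-participant percent shares of the three behaviors."""
    comp = analysis[["sb_min", "lpa_min", "mvpa_min"]].to_numpy(float)
    pct = 100.0 * comp / comp.sum(axis=1, keepdims=True)
    return pct.mean(axis=0)


def regression_table(
    fits: Mapping[str, Mapping[str, CompositionalRegression]],
) -> str:
    """Markdown table of pivot-coordinate coefficients per outcome.

    ``fits[outcome][pivot]`` is a fitted :class:`CompositionalRegression`;
    the printed B (SE) and p are the first (pivot) ilr coordinate of the
    headline fit — the association of that behavior relative to the
    geometric mean of the other two.
    """
    outcomes = list(fits)
    lines = [
        "# Movement composition vs. mental-health indicators",
        "",
        "| Behavior (pivot) | "
        + " | ".join(f"{o}: B (SE) | p" for o in outcomes)
        + " |",
        "|---" * (1 + 2 * len(outcomes)) + "|",
    ]
    pivots = list(next(iter(fits.values())).keys())
    for pivot in pivots:
        cells = []
        for o in outcomes:
            r = fits[o][pivot].result_
            cells.append(
                f"{r.params['ilr1']:.2f} ({r.bse['ilr1']:.2f}) | "
                f"{r.pvalues['ilr1']:.2f}"
            )
        lines.append(f"| {pivot} | " + " | ".join(cells) + " |")
    lines.append("")
    for o in outcomes:
        any_fit = next(iter(fits[o].values()))
        r = any_fit.result_
        lines.append(
            f"{o}: adjusted R^2 = {r.adj_r2:.2f} "
            f"(method: {r.method}, n = {r.nobs})"
        )
    return "\n".join(lines) + "\n"


def mancova_summary(result: MancovaResult) -> dict:
    d = result.to_dict()
    d["formatted"] = (
        f"F({result.df1},{result.df2}) = {result.f_stat:.2f}, "
        f"p = {result.p_value:.2f}, Lambda = {result.wilks_lambda:.2f}"
    )
    return d


def plot_reallocation_grid(grid: pd.DataFrame, path: str) -> None:
    """Panel-per-outcome plot of predicted change vs. reallocated minutes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outcomes = grid["outcome"].unique()
    fig, axes = plt.subplots(
        1, len(outcomes), figsize=(6 * len(outcomes), 4), squeeze=False
    )
    for ax, outcome in zip(axes[0], outcomes):
        sub = grid[grid["outcome"] == outcome]
        for (frm, to), cell in sub.groupby(["from_behavior", "to_behavior"]):
            cell = cell.sort_values("delta_minutes")
            line = ax.plot(
                cell["delta_minutes"], cell["predicted_change"],
                marker="o", label=f"{frm}→{to}",
            )[0]
            ax.fill_between(
                cell["delta_minutes"], cell["ci_low"], cell["ci_high"],
                alpha=0.15, color=line.get_color(),
            )
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel("Minutes reallocated")
        ax.set_ylabel("Predicted change (t-score points)")
        ax.set_title(str(outcome))
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
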