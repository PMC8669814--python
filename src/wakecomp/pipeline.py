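"""End-to-end orchestration: generate -> preprocess -> models -> isotemporal.

Each stage reads the previous stage's CSV, so runs are resumable, and the
whole pipeline is deterministic under the configured seed (fixed float
formatting makes repeated runs byte-identical).  Every run directory gets
the resolved configuration plus a structured log with row accounting.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .accelerometry import CutPoints, summarize_participants
from .config import PipelineConfig
from .isotemporal import BaseComposition, build_grid, summarize_grid
from .models import (
    CompositionalRegression,
    fit_compositional_mancova,
)
from .preprocess import ChainedImputer, build_analysis_table
from .report import (
    descriptives_table,
    mancova_summary,
    plot_reallocation_grid,
    regression_table,
)
from .simplex import compositional_mean

OUTCOMES = ("internalizing_t", "externalizing_t")
PIVOTS = ("SB", "LPA", "MVPA")
_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str, snapshot: str | None = None):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage
        self.snapshot = snapshot


def _generator_config(cfg: PipelineConfig) -> cohort_mod.GeneratorConfig:
    c = cfg.cohort
    outcomes = cohort_mod.default_outcome_models()
    if c.null_effects:
        outcomes = {
            k: cohort_mod.OutcomeModel(mean=v.mean, noise_sd=v.noise_sd)
            for k, v in outcomes.items()
        }
    return cohort_mod.GeneratorConfig(
        n=c.n,
        prop_rdcd=c.prop_rdcd,
        mean_composition_pct=tuple(c.mean_composition_pct),
        ilr_dispersion=cohort_mod.calibrate_ilr_dispersion(
            tuple(c.mean_composition_pct)
        ),
        outcomes=outcomes,
        outcome_correlation=c.outcome_correlation,
        missing_rates=dict(c.missing_rates),
        low_income_missing_odds=c.low_income_missing_odds,
        wear_minutes_sd=c.wear_minutes_sd,
        seed=cfg.seed,
    )


def stage_generate(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    gen = _generator_config(cfg)
    table, miss_log = cohort_mod.generate_cohort(gen)
    if cfg.accel.simulate_epochs:
        table = _roundtrip_through_epochs(cfg, table)
    table.to_csv(outdir / "cohort.csv", index=False, float_format=_FLOAT_FMT)
    miss_log.to_csv(outdir / "missingness_log.csv", index=False)
    return table

def _roundtrip_through_epochs(cfg: PipelineConfig, table: pd.DataFrame) -> pd.DataFrame:
    """Regenerate each complete row's minutes through synthetic epoch streams.

    Exercises the accelerometry stage end to end: emit count streams that
    encode the row's composition, then classify and summarize them back.
    """
    a = cfg.accel
    cp = CutPoints(a.sb_max, a.lpa_max, a.reference_epoch_seconds)
    rngs = np.random.SeedSequence(cfg.seed + 7).spawn(len(table))
    rows = []
    for (i, row), ss in zip(table.iterrows(), rngs):
        if row[["sb_min", "lpa_min", "mvpa_min"]].isna().any():
            continue
        streams = cohort_mod.emit_epoch_streams(
            row, days=3, seed=np.random.default_rng(ss),
            cutpoints=cp, epoch_seconds=a.epoch_seconds,
        )
        for s in streams:
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": row["id"],
                        "day": s.day_id,
                        "counts": s.counts,
                        "worn": s.wear_mask,
                    }
                )
            )
    epochs = pd.concat(rows, ignore_index=True)
    summ = summarize_participants(
        epochs, cp, a.epoch_seconds, a.min_wear_minutes, a.min_valid_days
    ).rename(columns={"participant_id": "id"})
    out = table.copy()
    merged = out[["id"]].merge(summ, on="id", how="left")
    got = merged["sb_min"].notna().to_numpy()
    for c in ("sb_min", "lpa_min", "mvpa_min", "wear_min"):
        vals = out[c].to_numpy(float)
        vals[got] = merged.loc[got, c].to_numpy(float)
        out[c] = vals
    return out


def stage_preprocess(
    cfg: PipelineConfig, cohort: pd.DataFrame, outdir: Path
) -> pd.DataFrame:
    imp = ChainedImputer(
        cfg.impute.n_imputations,
        cfg.impute.n_cycles,
        cfg.impute.composition_scale,
        seed=cfg.seed + 1,
    )
    completed = imp.fit(cohort).transform(cohort)
    analysis = build_analysis_table(
        completed, cfg.closure_kappa, imputed_mask=imp.imputed_mask_
    )
    analysis.to_csv(outdir / "analysis_table.csv", index=False,
                    float_format=_FLOAT_FMT)
    with open(outdir / "imputation_log.json", "w") as fh:
        json.dump(imp.log_, fh, indent=2)
    return analysis


def stage_models(cfg: PipelineConfig, analysis: pd.DataFrame, outdir: Path):
    manc = fit_compositional_mancova(
        analysis[["ilr1", "ilr2"]].to_numpy(),
        analysis["group"].to_numpy(),
        analysis,
    )
    with open(outdir / "mancova.json", "w") as fh:
        json.dump(mancova_summary(manc), fh, indent=2)
    fits: dict[str, dict[str, CompositionalRegression]] = {}
    coef_rows = []
    for outcome in OUTCOMES:
        fits[outcome] = {}
        for pivot in PIVOTS:
            est = CompositionalRegression(
                pivot=pivot, robust=cfg.model.robust, alpha=cfg.model.alpha,
                seed=cfg.seed + 2,
            ).fit(analysis, outcome)
            fits[outcome][pivot] = est
            r = est.result_
            coef_rows.append(
                {
                    "outcome": outcome,
                    "pivot": pivot,
                    "method": r.method,
                    "B": r.params["ilr1"],
                    "SE": r.bse["ilr1"],
                    "p": r.pvalues["ilr1"],
                    "adj_r2": r.adj_r2,
                    "n_influential": est.influence_.n_flagged,
                }
            )
    pd.DataFrame(coef_rows).to_csv(
        outdir / "regression_coefficients.csv", index=False,
        float_format=_FLOAT_FMT,
    )
    with open(outdir / "regression_tables.md", "w") as fh:
        fh.write(regression_table(fits))
    return manc, fits


def stage_isotemporal(
    cfg: PipelineConfig, analysis: pd.DataFrame, fits, outdir: Path
) -> pd.DataFrame:
    comp = compositional_mean(
        analysis[["sb_min", "lpa_min", "mvpa_min"]].to_numpy(),
        kappa=cfg.closure_kappa,
    )
    base = BaseComposition(comp)
    grids = []
    for outcome in OUTCOMES:
        fit = fits[outcome]["SB"].result_
        grids.append(
            build_grid(fit, base, deltas=tuple(cfg.isotemporal.deltas),
                       alpha=cfg.model.alpha)
        )
    grid = pd.concat(grids, ignore_index=True)
    grid.to_csv(outdir / "reallocation_grid.csv", index=False,
                float_format=_FLOAT_FMT)
    summarize_grid(grid).to_json(
        outdir / "reallocation_summary.json", orient="records", indent=2
    )
    if cfg.output.plots:
        plot_reallocation_grid(grid, str(outdir / "reallocation_grid.png"))
    return grid


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage into ``outdir``; returns a summary dict (also logged)."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "resolved_config.yaml")
    log: dict = {"seed": cfg.seed, "stages": {}}
    try:
        cohort = stage_generate(cfg, outdir)
        # reload from disk so an in-memory run equals a stagewise CSV restart
        cohort = pd.read_csv(outdir / "cohort.csv")
        log["stages"]["generate"] = {
            "rows": len(cohort),
            "missing_accel": int(cohort["sb_min"].isna().sum()),
            "missing_outcomes": int(cohort["internalizing_t"].isna().sum()),
        }
    except Exception as e:
        raise PipelineError("generate", str(e)) from e
    try:
        analysis = stage_preprocess(cfg, cohort, outdir)
        analysis = pd.read_csv(outdir / "analysis_table.csv")
        log["stages"]["preprocess"] = {
            "rows": len(analysis),
            "imputed_accel_rows": int(analysis.get("accel_imputed",
                                                   pd.Series(False)).sum()),
            "imputed_outcome_rows": int(analysis.get("outcomes_imputed",
                                                     pd.Series(False)).sum()),
        }
    except Exception as e:
        raise PipelineError("preprocess", str(e),
                            snapshot=str(outdir / "cohort.csv")) from e
    with open(outdir / "descriptives.md", "w") as fh:
        fh.write(descriptives_table(analysis))
    try:
        manc, fits = stage_models(cfg, analysis, outdir)
        log["stages"]["models"] = {
            "mancova": mancova_summary(manc)["formatted"],
            "methods": {
                o: {p: fits[o][p].result_.method for p in PIVOTS}
                for o in OUTCOMES
            },
        }
    except Exception as e:
        raise PipelineError("models", str(e),
                            snapshot=str(outdir / "analysis_table.csv")) from e
    try:
        grid = stage_isotemporal(cfg, analysis, fits, outdir)
        log["stages"]["isotemporal"] = {
            "cells": len(grid),
            "significant": int(grid["significant"].sum()),
        }
    except Exception as e:
        raise PipelineError("isotemporal", str(e),
                            snapshot=str(outdir / "analysis_table.csv")) from e
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return log
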