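"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a preschool cohort of typically-developing (TD)
children and children at risk for Developmental Coordination Disorder (rDCD):

* wake-time compositions are logistic-normal — multivariate normal in ilr
  coordinates around the ilr image of a target mean composition, mapped back
  to the simplex and scaled to a 724-min wake window.  The 2x2 ilr dispersion
  is moment-matched to target percent-space standard deviations by a
  simulation-based calibration routine (:func:`calibrate_ilr_dispersion`);
* covariates (age, sex, four-bracket household income, ethnicity, a BMI
  score) are drawn from marginals typical of such cohorts;
* two CBCL-like outcome t-scores (internalizing, externalizing) are linear in
  the canonical ilr coordinates and covariates plus Gaussian noise, with the
  marginal mean/SD calibrated on the t-score scale (population mean 50,
  SD 10);
* missingness is injected block-wise (all accelerometry columns together;
  both outcomes together) and may depend on household income — the
  missing-at-random structure the imputation stage assumes.

All randomness flows from one integer seed through
``numpy.random.SeedSequence.spawn``, so each stage has an independent,
reproducible stream and adding draws to one stage never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .accelerometry import CutPoints, EVENSON_15S, EpochSeries, rescale_cutpoints
from .simplex import (
    Composition,
    close,
    ilr_forward,
    ilr_inverse,
    make_default_sbp,
)

WAKE_WINDOW_MIN = 724.0

#: Target mean wake-time composition, percent of the wake window.
MEAN_COMPOSITION_PCT = (62.33, 27.75, 9.92)
#: Target percent-space standard deviations per part.
COMPOSITION_SD_PCT = (5.16, 3.50, 2.65)

INCOME_LEVELS = ("<50k", "50-100k", "100-150k", ">150k")
INCOME_PROBS = (0.132, 0.302, 0.312, 0.253)


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class OutcomeModel:
    """Linear outcome model on the t-score scale.

    ``mean`` is the marginal mean of the outcome; effects act on centered
    predictors so the marginal mean is exact by construction (the equivalent
    raw-scale intercept is ``mean - sum(effect * predictor mean)``).
    ``ilr1``/``ilr2`` are effects per unit of the canonical (SB-pivot) ilr
    coordinates; covariate effects are per unit / per indicator.
    """

    mean: float = 50.0
    ilr1: float = 0.0
    ilr2: float = 0.0
    group_rdcd: float = 0.0
    age: float = 0.0
    sex_male: float = 0.0
    income: tuple[float, float, float] = (0.0, 0.0, 0.0)  # vs lowest bracket
    ethnicity_white: float = 0.0
    bmi_score: float = 0.0
    noise_sd: float = 10.0


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 589
    prop_rdcd: float = 0.489
    mean_composition_pct: tuple[float, float, float] = MEAN_COMPOSITION_PCT
    ilr_dispersion: np.ndarray | None = None
    outcomes: Mapping[str, OutcomeModel] = field(default_factory=dict)
    outcome_correlation: float = 0.5  # residual correlation, an assumption
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: {"accel": 0.127, "outcomes": 0.012}
    )
    #: odds multiplier for missingness in the lowest income bracket (MAR)
    low_income_missing_odds: float = 2.0
    wear_minutes_sd: float = 0.0  # 0 -> constant 724-min window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise GeneratorError("n must be at least 10")
        if not 0 <= self.prop_rdcd <= 1:
            raise GeneratorError("prop_rdcd must be a probability")
        for k, v in self.missing_rates.items():
            if not 0 <= v <= 1:
                raise GeneratorError(f"missing rate {k}={v} outside [0,1]")


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


_CALIBRATION_CACHE: dict[tuple, np.ndarray] = {}


def calibrate_ilr_dispersion(
    mean_pct: Sequence[float] = MEAN_COMPOSITION_PCT,
    sd_pct: Sequence[float] = COMPOSITION_SD_PCT,
    n_mc: int = 20_000,
) -> np.ndarray:
    """Moment-match the 2x2 ilr covariance to percent-space part SDs.

    Uses a fixed standard-normal quasi-sample pushed through the inverse ilr,
    optimizing (log sd1, log sd2, atanh rho) so the simulated percent SDs hit
    the targets; deterministic by construction.
    """
    key = (tuple(np.asarray(mean_pct, float)), tuple(np.asarray(sd_pct, float)), n_mc)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key].copy()
    basis = make_default_sbp()
    mu = ilr_forward(close(np.asarray(mean_pct, float), 1.0), basis)
    eps = np.random.default_rng(20080915).standard_normal((n_mc, 2))
    target = np.asarray(sd_pct, float)

    def unpack(theta):
        s1, s2 = np.exp(theta[:2])
        rho = np.tanh(theta[2])
        cov = np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])
        return cov

    def resid(theta):
        cov = unpack(theta)
        L = np.linalg.cholesky(cov)
        z = mu + eps @ L.T
        pct = ilr_inverse(z, basis, kappa=100.0)
        return pct.std(axis=0, ddof=1) - target

    theta0 = np.array([np.log(0.13), np.log(0.2), 0.0])
    sol = least_squares(resid, theta0, xtol=1e-12, ftol=1e-12)
    _CALIBRATION_CACHE[key] = unpack(sol.x)
    return _CALIBRATION_CACHE[key].copy()


def default_outcome_models() -> dict[str, OutcomeModel]:
    """Calibrated default outcome models.

    Canonical-ilr effects are the ones a pooled compositional regression on
    such a cohort recovers: externalizing has a negative sedentary-pivot
    effect (-5.24 t-score points per unit ilr1), internalizing essentially
    none (-0.26); the second-coordinate effects (+1.77824, +3.40637) complete
    the coefficient pair consistent with the pivot-rotated first coordinates
    (+4.16/+1.08 externalizing, +3.08/-2.82 internalizing).  rDCD children
    score a few points higher on both scales.  Noise SDs are solved so the
    marginal SDs are ~9.27 and ~9.82 t-score points.
    """
    disp = calibrate_ilr_dispersion()
    prop = 0.489

    def noise_for(target_sd, b1, b2, grp):
        b = np.array([b1, b2])
        var_sys = float(b @ disp @ b) + grp * grp * prop * (1 - prop)
        if var_sys >= target_sd**2:
            raise GeneratorError("systematic variance exceeds target outcome SD")
        return float(np.sqrt(target_sd**2 - var_sys))

    models = {
        "internalizing_t": OutcomeModel(
            mean=48.02, ilr1=-0.26, ilr2=3.40637, group_rdcd=3.08,
            noise_sd=noise_for(9.82, -0.26, 3.40637, 3.08),
        ),
        "externalizing_t": OutcomeModel(
            mean=45.55, ilr1=-5.24, ilr2=1.77824, group_rdcd=4.03,
            noise_sd=noise_for(9.27, -5.24, 1.77824, 4.03),
        ),
    }
    return models


def default_config(n: int = 589, seed: int = 0, **overrides) -> GeneratorConfig:
    """Generator configuration with every calibration applied."""
    cfg = dict(
        n=n,
        seed=seed,
        ilr_dispersion=calibrate_ilr_dispersion(),
        outcomes=default_outcome_models(),
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def sample_compositions(
    n: int,
    mean_composition: Composition | Sequence[float],
    ilr_dispersion: np.ndarray,
    seed: int | np.random.Generator = 0,
    kappa: float = WAKE_WINDOW_MIN,
) -> np.ndarray:
    """Draw n logistic-normal compositions (rows, minutes summing to kappa)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    basis = make_default_sbp()
    mean_parts = (
        mean_composition.parts
        if isinstance(mean_composition, Composition)
        else np.asarray(mean_composition, float)
    )
    if np.any(mean_parts <= 0):
        raise GeneratorError("mean composition must be strictly positive")
    mu = ilr_forward(close(mean_parts, 1.0), basis)
    cov = np.asarray(ilr_dispersion, float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
        raise GeneratorError("ilr dispersion must be a symmetric 2x2 matrix")
    if np.allclose(cov, 0):
        z = np.tile(mu, (n, 1))
    else:
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as e:
            raise GeneratorError("ilr dispersion is not positive-definite") from e
        z = mu + rng.standard_normal((n, 2)) @ L.T
    return ilr_inverse(z, basis, kappa=kappa)


def sample_covariates(
    n: int, prop_rdcd: float = 0.489, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Covariate table with marginals typical of a preschool motor cohort."""
    if n < 1:
        raise GeneratorError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    income_p = np.asarray(INCOME_PROBS) / np.sum(INCOME_PROBS)
    df = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(1, n + 1)],
            "group": np.where(rng.random(n) < prop_rdcd, "rDCD", "TD"),
            "age": rng.normal(4.94, 0.59, n),
            "sex": np.where(rng.random(n) < 0.574, "male", "female"),
            "income": rng.choice(INCOME_LEVELS, size=n, p=income_p),
            "ethnicity": np.where(rng.random(n) < 0.810, "White", "non-White"),
            "bmi_score": rng.normal(56.07, 27.14, n),
        }
    )
    df["income"] = pd.Categorical(df["income"], categories=INCOME_LEVELS)
    return df


def _outcome_design(ilr_table: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    inc = pd.get_dummies(covariates["income"]).reindex(
        columns=list(INCOME_LEVELS), fill_value=0
    )
    cols = [
        ilr_table[:, 0],
        ilr_table[:, 1],
        (covariates["group"] == "rDCD").to_numpy(float),
        covariates["age"].to_numpy(float),
        (covariates["sex"] == "male").to_numpy(float),
        inc[INCOME_LEVELS[1]].to_numpy(float),
        inc[INCOME_LEVELS[2]].to_numpy(float),
        inc[INCOME_LEVELS[3]].to_numpy(float),
        (covariates["ethnicity"] == "White").to_numpy(float),
        covariates["bmi_score"].to_numpy(float),
    ]
    return np.column_stack(cols)


def simulate_outcomes(
    ilr_table: np.ndarray,
    covariates: pd.DataFrame,
    outcome_models: Mapping[str, OutcomeModel],
    seed: int | np.random.Generator = 0,
    residual_correlation: float = 0.0,
) -> pd.DataFrame:
    """Simulate outcome t-scores linear in ilr coordinates and covariates.

    Effects multiply centered predictors, so each outcome's marginal mean is
    exactly its model's ``mean``.  Residuals across the outcomes may be
    correlated.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = _outcome_design(np.atleast_2d(ilr_table), covariates)
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    names = list(outcome_models)
    betas = []
    for name in names:
        m = outcome_models[name]
        beta = np.array(
            [m.ilr1, m.ilr2, m.group_rdcd, m.age, m.sex_male, *m.income,
             m.ethnicity_white, m.bmi_score]
        )
        if beta.size != Xc.shape[1]:
            raise GeneratorError("outcome coefficients not conformable with design")
        betas.append(beta)
    k = len(names)
    rho = float(residual_correlation)
    C = np.full((k, k), rho) + (1 - rho) * np.eye(k)
    try:
        Lc = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as e:
        raise GeneratorError("residual correlation matrix not positive-definite") from e
    eps = rng.standard_normal((n, k)) @ Lc.T
    out = {}
    for j, name in enumerate(names):
        m = outcome_models[name]
        out[name] = m.mean + Xc @ betas[j] + m.noise_sd * eps[:, j]
    return pd.DataFrame(out, index=covariates.index)


ACCEL_COLS = ("sb_min", "lpa_min", "mvpa_min", "wear_min")
OUTCOME_COLS = ("internalizing_t", "externalizing_t")
_BLOCKS = {
    "accel": ACCEL_COLS,
    "outcomes": OUTCOME_COLS,
    "income": ("income",),
    "ethnicity": ("ethnicity",),
}


def inject_missingness(
    table: pd.DataFrame,
    missing_rates: Mapping[str, float],
    seed: int | np.random.Generator = 0,
    low_income_missing_odds: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank out whole blocks of cells, optionally income-dependent (MAR).

    Per-participant deletion probabilities are the block rate times a weight
    that is ``low_income_missing_odds`` for the lowest income bracket and 1
    otherwise, renormalized so the marginal rate equals the configured rate.
    Returns the table with NaNs plus a (row, block) log.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = table.copy()
    log_rows = []
    low = (table["income"].astype(object) == INCOME_LEVELS[0]).to_numpy()
    for block, rate in missing_rates.items():
        if block not in _BLOCKS:
            raise GeneratorError(f"unknown missingness block {block!r}")
        if not 0 <= rate <= 1:
            raise GeneratorError(f"rate for {block!r} outside [0,1]")
        if rate == 0:
            continue
        w = np.where(low, low_income_missing_odds, 1.0)
        p = np.clip(rate * w / w.mean(), 0, 1)
        hit = rng.random(len(out)) < p
        cols = [c for c in _BLOCKS[block] if c in out.columns]
        out.loc[hit, cols] = np.nan
        log_rows.extend({"row": int(i), "block": block} for i in np.flatnonzero(hit))
    log = pd.DataFrame(log_rows, columns=["row", "block"])
    return out, log


def emit_epoch_streams(
    record: Mapping[str, float],
    days: int = 7,
    seed: int | np.random.Generator = 0,
    cutpoints: CutPoints = EVENSON_15S,
    epoch_seconds: int = 3,
    nonwear_minutes: float = 0.0,
) -> list[EpochSeries]:
    """Epoch streams whose classification recovers a record's daily minutes.

    For each day the requested minutes per behavior are converted to whole
    epochs (rounded), counts are drawn uniformly inside each behavior's
    cut-point band, and epoch order is shuffled; optional trailing non-wear
    padding carries zero counts with the wear mask off.  Total requested
    minutes may not exceed 24 h.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cp = rescale_cutpoints(cutpoints, epoch_seconds)
    minutes = [float(record[k]) for k in ("sb_min", "lpa_min", "mvpa_min")]
    if any(m < 0 for m in minutes):
        raise GeneratorError("negative minutes in record")
    if sum(minutes) + nonwear_minutes > 24 * 60:
        raise GeneratorError("daily minutes exceed 24 h")
    per_min = 60 // epoch_seconds
    n_epochs = [int(round(m * per_min)) for m in minutes]
    bands = [
        (0, cp.sb_max),
        (cp.sb_max + 1, cp.lpa_max),
        (cp.lpa_max + 1, 3 * cp.lpa_max),
    ]
    streams = []
    for day in range(1, days + 1):
        counts = np.concatenate(
            [rng.integers(lo, hi + 1, size=k) for (lo, hi), k in zip(bands, n_epochs)]
        ) if sum(n_epochs) else np.empty(0, dtype=int)
        rng.shuffle(counts)
        mask = np.ones(counts.size, bool)
        pad = int(round(nonwear_minutes * per_min))
        if pad:
            counts = np.concatenate([counts, np.zeros(pad, dtype=int)])
            mask = np.concatenate([mask, np.zeros(pad, bool)])
        streams.append(EpochSeries(day, counts, epoch_seconds, mask))
    return streams


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full seeded cohort table plus the missingness log.

    Columns: id, group, age, sex, income, ethnicity, bmi_score, wear_min,
    sb_min, lpa_min, mvpa_min, internalizing_t, externalizing_t.
    """
    disp = (
        config.ilr_dispersion
        if config.ilr_dispersion is not None
        else calibrate_ilr_dispersion(config.mean_composition_pct)
    )
    outcomes = dict(config.outcomes) or default_outcome_models()
    r_cov, r_comp, r_out, r_wear, r_miss = _streams(config.seed, 5)

    cov = sample_covariates(config.n, config.prop_rdcd, r_cov)
    if config.wear_minutes_sd > 0:
        wear = r_wear.normal(723.92, config.wear_minutes_sd, config.n)
        wear = np.clip(wear, 600.0, 24 * 60.0)
    else:
        wear = np.full(config.n, WAKE_WINDOW_MIN)
    props = sample_compositions(
        config.n, close(np.asarray(config.mean_composition_pct, float), 1.0),
        disp, r_comp, kappa=1.0,
    )
    minutes = props * wear[:, None]
    ilr_table = ilr_forward(props, make_default_sbp())
    ys = simulate_outcomes(
        ilr_table, cov, outcomes, r_out, config.outcome_correlation
    )
    table = cov.copy()
    table["wear_min"] = wear
    table[["sb_min", "lpa_min", "mvpa_min"]] = minutes
    for c in ys.columns:
        table[c] = ys[c]
    table, log = inject_missingness(
        table, config.missing_rates, r_miss, config.low_income_missing_odds
    )
    return table, log
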