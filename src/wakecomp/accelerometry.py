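"""Epoch-level accelerometer processing for preschool movement behaviors.

Count streams recorded in short (default 3-s) epochs are classified into
sedentary behavior, light and moderate-to-vigorous physical activity with
count cut points, summed into daily minutes, screened against wear-time
validity rules (>= 10 h/day worn, >= 3 valid days), and averaged into one
mean daily composition per participant.

Cut points are stored against the epoch length they were validated at (the
2008 Evenson thresholds are expressed per 15-s epoch: sedentary <= 25 counts,
light 26-573, MVPA >= 574) and rescaled linearly, with floor rounding, to the
recording epoch.  Wear/non-wear follows the parent-diary mask supplied with
the data; a consecutive-zeros heuristic is available as an explicit opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SB, LPA, MVPA, NONWEAR = "SB", "LPA", "MVPA", "NONWEAR"

#: Evenson (2008) children's cut points, counts per 15-s epoch.
EVENSON_15S: "CutPoints"

MIN_WEAR_MINUTES = 600  # 10 h/day
MIN_VALID_DAYS = 3


class AccelerometryError(ValueError):
    pass


@dataclass(frozen=True)
class CutPoints:
    """Count thresholds per epoch: SB <= sb_max < LPA <= lpa_max < MVPA."""

    sb_max: int
    lpa_max: int
    reference_epoch_seconds: int = 15

    def __post_init__(self) -> None:
        if not (0 <= self.sb_max < self.lpa_max):
            raise AccelerometryError("need 0 <= sb_max < lpa_max")
        if self.reference_epoch_seconds <= 0 or 60 % self.reference_epoch_seconds:
            raise AccelerometryError("reference epoch must divide 60 s")


EVENSON_15S = CutPoints(sb_max=25, lpa_max=573, reference_epoch_seconds=15)


@dataclass(frozen=True)
class EpochSeries:
    """One day of epoch counts plus the diary wear mask."""

    day_id: object
    counts: np.ndarray
    epoch_seconds: int = 3
    wear_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise AccelerometryError("counts must be 1-d")
        if np.any(counts < 0):
            raise AccelerometryError("negative activity counts")
        mask = self.wear_mask
        mask = np.ones(counts.size, bool) if mask is None else np.asarray(mask, bool)
        if mask.size != counts.size:
            raise AccelerometryError("wear_mask and counts length differ")
        if self.epoch_seconds <= 0 or 60 % self.epoch_seconds:
            raise AccelerometryError("epoch_seconds must divide 60")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "wear_mask", mask)


@dataclass(frozen=True)
class DailySummary:
    minutes_sb: float
    minutes_lpa: float
    minutes_mvpa: float
    wear_minutes: float
    valid: bool
    day_id: object = None

    @property
    def minutes(self) -> tuple[float, float, float]:
        return (self.minutes_sb, self.minutes_lpa, self.minutes_mvpa)


@dataclass(frozen=True)
class ParticipantSummary:
    """Mean daily minutes over valid days, or an exclusion flag."""

    mean_sb: float | None
    mean_lpa: float | None
    mean_mvpa: float | None
    mean_wear: float | None
    n_valid_days: int
    excluded: bool


def rescale_cutpoints(cp: CutPoints, target_epoch_seconds: int) -> CutPoints:
    """Express cut points in another epoch length (linear scale, floor).

    The two epoch lengths must divide one another so the scaling is a clean
    ratio; order of the thresholds is preserved.
    """
    ref = cp.reference_epoch_seconds
    if target_epoch_seconds <= 0 or (
        ref % target_epoch_seconds and target_epoch_seconds % ref
    ):
        raise AccelerometryError(
            f"epoch lengths {ref}s and {target_epoch_seconds}s are not divisible"
        )
    if target_epoch_seconds == ref:
        return cp
    ratio = target_epoch_seconds / ref
    return CutPoints(
        sb_max=int(np.floor(cp.sb_max * ratio)),
        lpa_max=int(np.floor(cp.lpa_max * ratio)),
        reference_epoch_seconds=target_epoch_seconds,
    )


def classify_epochs(series: EpochSeries, cp: CutPoints) -> np.ndarray:
    """Label every epoch SB / LPA / MVPA / NONWEAR.

    ``cp`` must already be expressed in the series' epoch length.  Wear
    epochs are binned by the closed-left intervals [0, sb_max], (sb_max,
    lpa_max], (lpa_max, inf); non-wear epochs are NONWEAR whatever their
    counts.
    """
    if cp.reference_epoch_seconds != series.epoch_seconds:
        raise AccelerometryError(
            "cut points epoch length does not match the series; "
            "rescale_cutpoints() first"
        )
    counts = series.counts
    labels = np.full(counts.size, NONWEAR, dtype=object)
    worn = series.wear_mask
    labels[worn & (counts <= cp.sb_max)] = SB
    labels[worn & (counts > cp.sb_max) & (counts <= cp.lpa_max)] = LPA
    labels[worn & (counts > cp.lpa_max)] = MVPA
    return labels


def summarize_day(
    labels: Sequence[str] | np.ndarray,
    epoch_seconds: int,
    min_wear_minutes: float = MIN_WEAR_MINUTES,
    day_id: object = None,
) -> DailySummary:
    """Aggregate epoch labels to daily minutes; flag 10-h wear validity."""
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise AccelerometryError("empty day")
    per_min = epoch_seconds / 60.0
    m_sb = float(np.sum(labels == SB)) * per_min
    m_lpa = float(np.sum(labels == LPA)) * per_min
    m_mvpa = float(np.sum(labels == MVPA)) * per_min
    wear = m_sb + m_lpa + m_mvpa
    return DailySummary(m_sb, m_lpa, m_mvpa, wear, wear >= min_wear_minutes, day_id)


def average_valid_days(
    days: Iterable[DailySummary], min_days: int = MIN_VALID_DAYS
) -> ParticipantSummary:
    """Mean daily minutes over valid days; exclusion when too few.

    Exclusion is a value, not an error: downstream code drops excluded
    participants with an accounting log entry.
    """
    days = list(days)
    if not days:
        raise AccelerometryError("no days supplied")
    valid = [d for d in days if d.valid]
    if len(valid) < min_days:
        return ParticipantSummary(None, None, None, None, len(valid), True)
    arr = np.array([[d.minutes_sb, d.minutes_lpa, d.minutes_mvpa, d.wear_minutes]
                    for d in valid])
    m = arr.mean(axis=0)
    return ParticipantSummary(m[0], m[1], m[2], m[3], len(valid), False)


def detect_nonwear(
    counts: np.ndarray, epoch_seconds: int, window_minutes: int = 20
) -> np.ndarray:
    """Consecutive-zero non-wear heuristic (opt-in extension).

    Marks any run of zero counts lasting at least ``window_minutes`` as
    non-wear.  The default pipeline trusts the diary mask instead.
    """
    counts = np.asarray(counts)
    need = int(window_minutes * 60 / epoch_seconds)
    worn = np.ones(counts.size, bool)
    run_start = None
    for i in range(counts.size + 1):
        zero = i < counts.size and counts[i] == 0
        if zero and run_start is None:
            run_start = i
        elif not zero and run_start is not None:
            if i - run_start >= need:
                worn[run_start:i] = False
            run_start = None
    return worn


def summarize_participants(
    epochs: pd.DataFrame,
    cutpoints: CutPoints = EVENSON_15S,
    epoch_seconds: int = 3,
    min_wear_minutes: float = MIN_WEAR_MINUTES,
    min_valid_days: int = MIN_VALID_DAYS,
) -> pd.DataFrame:
    """Long epoch table -> one row of mean daily minutes per participant.

    ``epochs`` needs columns participant_id, day, counts, worn.  Cut points
    are rescaled to ``epoch_seconds`` automatically.  Output columns:
    participant_id, sb_min, lpa_min, mvpa_min, wear_min, n_valid_days,
    excluded.
    """
    required = {"participant_id", "day", "counts", "worn"}
    missing = required - set(epochs.columns)
    if missing:
        raise AccelerometryError(f"epoch table lacks columns {sorted(missing)}")
    cp = rescale_cutpoints(cutpoints, epoch_seconds)
    rows = []
    for pid, sub in epochs.groupby("participant_id", sort=True):
        days = []
        for day, d in sub.groupby("day", sort=True):
            series = EpochSeries(
                day,
                d["counts"].to_numpy(),
                epoch_seconds,
                d["worn"].to_numpy(bool),
            )
            labels = classify_epochs(series, cp)
            days.append(summarize_day(labels, epoch_seconds, min_wear_minutes, day))
        s = average_valid_days(days, min_valid_days)
        rows.append(
            {
                "participant_id": pid,
                "sb_min": s.mean_sb,
                "lpa_min": s.mean_lpa,
                "mvpa_min": s.mean_mvpa,
                "wear_min": s.mean_wear,
                "n_valid_days": s.n_valid_days,
                "excluded": s.excluded,
            }
        )
    return pd.DataFrame(rows)
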