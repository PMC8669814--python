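"""Pipeline configuration: YAML round-trip plus validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .accelerometry import MIN_VALID_DAYS, MIN_WEAR_MINUTES


class ConfigError(ValueError):
    pass


@dataclass
class CohortSettings:
    n: int = 589
    prop_rdcd: float = 0.489
    mean_composition_pct: list = field(default_factory=lambda: [62.33, 27.75, 9.92])
    missing_rates: dict = field(
        default_factory=lambda: {"accel": 0.127, "outcomes": 0.012}
    )
    low_income_missing_odds: float = 2.0
    wear_minutes_sd: float = 0.0
    outcome_correlation: float = 0.5  # assumed; not an observed quantity
    null_effects: bool = False  # zero all outcome effects (type-I studies)


@dataclass
class AccelSettings:
    epoch_seconds: int = 3
    sb_max: int = 25
    lpa_max: int = 573
    reference_epoch_seconds: int = 15
    min_wear_minutes: float = MIN_WEAR_MINUTES
    min_valid_days: int = MIN_VALID_DAYS
    simulate_epochs: bool = False  # regenerate minutes through epoch streams


@dataclass
class ImputeSettings:
    n_imputations: int = 5
    n_cycles: int = 10
    composition_scale: str = "ilr"


@dataclass
class ModelSettings:
    robust: str | bool = "auto"
    alpha: float = 0.05


@dataclass
class IsotemporalSettings:
    deltas: list = field(default_factory=lambda: [5, 10, 15, 20, 25])


@dataclass
class OutputSettings:
    plots: bool = False


@dataclass
class PipelineConfig:
    seed: int = 0
    closure_kappa: float = 724.0
    cohort: CohortSettings = field(default_factory=CohortSettings)
    accel: AccelSettings = field(default_factory=AccelSettings)
    impute: ImputeSettings = field(default_factory=ImputeSettings)
    model: ModelSettings = field(default_factory=ModelSettings)
    isotemporal: IsotemporalSettings = field(default_factory=IsotemporalSettings)
    output: OutputSettings = field(default_factory=OutputSettings)

    def validate(self) -> "PipelineConfig":
        if self.closure_kappa <= 0:
            raise ConfigError("closure_kappa must be positive")
        if self.cohort.n < 10:
            raise ConfigError("cohort.n must be >= 10")
        if not 0 <= self.cohort.prop_rdcd <= 1:
            raise ConfigError("cohort.prop_rdcd must be in [0,1]")
        for k, v in self.cohort.missing_rates.items():
            if not 0 <= v <= 1:
                raise ConfigError(f"missing rate {k}={v} outside [0,1]")
        if self.impute.composition_scale not in ("ilr", "raw"):
            raise ConfigError("impute.composition_scale must be 'ilr' or 'raw'")
        if self.model.robust not in (True, False, "auto"):
            raise ConfigError("model.robust must be true, false or 'auto'")
        if not 0 < self.model.alpha < 1:
            raise ConfigError("model.alpha must be in (0,1)")
        if any(d < 0 for d in self.isotemporal.deltas):
            raise ConfigError("isotemporal deltas must be nonnegative")
        if self.accel.epoch_seconds <= 0 or 60 % self.accel.epoch_seconds:
            raise ConfigError("accel.epoch_seconds must divide 60")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        sections = {
            "cohort": CohortSettings,
            "accel": AccelSettings,
            "impute": ImputeSettings,
            "model": ModelSettings,
            "isotemporal": IsotemporalSettings,
            "output": OutputSettings,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sections:
                known = sections[key].__dataclass_fields__
                bad = set(val) - set(known)
                if bad:
                    raise ConfigError(f"unknown keys in {key}: {sorted(bad)}")
                kwargs[key] = sections[key](**val)
            elif key in ("seed", "closure_kappa"):
                kwargs[key] = val
            else:
                raise ConfigError(f"unknown config key {key!r}")
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
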