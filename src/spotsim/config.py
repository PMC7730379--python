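"""Scenario configuration: the single source of truth for units, defaults and seeds.

All times handed to the simulation engine are hours from simulation start
(t = 0 at midnight of day 1).  Durations given in days in the configuration
are converted exactly once, at load time, by the consumers of this module.
Every stochastic draw in a run flows from the root ``seed`` through
documented substreams (see :func:`substream`).
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ExposurePattern",
    "SampleTiming",
    "Standardization",
    "SamplingDayMode",
    "TimeWindows",
    "ScenarioConfig",
    "ConfigError",
    "default_accumulation_days",
    "load_config",
    "save_config",
    "substream",
]


class ConfigError(ValueError):
    """Raised for any invalid or unloadable scenario configuration."""


class ExposurePattern(str, enum.Enum):
    """Daily oral exposure pattern (1-3 events/day, random or fixed slots)."""

    once_random = "once_random"
    once_evening = "once_evening"
    twice_random = "twice_random"
    twice_morning_afternoon = "twice_morning_afternoon"
    thrice_random = "thrice_random"
    thrice_morning_afternoon_evening = "thrice_morning_afternoon_evening"

    @property
    def events_per_day(self) -> int:
        return {"once": 1, "twice": 2, "thrice": 3}[self.value.split("_", 1)[0]]

    @property
    def is_random(self) -> bool:
        return self.value.endswith("_random")


class SampleTiming(str, enum.Enum):
    """Which void (or composite) is collected on a sampling day."""

    random_void = "random_void"
    first_morning = "first_morning"
    first_evening = "first_evening"
    whole_day_volume_weighted = "whole_day_volume_weighted"


class Standardization(str, enum.Enum):
    """Urine-dilution standardization applied to collected concentrations."""

    none = "none"
    creatinine = "creatinine"
    specific_gravity = "specific_gravity"


class SamplingDayMode(str, enum.Enum):
    """How sampling days are placed inside the exposure window."""

    even = "even"
    random = "random"


class TimeWindows(BaseModel):
    """Time-of-day windows (hours) used by fixed-slot exposure patterns.

    ``waking`` bounds the "random time" draws.  Defaults describe plausible
    adult waking-hour behaviour and can be overridden in the config file.
    """

    model_config = ConfigDict(extra="forbid")

    morning: tuple[float, float] = (7.0, 10.0)
    afternoon: tuple[float, float] = (12.0, 15.0)
    evening: tuple[float, float] = (18.0, 22.0)
    waking: tuple[float, float] = (7.0, 23.0)

    @model_validator(mode="after")
    def _check(self) -> "TimeWindows":
        for name in ("morning", "afternoon", "evening", "waking"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo < hi <= 24.0):
                raise ValueError(f"time window '{name}' must satisfy 0 <= start < end <= 24")
        if not (self.morning[1] <= self.afternoon[0] and self.afternoon[1] <= self.evening[0]):
            raise ValueError("morning, afternoon and evening windows must be ordered and disjoint")
        return self


def default_accumulation_days(biological_half_life: float) -> float:
    """Default accumulation period: 7 elimination half-lives, floored at 14 days.

    Parameters
    ----------
    biological_half_life
        Elimination half-life in **hours**; must be positive.

    Returns
    -------
    float
        Accumulation period in days, ``max(14, 7 * t_half / 24)`` without
        rounding to whole days.
    """
    if not biological_half_life > 0:
        raise ConfigError("biological_half_life must be positive (hours)")
    return max(14.0, 7.0 * biological_half_life / 24.0)


class ScenarioConfig(BaseModel):
    """All user inputs of a simulation scenario.

    Durations are in the units stated per field (hours or days); GSDs are
    dimensionless geometric standard deviations (1 = no variability).
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # --- chemical ---
    biological_half_life: float = Field(gt=0, description="elimination half-life, hours")
    half_life_gsd: float = Field(default=1.3, ge=1.0)
    absorption_half_life: float = Field(default=0.4, gt=0, description="oral absorption half-life, hours")
    fraction_excreted: float = Field(default=1.0, gt=0, le=1.0, description="fraction of elimination excreted in urine as the measured analyte")

    # --- exposure ---
    exposure_pattern: ExposurePattern = ExposurePattern.once_random
    within_gsd: float = Field(default=3.0, ge=1.0)
    between_gsd: float = Field(default=2.0, ge=1.0)

    # --- design ---
    window_days: int = Field(default=7, ge=1, description="exposure period of interest, days")
    max_samples: int = Field(default=7, ge=1)
    sample_timing: SampleTiming = SampleTiming.random_void
    sampling_day_mode: SamplingDayMode = SamplingDayMode.even
    standardization: Standardization = Standardization.none
    sg_reference: float = Field(default=1.020, gt=1.0)

    # --- population / simulation ---
    n_individuals: int = Field(default=3000, ge=2)
    accumulation_days: float | None = None
    n_schedule_templates: int = Field(default=8, ge=1)
    schedule_days_per_template: int = Field(default=6, ge=1)
    time_windows: TimeWindows = Field(default_factory=TimeWindows)
    seed: int = Field(default=1, ge=0)

    @model_validator(mode="after")
    def _invariants(self) -> "ScenarioConfig":
        if self.accumulation_days is None:
            object.__setattr__(
                self, "accumulation_days", default_accumulation_days(self.biological_half_life)
            )
        elif not self.accumulation_days > 0:
            raise ValueError("accumulation_days must be positive")
        if self.max_samples > self.window_days:
            raise ValueError(
                f"max_samples ({self.max_samples}) exceeds window_days ({self.window_days}): "
                "at most one biomonitoring sample per day is allowed"
            )
        if self.absorption_half_life >= self.biological_half_life:
            raise ValueError(
                "absorption_half_life must be shorter than biological_half_life "
                "(first-order absorption faster than elimination)"
            )
        return self

    # -- derived quantities used across modules (all in hours / integer days) --

    @property
    def accumulation_days_int(self) -> int:
        """Accumulation period rounded up to whole simulated days."""
        return int(math.ceil(self.accumulation_days))

    @property
    def total_days(self) -> int:
        return self.accumulation_days_int + self.window_days

    @property
    def window_start_h(self) -> float:
        return 24.0 * self.accumulation_days_int

    @property
    def window_end_h(self) -> float:
        return 24.0 * self.total_days

    def to_dict(self) -> dict[str, Any]:
        d = self.model_dump(mode="json")
        return d


# ----------------------------------------------------------------------------
# RNG substream allocation
#
# Root entropy is the config seed.  Named stages get fixed slots so that the
# draws of individual i never depend on n_individuals or on other stages:
#   bank           -> (seed, 0)
#   individual i   -> (seed, 1, i, stage)   stage: 0=parameters, 1=exposure,
#                                                  2=schedule, 3=sampling
#   sampling days  -> (seed, 3)
# ----------------------------------------------------------------------------

_STAGES = {"bank": 0, "params": 0, "exposure": 1, "schedule": 2, "sampling": 3}


def substream(seed: int, kind: str, individual: int | None = None) -> np.random.Generator:
    """Return the dedicated RNG substream for a simulation stage.

    ``kind`` is ``"bank"`` (the schedule-template bank, shared by the run) or
    one of ``"params"``, ``"exposure"``, ``"schedule"``, ``"sampling"`` with an
    ``individual`` index.
    """
    if kind == "bank":
        return np.random.default_rng(np.random.SeedSequence([seed, 0]))
    if kind == "days":  # placement of sampling days inside the window
        return np.random.default_rng(np.random.SeedSequence([seed, 3]))
    if kind not in _STAGES or individual is None:
        raise ValueError(f"unknown substream kind {kind!r} / missing individual index")
    return np.random.default_rng(np.random.SeedSequence([seed, 1, individual, _STAGES[kind]]))


# ----------------------------------------------------------------------------
# Loading / saving (YAML; JSON files are rejected with a pointer to YAML)
# ----------------------------------------------------------------------------


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario from a YAML file.

    Defaults are filled for absent fields only; invalid values raise
    :class:`ConfigError` naming the offending field.  JSON files are not
    accepted: the documented configuration dialect is YAML.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix.lower() == ".json":
        raise ConfigError(
            f"{path}: JSON configs are not supported; write the same keys as YAML (.yaml/.yml)"
        )
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of scenario fields")
    return validate_config(raw)


def validate_config(raw: dict[str, Any]) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a mapping, with named field errors."""
    try:
        return ScenarioConfig(**raw)
    except Exception as exc:
        # pydantic's report already names fields; re-raise under our error type
        raise ConfigError(str(exc)) from exc


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Serialize a config to YAML such that ``load_config`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_checksum_payload(config: ScenarioConfig) -> str:
    """Canonical JSON snapshot of a config (used by the run manifest)."""
    return json.dumps(config.to_dict(), sort_keys=True)
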