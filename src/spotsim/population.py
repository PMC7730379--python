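"""Population sampling: per-individual parameters and timed oral exposure events.

Each simulated person carries a geometric-mean dose drawn from a log-normal
distribution with population geometric mean 1 and the between-person GSD, and
a personal elimination half-life drawn log-normally around the chemical's
half-life with the half-life GSD.  Exposure events occur every simulated day
(accumulation period included, so internal levels reach their long-run regime
before the observation window) with per-event doses log-normal around the
person's geometric mean with the within-person GSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ExposurePattern, ScenarioConfig, TimeWindows

__all__ = ["Individual", "ExposureEvents", "sample_individual", "sample_individuals", "generate_exposure_events"]


@dataclass(frozen=True)
class Individual:
    """Per-person sampled parameters."""

    index: int
    gm_dose: float      # person-level geometric-mean dose (arbitrary mass units)
    half_life: float    # person-level elimination half-life, hours
    schedule_id: int | None = None  # template assigned later by the scheduler

    def __post_init__(self) -> None:
        if not (self.gm_dose > 0 and self.half_life > 0):
            raise ValueError("gm_dose and half_life must be positive")


@dataclass(frozen=True)
class ExposureEvents:
    """Timed dose intakes for one individual, strictly ordered in time."""

    times: np.ndarray   # hours from simulation start
    doses: np.ndarray   # arbitrary mass units, > 0

    def __post_init__(self) -> None:
        if self.times.shape != self.doses.shape:
            raise ValueError("times and doses must align")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValueError("exposure events must be strictly time-ordered")


def sample_individual(index: int, config: ScenarioConfig, rng: np.random.Generator) -> Individual:
    """Draw one individual's geometric-mean dose and elimination half-life."""
    gm_dose = float(rng.lognormal(mean=0.0, sigma=np.log(config.between_gsd)))
    half_life = float(
        rng.lognormal(mean=np.log(config.biological_half_life), sigma=np.log(config.half_life_gsd))
    )
    return Individual(index=index, gm_dose=gm_dose, half_life=half_life)


def sample_individuals(
    config: ScenarioConfig, rngs: list[np.random.Generator]
) -> list[Individual]:
    """Draw ``n_individuals`` individuals, one dedicated RNG substream each."""
    if len(rngs) != config.n_individuals:
        raise ValueError("one RNG substream per individual is required")
    return [sample_individual(i, config, rng) for i, rng in enumerate(rngs)]


def _daily_event_times(
    pattern: ExposurePattern, windows: TimeWindows, n_days: int, rng: np.random.Generator
) -> np.ndarray:
    """Time-of-day (hours) for each day's exposure events, shape (n_days, k).

    Random patterns draw independently within waking hours and sort within the
    day; coincident times are re-drawn.  Fixed-slot patterns draw uniformly
    within their named window, which forces morning < afternoon < evening.
    """
    k = pattern.events_per_day
    if pattern.is_random:
        lo, hi = windows.waking
        tod = rng.uniform(lo, hi, size=(n_days, k))
        tod.sort(axis=1)
        if k > 1:  # re-draw the (measure-zero) coincident rows
            bad = np.where((np.diff(tod, axis=1) <= 0).any(axis=1))[0]
            for row in bad:
                t = rng.uniform(lo, hi, size=k)
                t.sort()
                while (np.diff(t) <= 0).any():
                    t = np.sort(rng.uniform(lo, hi, size=k))
                tod[row] = t
        return tod
    slots = {
        ExposurePattern.once_evening: [windows.evening],
        ExposurePattern.twice_morning_afternoon: [windows.morning, windows.afternoon],
        ExposurePattern.thrice_morning_afternoon_evening: [
            windows.morning,
            windows.afternoon,
            windows.evening,
        ],
    }[pattern]
    cols = [rng.uniform(lo, hi, size=n_days) for lo, hi in slots]
    return np.stack(cols, axis=1)


def generate_exposure_events(
    individual: Individual, config: ScenarioConfig, rng: np.random.Generator
) -> ExposureEvents:
    """Generate this individual's dose events over accumulation + window.

    Exactly ``events_per_day`` events on each of ``config.total_days`` days;
    per-event dose ~ log-normal(GM = the person's gm_dose, GSD = within_gsd).
    """
    n_days = config.total_days
    tod = _daily_event_times(config.exposure_pattern, config.time_windows, n_days, rng)
    times = (24.0 * np.arange(n_days)[:, None] + tod).ravel()
    doses = rng.lognormal(
        mean=np.log(individual.gm_dose), sigma=np.log(config.within_gsd), size=times.size
    )
    return ExposureEvents(times=times, doses=doses)
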