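"""Sample collection schemes and equal-volume pooling.

On each sampling day one value is "collected" per individual according to the
timing scheme: a uniformly chosen void, the day's first void, the first void
at or after 18:00 (falling back to the day's last void), or a whole-day
composite.  Pools of n samples are equal-volume, so the pooled concentration
is the unweighted arithmetic mean of the component concentrations; pools are
nested (the first n sampling days in chronological order), so the
reliability-versus-n curves reflect the effect of *adding* samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SampleTiming, SamplingDayMode, ScenarioConfig, Standardization
from .pk import VoidConcentrations
from .schedules import VoidSchedule

__all__ = ["CollectedSamples", "sampling_days", "select_samples", "pool", "pooled_means"]

EVENING_START_H = 18.0


@dataclass(frozen=True)
class CollectedSamples:
    """One individual's collected concentrations, ordered by sampling day."""

    day_indices: np.ndarray     # window-relative day of each sample
    concentrations: np.ndarray  # raw or standardized, per the scenario config
    scheme: SampleTiming

    def __post_init__(self) -> None:
        if self.day_indices.shape != self.concentrations.shape:
            raise ValueError("day_indices and concentrations must align")
        if self.day_indices.size and np.any(np.diff(self.day_indices) <= 0):
            raise ValueError("at most one sample per day, in chronological order")


def sampling_days(
    window_days: int,
    max_samples: int,
    mode: SamplingDayMode = SamplingDayMode.even,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Window-relative day indices on which samples are collected.

    ``even`` spreads max_samples days evenly over the window
    (round(j*(D-1)/(m-1)); a single sample lands on the window's midpoint
    day); ``random`` draws the days uniformly without replacement.
    """
    if max_samples > window_days:
        raise ValueError("max_samples cannot exceed window_days")
    if mode is SamplingDayMode.random:
        if rng is None:
            raise ValueError("random sampling-day mode needs an RNG")
        return np.sort(rng.choice(window_days, size=max_samples, replace=False))
    if max_samples == 1:
        return np.array([round((window_days - 1) / 2)])
    j = np.arange(max_samples)
    return np.rint(j * (window_days - 1) / (max_samples - 1)).astype(int)


def _standardized(conc: VoidConcentrations, standardization: Standardization) -> np.ndarray:
    return {
        Standardization.none: conc.raw,
        Standardization.creatinine: conc.creatinine_std,
        Standardization.specific_gravity: conc.sg_std,
    }[standardization]


def _whole_day_composite(
    conc: VoidConcentrations,
    schedule: VoidSchedule,
    idx: np.ndarray,
    standardization: Standardization,
    sg_reference: float,
) -> float:
    """Concentration a lab would measure on the day's pooled (24-h) urine.

    Raw: volume-weighted mean Σ(c·v)/Σ(v).  Creatinine-standardized: analyte
    mass per gram creatinine in the pool, Σ(c·v)/Σ(cr·v).  SG-standardized:
    the raw composite rescaled by the pool's volume-weighted specific gravity.
    """
    v = schedule.volumes[idx]
    mass = conc.excreted_mass[idx].sum()
    if standardization is Standardization.creatinine:
        return float(mass / (schedule.creatinine[idx] * v).sum())
    raw = mass / v.sum()
    if standardization is Standardization.specific_gravity:
        sg_pool = float((schedule.specific_gravity[idx] * v).sum() / v.sum())
        return float(raw * (sg_reference - 1.0) / (sg_pool - 1.0))
    return float(raw)


def select_samples(
    conc: VoidConcentrations,
    schedule: VoidSchedule,
    config: ScenarioConfig,
    days: np.ndarray,
    rng: np.random.Generator,
) -> CollectedSamples:
    """Collect one concentration per sampling day under the configured scheme.

    ``days`` are window-relative day indices (from :func:`sampling_days`);
    the schedule's ``day_index`` is absolute, so the window offset is added
    here.
    """
    scheme = config.sample_timing
    std = config.standardization
    values = np.empty(len(days))
    per_void = _standardized(conc, std)
    for k, day in enumerate(days):
        abs_day = config.accumulation_days_int + int(day)
        idx = np.flatnonzero(schedule.day_index == abs_day)
        if idx.size == 0:
            raise ValueError(f"no voids on simulated day {abs_day}; invalid schedule")
        if scheme is SampleTiming.whole_day_volume_weighted:
            values[k] = _whole_day_composite(conc, schedule, idx, std, config.sg_reference)
            continue
        if scheme is SampleTiming.random_void:
            pick = idx[int(rng.integers(idx.size))]
        elif scheme is SampleTiming.first_morning:
            pick = idx[0]
        elif scheme is SampleTiming.first_evening:
            tod = schedule.times[idx] % 24.0
            evening = idx[tod >= EVENING_START_H]
            pick = evening[0] if evening.size else idx[-1]
        else:  # pragma: no cover
            raise ValueError(f"unknown sample timing {scheme}")
        values[k] = per_void[pick]
    return CollectedSamples(day_indices=np.asarray(days, dtype=int), concentrations=values, scheme=scheme)


def pool(samples: CollectedSamples, n: int) -> float:
    """Equal-volume pool of the first ``n`` samples: their arithmetic mean."""
    total = samples.concentrations.size
    if not 1 <= n <= total:
        raise ValueError(f"pool size n={n} out of range 1..{total}")
    return float(samples.concentrations[:n].mean())


def pooled_means(sample_matrix: np.ndarray) -> dict[int, np.ndarray]:
    """Nested pooled concentrations for every n, across all individuals.

    ``sample_matrix`` is (n_individuals, max_samples), day-ordered; entry n of
    the result is the per-individual mean of the first n samples.
    """
    cums = np.cumsum(sample_matrix, axis=1)
    return {n: cums[:, n - 1] / n for n in range(1, sample_matrix.shape[1] + 1)}
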