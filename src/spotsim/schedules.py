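"""Synthetic urination schedules (void times, volumes, creatinine, specific gravity).

The simulator needs realistic void-by-void urine output for every simulated
person.  The generator below produces a bank of schedule *templates* — by
default 8 templates of 6 single-day void patterns each, mirroring a
multi-day diary study design — and each simulated individual is assigned one
template for the whole run, with one of its day patterns drawn (with
replacement) for every simulated day.

Generating rules (all configurable at the call site):

* daily void count uniform on {4, ..., 9};
* 24-h urine volume log-normal (GM 1.5 L, GSD 1.4), split across the day's
  voids by a symmetric Dirichlet (concentration 4) with double weight on the
  first (overnight) void;
* per-template daily creatinine excretion normal(1.2, 0.25) g/day truncated
  above 0.4 g/day; a void's creatinine concentration is the excretion accrued
  since the previous void (the first void of a day pools the overnight
  interval back to the previous evening's last void) divided by the void's
  volume;
* specific gravity tied to urine concentration as
  SG = 1 + 0.0075 * (creatinine g/L) / 0.45, clipped to [1.002, 1.035].

These rules are explicit stand-ins chosen so that 24-h volume, voiding
frequency and creatinine concentration fall in adult reference ranges; real
diary data can be supplied instead via :func:`load_schedules`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DayPattern",
    "ScheduleTemplate",
    "VoidSchedule",
    "ScheduleError",
    "build_template_bank",
    "assign_schedule",
    "load_schedules",
    "save_schedules",
]

SG_SLOPE = 0.0075 / 0.45  # specific-gravity increment per g/L creatinine
SG_MIN, SG_MAX = 1.002, 1.035


class ScheduleError(ValueError):
    """Invalid urination-schedule data."""


@dataclass(frozen=True)
class DayPattern:
    """One single-day void sequence (times are time-of-day in hours)."""

    times: np.ndarray        # strictly increasing, first void in 05:00-09:00
    volumes: np.ndarray      # liters, > 0
    creatinine: np.ndarray   # g/L, > 0
    specific_gravity: np.ndarray  # dimensionless, > 1

    def __post_init__(self) -> None:
        n = self.times.size
        if n < 3:
            raise ScheduleError("a day pattern needs at least 3 voids")
        if not np.all(np.diff(self.times) > 0):
            raise ScheduleError("void times within a day must be strictly increasing")
        if not (np.all(self.volumes > 0) and np.all(self.creatinine > 0)):
            raise ScheduleError("void volumes and creatinine must be positive")
        if not np.all(self.specific_gravity > 1.0):
            raise ScheduleError("specific gravity must exceed 1.000")

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    @property
    def creatinine_mass(self) -> float:
        """Total creatinine excreted over the day (g)."""
        return float((self.creatinine * self.volumes).sum())


@dataclass(frozen=True)
class ScheduleTemplate:
    template_id: int
    day_patterns: list[DayPattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.day_patterns:
            raise ScheduleError("a schedule template needs at least one day pattern")


@dataclass(frozen=True)
class VoidSchedule:
    """A full multi-day void sequence for one individual (absolute hours)."""

    template_id: int
    times: np.ndarray
    volumes: np.ndarray
    creatinine: np.ndarray
    specific_gravity: np.ndarray
    day_index: np.ndarray  # simulated day each void belongs to

    def __post_init__(self) -> None:
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ScheduleError("void times must be strictly increasing")


def _strictly_increasing_times(first: float, n_rest: int, rng: np.random.Generator) -> np.ndarray:
    """First void plus n_rest later voids, strictly increasing, before 23:45."""
    while True:
        rest = np.sort(rng.uniform(first + 0.25, 23.75, size=n_rest))
        t = np.concatenate([[first], rest])
        if np.all(np.diff(t) > 0):
            return t


def _make_day_pattern(daily_creatinine_g: float, rng: np.random.Generator) -> DayPattern:
    n_voids = int(rng.integers(4, 10))
    total_volume = rng.lognormal(mean=np.log(1.5), sigma=np.log(1.4))
    first = rng.uniform(5.0, 9.0)
    times = _strictly_increasing_times(first, n_voids - 1, rng)

    alpha = np.full(n_voids, 4.0)
    alpha[0] = 8.0  # overnight void pools more volume
    volumes = total_volume * rng.dirichlet(alpha)

    # Fraction of the 24-h day accrued by each void; the first void reaches
    # back overnight to the (self-consistent, repeating) previous day's last
    # void, so the fractions sum to exactly 1 and creatinine mass balances.
    gaps = np.empty(n_voids)
    gaps[0] = times[0] + 24.0 - times[-1]
    gaps[1:] = np.diff(times)
    fractions = gaps / 24.0
    creatinine = daily_creatinine_g * fractions / volumes
    sg = np.clip(1.0 + SG_SLOPE * creatinine, SG_MIN, SG_MAX)
    return DayPattern(times=times, volumes=volumes, creatinine=creatinine, specific_gravity=sg)


def build_template_bank(
    n_templates: int = 8, days_per_template: int = 6, rng: np.random.Generator | None = None
) -> list[ScheduleTemplate]:
    """Generate a synthetic bank of urination-schedule templates.

    The default bank (8 templates x 6 day patterns) stands in for a diary
    study of eight adults observed over six consecutive days.
    """
    if n_templates < 1 or days_per_template < 1:
        raise ScheduleError("n_templates and days_per_template must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    bank = []
    for tid in range(n_templates):
        daily_creatinine = float(rng.normal(1.2, 0.25))
        while daily_creatinine <= 0.4:
            daily_creatinine = float(rng.normal(1.2, 0.25))
        days = [_make_day_pattern(daily_creatinine, rng) for _ in range(days_per_template)]
        bank.append(ScheduleTemplate(template_id=tid, day_patterns=days))
    return bank


def assign_schedule(
    bank: list[ScheduleTemplate], n_days: int, rng: np.random.Generator
) -> VoidSchedule:
    """Assign one template and draw a day pattern for each simulated day.

    The template is selected uniformly once and kept for the whole simulation;
    day patterns are selected uniformly *with replacement* for each day and
    offset to absolute hours.
    """
    if not bank:
        raise ScheduleError("template bank is empty")
    if n_days <= 0:
        raise ScheduleError("n_days must be positive")
    template = bank[int(rng.integers(len(bank)))]
    picks = rng.integers(len(template.day_patterns), size=n_days)
    times, volumes, creat, sg, day_idx = [], [], [], [], []
    for day, p in enumerate(picks):
        pat = template.day_patterns[p]
        times.append(pat.times + 24.0 * day)
        volumes.append(pat.volumes)
        creat.append(pat.creatinine)
        sg.append(pat.specific_gravity)
        day_idx.append(np.full(pat.times.size, day))
    return VoidSchedule(
        template_id=template.template_id,
        times=np.concatenate(times),
        volumes=np.concatenate(volumes),
        creatinine=np.concatenate(creat),
        specific_gravity=np.concatenate(sg),
        day_index=np.concatenate(day_idx),
    )


# ----------------------------------------------------------------------------
# CSV interchange: template_id, day, time_of_day_h, volume_L, creatinine_gL,
# specific_gravity — one row per void.
# ----------------------------------------------------------------------------

_CSV_COLUMNS = ["template_id", "day", "time_of_day_h", "volume_L", "creatinine_gL", "specific_gravity"]


def load_schedules(path: str | Path | io.IOBase) -> list[ScheduleTemplate]:
    """Load user-supplied urination schedules from CSV, validating every row."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ScheduleError(f"schedule CSV is missing columns: {missing}")
    bank = []
    for tid, tdf in df.groupby("template_id", sort=True):
        days = []
        for day, ddf in tdf.groupby("day", sort=True):
            ddf = ddf.reset_index()
            bad = ddf.index[ddf["volume_L"] <= 0].tolist()
            if bad:
                raise ScheduleError(
                    f"template {tid} day {day}: non-positive volume at CSV row(s) "
                    f"{[int(ddf.loc[b, 'index']) + 2 for b in bad]}"
                )
            bad = ddf.index[ddf["specific_gravity"] <= 1.0].tolist()
            if bad:
                raise ScheduleError(
                    f"template {tid} day {day}: specific gravity <= 1 at CSV row(s) "
                    f"{[int(ddf.loc[b, 'index']) + 2 for b in bad]}"
                )
            t = ddf["time_of_day_h"].to_numpy(float)
            if not np.all(np.diff(t) > 0):
                raise ScheduleError(f"template {tid} day {day}: void times are not strictly increasing")
            try:
                days.append(
                    DayPattern(
                        times=t,
                        volumes=ddf["volume_L"].to_numpy(float),
                        creatinine=ddf["creatinine_gL"].to_numpy(float),
                        specific_gravity=ddf["specific_gravity"].to_numpy(float),
                    )
                )
            except ScheduleError as exc:
                raise ScheduleError(f"template {tid} day {day}: {exc}") from exc
        bank.append(ScheduleTemplate(template_id=int(tid), day_patterns=days))
    if not bank:
        raise ScheduleError("schedule CSV contains no templates")
    return bank


def save_schedules(bank: list[ScheduleTemplate], path: str | Path) -> None:
    """Write a template bank to the documented CSV interchange format."""
    rows = []
    for template in bank:
        for day, pat in enumerate(template.day_patterns):
            for i in range(pat.times.size):
                rows.append(
                    (template.template_id, day, pat.times[i], pat.volumes[i], pat.creatinine[i], pat.specific_gravity[i])
                )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
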