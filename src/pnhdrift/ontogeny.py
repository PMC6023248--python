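"""Ontogenic growth of the HSC pool and the replication-event clock.

The active hematopoietic stem cell pool grows from roughly 20 cells at birth
to roughly 400 cells in adulthood.  Each cell replicates about once per year,
so biological time is measured in replication events: when the number of
birth-death (division + differentiation) events equals the pool size, one
year has passed.  During ontogenic growth the Moran-like dynamics are
periodically interrupted by division-only events, inserted on a fixed
two-week grid, so that the pool tracks a deterministic growth curve.

This module is purely deterministic: it defines the growth curve, the pool
size as a function of age, and the exact ordered sequence of events
(`birth_death` or `growth_division`) between any two ages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "GrowthSchedule",
    "Event",
    "BIRTH_DEATH",
    "GROWTH_DIVISION",
    "pool_size_at_age",
    "event_schedule",
    "compressed_schedule",
    "cumulative_replications",
]

BIRTH_DEATH = "birth_death"
GROWTH_DIVISION = "growth_division"

#: Reference body-mass-for-age medians (kg), sexes averaged, used to shape the
#: default growth curve.  The cited derivation of the active HSC pool scales
#: it with body mass, so the pool fraction gained by age `a` follows the mass
#: fraction gained by age `a` (normalized birth -> maturity).
_REFERENCE_MASS_KG: Tuple[Tuple[float, float], ...] = (
    (0.0, 3.5),
    (0.5, 7.5),
    (1.0, 10.0),
    (2.0, 12.5),
    (3.0, 14.5),
    (4.0, 16.5),
    (5.0, 18.5),
    (6.0, 21.0),
    (7.0, 23.5),
    (8.0, 26.0),
    (9.0, 29.0),
    (10.0, 32.0),
    (11.0, 36.0),
    (12.0, 40.0),
    (13.0, 45.0),
    (14.0, 50.0),
    (15.0, 55.0),
    (16.0, 60.0),
    (17.0, 64.0),
    (18.0, 67.5),
)


@dataclass(frozen=True)
class GrowthSchedule:
    """Deterministic growth of the HSC pool and its event clock.

    Parameters
    ----------
    n_birth, n_adult
        Pool size at birth and at/after ``maturity_age`` (defaults 20, 400).
    maturity_age
        Age in years at which the pool reaches ``n_adult``.
    growth_interval_days
        Spacing of the grid on which growth (division-only) events are
        inserted; also the granularity of the event clock (default 14 days,
        i.e. 26 intervals per year).
    curve
        ``"mass_table"`` (default): pool gain proportional to body-mass gain
        from a reference mass-for-age table; ``"logistic"``: logistic in age
        with rate chosen so the pool rounds to ``n_adult`` at maturity;
        ``"table"``: user-supplied curve, ``curve_table`` = sequence of
        (age_years, pool_size) pairs.
    """

    n_birth: int = 20
    n_adult: int = 400
    maturity_age: float = 18.0
    growth_interval_days: float = 14.0
    curve: str = "mass_table"
    curve_table: Tuple[Tuple[float, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_birth < 1 or self.n_adult < self.n_birth:
            raise ValueError("need 1 <= n_birth <= n_adult")
        if self.maturity_age <= 0:
            raise ValueError("maturity_age must be positive")
        if self.growth_interval_days <= 0:
            raise ValueError("growth_interval_days must be positive")
        if self.curve not in ("mass_table", "logistic", "table"):
            raise ValueError(f"unknown curve form: {self.curve!r}")
        if self.curve == "table" and len(self.curve_table) < 2:
            raise ValueError("curve='table' requires curve_table points")

    @property
    def intervals_per_year(self) -> int:
        """Number of growth intervals per model year (26 for 14 days)."""
        return max(1, round(365.0 / self.growth_interval_days))

    # -- continuous curve -------------------------------------------------

    def _curve_value(self, age: np.ndarray) -> np.ndarray:
        """Raw (unrounded) pool size at the given ages."""
        a = np.minimum(np.asarray(age, dtype=float), self.maturity_age)
        if self.curve == "logistic":
            b = (self.n_adult - self.n_birth) / self.n_birth
            # steepness chosen so the curve rounds to n_adult at maturity
            k = math.log(b * (self.n_adult - 0.5) / 0.5) / self.maturity_age
            val = self.n_adult / (1.0 + b * np.exp(-k * a))
        elif self.curve == "table":
            tbl = np.asarray(self.curve_table, dtype=float)
            val = np.interp(a, tbl[:, 0], tbl[:, 1])
        else:  # mass_table
            tbl = np.asarray(_REFERENCE_MASS_KG)
            # rescale the reference age axis onto [0, maturity_age]
            ref_age = tbl[:, 0] * (self.maturity_age / tbl[-1, 0])
            mass = np.interp(a, ref_age, tbl[:, 1])
            g = (mass - tbl[0, 1]) / (tbl[-1, 1] - tbl[0, 1])
            val = self.n_birth + (self.n_adult - self.n_birth) * g
        val = np.where(np.asarray(age, dtype=float) >= self.maturity_age,
                       float(self.n_adult), val)
        return val

    # -- discrete per-interval table --------------------------------------

    def _interval_index(self, age: float) -> int:
        """Snap an age (years) to the event-clock grid."""
        if age < 0:
            raise ValueError("age must be non-negative")
        return round(age * self.intervals_per_year)

    def _pool_table(self, n_intervals: int) -> np.ndarray:
        """Integer pool size at each interval boundary 0..n_intervals."""
        ipy = self.intervals_per_year
        ages = np.arange(n_intervals + 1) / ipy
        raw = np.rint(self._curve_value(ages)).astype(int)
        raw = np.clip(raw, self.n_birth, self.n_adult)
        # enforce monotone non-decreasing pool size
        return np.maximum.accumulate(raw)


def pool_size_at_age(schedule: GrowthSchedule, age: float) -> int:
    """Integer HSC pool size at the given age (years).

    Piecewise constant between growth events; ``n_birth`` at age 0 and
    ``n_adult`` at and beyond maturity.
    """
    j = schedule._interval_index(age)
    return int(schedule._pool_table(j)[j])


@dataclass(frozen=True)
class Event:
    kind: str        # BIRTH_DEATH or GROWTH_DIVISION
    pool_size: int   # pool size *before* the event


def compressed_schedule(
    schedule: GrowthSchedule, from_age: float, to_age: float
) -> List[Tuple[str, int, int]]:
    """Ordered event runs between two ages as (kind, pool_size, count).

    Per two-week interval at pool size N, N/26 birth-death events are due;
    the fractional remainder is carried exactly (integer accumulator) so any
    whole adult year contains exactly ``n_adult`` birth-death events.  Growth
    (division-only) events are appended at the end of each interval to bring
    the pool to the next boundary's size.  The carry is defined from birth,
    so schedules over subranges are slices of the lifetime sequence.
    """
    if not 0 <= from_age:
        raise ValueError("from_age must be non-negative")
    if to_age < from_age:
        raise ValueError("to_age must be >= from_age")
    ipy = schedule.intervals_per_year
    j0 = schedule._interval_index(from_age)
    j1 = schedule._interval_index(to_age)
    pool = schedule._pool_table(max(j1, 1))

    runs: List[Tuple[str, int, int]] = []
    carry = 0
    for j in range(j1):
        n_now = int(pool[j])
        carry += n_now
        n_events, carry = divmod(carry, ipy)
        if j >= j0:
            if n_events:
                runs.append((BIRTH_DEATH, n_now, n_events))
            n_next = int(pool[j + 1])
            for size in range(n_now, n_next):
                runs.append((GROWTH_DIVISION, size, 1))
    return runs


def event_schedule(
    schedule: GrowthSchedule, from_age: float, to_age: float
) -> List[Event]:
    """Fully expanded ordered event sequence between two ages."""
    out: List[Event] = []
    for kind, size, count in compressed_schedule(schedule, from_age, to_age):
        out.extend(Event(kind, size) for _ in range(count))
    return out


def cumulative_replications(schedule: GrowthSchedule, age: float) -> int:
    """Total number of replication events (both kinds) from birth to `age`.

    Every event involves exactly one cell division, so this is the number of
    independent opportunities for a PIG-A mutation up to that age.
    """
    return sum(c for _, _, c in compressed_schedule(schedule, 0.0, age))
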