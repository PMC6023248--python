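"""Single-clone Moran-type Markov chain for PIG-A mutant dynamics.

State is the number of mutant cells m in a pool of N HSC.  One time step is
one birth-death event: a cell is selected (uniformly under neutrality, or
fitness-weighted) for division; a normal parent's daughter mutates with
probability mu; then one cell of the N+1 is selected for differentiation and
leaves the pool.  The master equation

    P_m[x+1] = sum_k p_{m,k} P_k[x]

is evolved numerically over the exact event sequence given by the ontogeny
module; division-only (growth) events use a rectangular operator that extends
the state space by one.

In the neutral, mutation-free case the chain is a symmetric frequency-
dependent random walk: p_{m+1,m} = p_{m-1,m} = (N m - m^2)/(N (N+1)), maximal
at m = N/2, with absorbing boundaries at m = 0 and m = N.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ontogeny import (
    BIRTH_DEATH,
    GROWTH_DIVISION,
    GrowthSchedule,
    compressed_schedule,
    pool_size_at_age,
)

__all__ = [
    "SelectionModel",
    "NEUTRAL",
    "PoolModel",
    "StateDistribution",
    "selection_division_probability",
    "build_birth_death_operator",
    "build_division_only_operator",
    "evolve",
    "run_chain",
    "ChainRun",
    "clinical_probability",
    "clinical_threshold_count",
    "first_passage_pmf",
]

logger = logging.getLogger(__name__)

#: total-probability drift tolerated before evolve raises
MASS_TOL = 1e-10
#: most negative probability entry tolerated (clamped to 0 below this scale)
NEG_TOL = -1e-14


@dataclass(frozen=True)
class SelectionModel:
    """Relative fitness of mutant (PIG-A) vs normal cells.

    ``r_pig_a == r_healthy`` reproduces the neutral dynamics exactly.  By
    default only the division pick is fitness-weighted; set
    ``weighted_differentiation`` to weight the differentiation pick as well.
    """

    r_pig_a: float = 1.0
    r_healthy: float = 1.0
    weighted_differentiation: bool = False

    def __post_init__(self) -> None:
        if self.r_pig_a <= 0 or self.r_healthy <= 0:
            raise ValueError("fitness factors must be positive")

    @property
    def is_neutral(self) -> bool:
        return self.r_pig_a == self.r_healthy


NEUTRAL = SelectionModel()


@dataclass(frozen=True)
class PoolModel:
    """All parameters of the stochastic HSC pool model.

    mu is the PIG-A mutation probability per replication (default 5e-7);
    replication rate is fixed at one per cell per year by the event clock in
    the growth schedule.
    """

    mu: float = 5e-7
    schedule: GrowthSchedule = field(default_factory=GrowthSchedule)
    selection: SelectionModel = NEUTRAL

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("mu must be in [0, 1)")


@dataclass
class StateDistribution:
    """Probability vector over mutant counts m = 0..N at a given age."""

    probabilities: np.ndarray
    age: float

    @property
    def pool_size(self) -> int:
        return len(self.probabilities) - 1

    def validate(self, tol: float = MASS_TOL) -> None:
        p = self.probabilities
        if p.min() < NEG_TOL:
            raise ValueError(f"negative probability {p.min():.3e}")
        if abs(p.sum() - 1.0) > tol:
            raise ValueError(f"probability mass drifted to {p.sum()!r}")

    def copy(self) -> "StateDistribution":
        return StateDistribution(self.probabilities.copy(), self.age)


def _clamp_roundoff(p: np.ndarray) -> np.ndarray:
    """Clamp tiny negative round-off to zero; genuine negatives are errors."""
    lo = p.min()
    if lo < 0.0:
        if lo < NEG_TOL:
            raise FloatingPointError(f"probability entry {lo:.3e} below {NEG_TOL}")
        logger.warning("clamping round-off negative probability %.3e to 0", lo)
        p = np.where(p < 0.0, 0.0, p)
    return p


def point_mass(N: int, m: int, age: float = 0.0) -> StateDistribution:
    """Distribution concentrated at m mutants in a pool of N."""
    if not 0 <= m <= N:
        raise ValueError("m must lie in 0..N")
    p = np.zeros(N + 1)
    p[m] = 1.0
    return StateDistribution(p, age)


def selection_division_probability(
    m, N: int, selection: SelectionModel = NEUTRAL
):
    """Probability that the cell picked for division is a mutant.

    r_pig_a * m / (r_pig_a * m + r_healthy * (N - m)); equals m/N when the
    fitness factors coincide.
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0) or np.any(m_arr > N):
        raise ValueError("m must lie in 0..N")
    if selection.is_neutral:
        out = m_arr / N  # exact reduction to the selection-free case
    else:
        w = selection.r_pig_a * m_arr
        out = w / (w + selection.r_healthy * (N - m_arr))
    return out if isinstance(m, np.ndarray) else float(out)


def _diff_pick(m, pool: int, selection: SelectionModel):
    """Probability the differentiating cell is a mutant, pool cells present."""
    m_arr = np.asarray(m, dtype=float)
    if selection.weighted_differentiation and not selection.is_neutral:
        w = selection.r_pig_a * m_arr
        return w / (w + selection.r_healthy * (pool - m_arr))
    return m_arr / pool


def build_birth_death_operator(
    N: int, mu: float, selection: SelectionModel = NEUTRAL
) -> sp.csr_matrix:
    """Tridiagonal (N+1)x(N+1) transition operator for one birth-death event.

    Column k holds the probabilities of moving from k mutants to k-1, k, k+1.
    Columns sum to one exactly (stay is computed as the complement of the
    analytic up/down entries, which themselves match the printed three-branch
    formulas).
    """
    if N < 1:
        raise ValueError("pool size must be >= 1")
    k = np.arange(N + 1, dtype=float)
    if mu == 0.0 and selection.is_neutral:
        # closed symmetric form: up = down = (N k - k^2)/(N (N+1)), exact
        up = down = (N * k - k * k) / (N * (N + 1.0))
    else:
        phi = selection_division_probability(k, N, selection)  # mutant divides
        psi_up = _diff_pick(k + 1, N + 1, selection)           # after +1 mutant
        psi_same = _diff_pick(k, N + 1, selection)             # mutant count k
        up = (phi + (1.0 - phi) * mu) * (1.0 - psi_up)         # k -> k+1
        down = (1.0 - phi) * (1.0 - mu) * psi_same             # k -> k-1
    stay = 1.0 - up - down
    # T[m, k]: offset -1 holds k -> k+1 moves, offset +1 holds k -> k-1 moves
    T = sp.diags(
        [up[:-1], stay, down[1:]], offsets=[-1, 0, 1], format="csr"
    )
    return T


def build_division_only_operator(
    N: int, mu: float, selection: SelectionModel = NEUTRAL
) -> sp.csr_matrix:
    """Rectangular (N+2)x(N+1) operator for a growth (division-only) event.

    One cell divides and no differentiation follows, so the pool grows from N
    to N+1 and the mutant count either stays (normal parent, no mutation) or
    increases by one (mutant parent, or mutated daughter of a normal parent).
    """
    if N < 1:
        raise ValueError("pool size must be >= 1")
    k = np.arange(N + 1, dtype=float)
    phi = selection_division_probability(k, N, selection)
    up = phi + (1.0 - phi) * mu
    stay = 1.0 - up
    rows = np.concatenate([np.arange(N + 1), np.arange(N + 1) + 1])
    cols = np.concatenate([np.arange(N + 1), np.arange(N + 1)])
    vals = np.concatenate([stay, up])
    return sp.csr_matrix((vals, (rows, cols)), shape=(N + 2, N + 1))


class _OperatorCache:
    """Per-run cache of transition operators keyed by (kind, N)."""

    def __init__(self, mu: float, selection: SelectionModel):
        self.mu = mu
        self.selection = selection
        self._ops: Dict[Tuple[str, int], sp.csr_matrix] = {}

    def get(self, kind: str, N: int) -> sp.csr_matrix:
        key = (kind, N)
        if key not in self._ops:
            if kind == BIRTH_DEATH:
                self._ops[key] = build_birth_death_operator(
                    N, self.mu, self.selection
                )
            else:
                self._ops[key] = build_division_only_operator(
                    N, self.mu, self.selection
                )
        return self._ops[key]


def evolve(
    model: PoolModel,
    initial: StateDistribution,
    from_age: float,
    to_age: float,
    _cache: Optional[_OperatorCache] = None,
) -> StateDistribution:
    """Evolve the master equation from `from_age` to `to_age`.

    The initial distribution must match the pool size at `from_age`; the
    returned distribution matches the pool size at `to_age`.  Probability
    mass is conserved to 1e-10 over a full lifetime (monitored, not
    renormalized).
    """
    expected_N = pool_size_at_age(model.schedule, from_age)
    if initial.pool_size != expected_N:
        raise ValueError(
            f"initial pool size {initial.pool_size} != schedule size "
            f"{expected_N} at age {from_age}"
        )
    cache = _cache or _OperatorCache(model.mu, model.selection)
    p = initial.probabilities.copy()
    for kind, N, count in compressed_schedule(model.schedule, from_age, to_age):
        T = cache.get(kind, N)
        for _ in range(count):
            p = T @ p
    p = _clamp_roundoff(p)
    out = StateDistribution(p, to_age)
    out.validate()
    return out


def clinical_threshold_count(N: int, threshold_fraction: float) -> int:
    """Smallest mutant count m with m/N at least the clinical threshold."""
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in (0, 1]")
    return math.ceil(threshold_fraction * N)


def clinical_probability(
    dist: StateDistribution, threshold_fraction: float = 0.2
) -> float:
    """P(m >= ceil(threshold * N)): probability of clinical PNH."""
    m_star = clinical_threshold_count(dist.pool_size, threshold_fraction)
    return float(dist.probabilities[m_star:].sum())


@dataclass
class ChainRun:
    """Yearly record of a single-clone chain evolution from birth.

    marginals[y] is the state distribution at integer age ``ages[y]``; the
    summary frame carries pool size and clinical probability per year.
    """

    model: PoolModel
    ages: np.ndarray
    pool_sizes: np.ndarray
    marginals: List[np.ndarray]
    summary: pd.DataFrame

    def distribution_at(self, age: int) -> StateDistribution:
        idx = int(np.searchsorted(self.ages, age))
        if idx >= len(self.ages) or self.ages[idx] != age:
            raise KeyError(f"age {age} not recorded")
        return StateDistribution(self.marginals[idx].copy(), float(age))


def run_chain(
    model: PoolModel,
    to_age: int = 100,
    threshold_fraction: float = 0.2,
) -> ChainRun:
    """Evolve from the all-normal state at birth, recording each year."""
    cache = _OperatorCache(model.mu, model.selection)
    dist = point_mass(pool_size_at_age(model.schedule, 0.0), 0)
    ages, pools, margs, p_clin = [], [], [], []
    for year in range(1, to_age + 1):
        dist = evolve(model, dist, year - 1.0, float(year), _cache=cache)
        ages.append(year)
        pools.append(dist.pool_size)
        margs.append(dist.probabilities.copy())
        p_clin.append(clinical_probability(dist, threshold_fraction))
    summary = pd.DataFrame(
        {"age": ages, "pool_size": pools, "p_clinical": p_clin}
    )
    return ChainRun(model, np.array(ages), np.array(pools), margs, summary)


def first_passage_pmf(
    model: PoolModel,
    threshold_fraction: float = 0.2,
    max_age: int = 100,
) -> pd.Series:
    """Per-year probability of first reaching the clinical threshold.

    States at or above ceil(threshold * N) are made absorbing: after every
    event, mass in the absorbing set is moved to an accumulator and removed,
    which keeps the bookkeeping exact while the pool (and hence the absolute
    threshold) grows.  The entry at age y is the probability that diagnosis
    occurs during year y; the cumulative sum is non-decreasing and <= 1.
    """
    cache = _OperatorCache(model.mu, model.selection)
    N0 = pool_size_at_age(model.schedule, 0.0)
    p = np.zeros(N0 + 1)
    p[0] = 1.0
    absorbed = 0.0
    yearly = np.zeros(max_age)
    prev_cum = 0.0
    for year in range(1, max_age + 1):
        for kind, N, count in compressed_schedule(
            model.schedule, year - 1.0, float(year)
        ):
            T = cache.get(kind, N)
            for _ in range(count):
                p = T @ p
                m_star = clinical_threshold_count(len(p) - 1, threshold_fraction)
                tail = p[m_star:].sum()
                if tail > 0.0:
                    absorbed += tail
                    p[m_star:] = 0.0
        yearly[year - 1] = absorbed - prev_cum
        prev_cum = absorbed
    return pd.Series(yearly, index=pd.RangeIndex(1, max_age + 1, name="age"),
                     name="first_passage")
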