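"""Post-diagnosis clone-fate statistics and closed-form arrival analytics.

Once a clone is established (diagnosis at 20% of the pool), its subsequent
fate under neutral drift is a frequency-dependent random walk: the mean
clone size is a martingale (exactly constant when mu = 0), the size
distribution widens and skews right, and recession below the clinical
threshold — or outright extinction — is a matter of time.  These analyses
evolve the adult single-clone chain from a point mass.

The waiting time to the k-th mutation in x independent replications is
negative-binomial; its cumulative distribution equals a binomial tail, which
provides a closed-form cross-check of the history chain's clone-existence
curves.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .moran_chain import (
    PoolModel,
    StateDistribution,
    _OperatorCache,
    clinical_threshold_count,
    point_mass,
)
from .ontogeny import BIRTH_DEATH

__all__ = [
    "postdiagnosis_distribution",
    "recession_probabilities",
    "expansion_fraction",
    "analytic_arrival_probability",
]


def _evolve_adult(
    model: PoolModel, dist: StateDistribution, years: int
) -> StateDistribution:
    """Evolve in the fixed adult pool: N birth-death events per year."""
    N = model.schedule.n_adult
    cache = _OperatorCache(model.mu, model.selection)
    T = cache.get(BIRTH_DEATH, N)
    p = dist.probabilities.copy()
    for _ in range(years * N):
        p = T @ p
    return StateDistribution(p, dist.age + years)


def postdiagnosis_distribution(
    model: PoolModel, start_fraction: float, years: int
) -> StateDistribution:
    """Clone-size distribution `years` after a clone held `start_fraction`.

    Starts from a point mass at m = ceil(start_fraction * N) in the adult
    pool and evolves whole adult years.
    """
    if not 0.0 < start_fraction < 1.0:
        raise ValueError("start_fraction must be in (0, 1)")
    if years < 0:
        raise ValueError("years must be non-negative")
    N = model.schedule.n_adult
    m0 = clinical_threshold_count(N, start_fraction)
    dist = point_mass(N, m0, age=0.0)
    if years == 0:
        return dist
    out = _evolve_adult(model, dist, years)
    out.validate()
    return out


def recession_probabilities(
    model: PoolModel,
    start_fraction: float,
    thresholds: Sequence[float] = (0.0, 0.05, 0.10, 0.15, 0.20),
    max_years: int = 50,
) -> pd.DataFrame:
    """P(clone below each threshold) per year after diagnosis.

    Rows are years since diagnosis (0..max_years), columns threshold
    fractions; the entry at (t, theta) is P(m < ceil(theta * N)) at year t
    starting from a point mass at ceil(start_fraction * N).  Threshold 0
    denotes outright extinction, P(m = 0).
    """
    if not 0.0 < start_fraction < 1.0:
        raise ValueError("start_fraction must be in (0, 1)")
    N = model.schedule.n_adult
    m0 = clinical_threshold_count(N, start_fraction)
    cache = _OperatorCache(model.mu, model.selection)
    T = cache.get(BIRTH_DEATH, N)
    p = np.zeros(N + 1)
    p[m0] = 1.0

    def row(pvec: np.ndarray) -> dict:
        out = {}
        for th in thresholds:
            if th == 0.0:
                out[th] = float(pvec[0])
            else:
                out[th] = float(pvec[: clinical_threshold_count(N, th)].sum())
        return out

    rows = [row(p)]
    for _ in range(max_years):
        for _ in range(N):
            p = T @ p
        rows.append(row(p))
    table = pd.DataFrame(rows, index=pd.RangeIndex(0, max_years + 1,
                                                   name="years_since_diagnosis"))
    table.columns.name = "threshold_fraction"
    return table


def expansion_fraction(
    model: PoolModel,
    start_fraction: float,
    gain: float = 5.0,
    horizon_years: int = 1,
    relative: bool = False,
) -> float:
    """P(clone grows by >= `gain` within the horizon).

    By default `gain` is in percentage points of the pool (a 20% clone
    reaching 25%), matching how clinical series report clone growth; set
    ``relative=True`` for a relative increase (20% reaching 21% for gain=5).
    """
    if not 0.0 < start_fraction < 1.0:
        raise ValueError("start_fraction must be in (0, 1)")
    if horizon_years < 0:
        raise ValueError("horizon_years must be non-negative")
    if horizon_years == 0:
        return 0.0
    N = model.schedule.n_adult
    m0 = clinical_threshold_count(N, start_fraction)
    if relative:
        target = start_fraction * (1.0 + gain / 100.0)
    else:
        target = start_fraction + gain / 100.0
    m_target = math.ceil(target * N)
    dist = _evolve_adult(model, point_mass(N, m0), horizon_years)
    if m_target > N:
        return 0.0
    return float(dist.probabilities[m_target:].sum())


def analytic_arrival_probability(k: int, replications: int, mu: float) -> float:
    """P(at least k mutation events in `replications` trials of rate mu).

    The waiting time to the k-th success is negative-binomial; its CDF at x
    trials equals the binomial tail P(Bin(x, mu) >= k).  For k = 1 this is
    1 - (1 - mu)^x.  Used as the closed-form check of the history chain's
    first/second clone existence probabilities.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if replications < 0:
        raise ValueError("replications must be non-negative")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be a probability")
    return float(stats.binom.sf(k - 1, replications, mu))
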