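"""Independent verification of the chain modules.

Two oracles, both implementing the update rules directly rather than through
transition operators:

* a vectorized Monte-Carlo agent simulator that draws every division,
  mutation and differentiation event per replicate (all replicates share the
  deterministic event schedule, so the ensemble is evolved with flat numpy
  arrays), and
* an exhaustive path enumerator for tiny pools that sums the probability of
  every (division choice, mutation outcome, differentiation choice) path at
  the level of individual cells, exact to floating precision.

Neither touches the operator-construction code they are used to check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .moran_chain import PoolModel, StateDistribution
from .multiclone_chain import (
    HistoryDistribution,
    HistoryState,
    StateSpace,
)
from .ontogeny import BIRTH_DEATH, GROWTH_DIVISION, event_schedule, pool_size_at_age

__all__ = [
    "TrajectoryEnsemble",
    "simulate",
    "compare_to_chain",
    "enumerate_exact",
    "sample_ensemble_from_distribution",
]


@dataclass
class TrajectoryEnsemble:
    """Recorded (history, m1, m2) snapshots of Monte-Carlo replicates."""

    n_reps: int
    seed: int
    ages: Tuple[float, ...]
    pool_sizes: Dict[float, int]
    hist: Dict[float, np.ndarray]
    m1: Dict[float, np.ndarray]
    m2: Dict[float, np.ndarray]

    def counts(self, age: float) -> np.ndarray:
        """Replicate counts per state index of the StateSpace at `age`."""
        space = StateSpace(self.pool_sizes[age])
        idx = space.index(self.hist[age], self.m1[age], self.m2[age])
        return np.bincount(idx, minlength=space.size)


def simulate(
    model: PoolModel,
    n_reps: int,
    seed: int,
    record_ages: Sequence[float],
    initial: Optional[HistoryState] = None,
    from_age: float = 0.0,
) -> TrajectoryEnsemble:
    """Agent-based Monte Carlo of the two-clone neutral dynamics.

    Each replicate follows the exact event schedule: at a birth-death event
    one of the N cells is drawn uniformly for division, a normal parent's
    daughter mutates with probability mu (advancing the history, at most
    twice), then one of the N+1 cells is drawn uniformly for differentiation.
    Growth events divide without differentiation.  Deterministic for a fixed
    (seed, n_reps).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not model.selection.is_neutral:
        raise NotImplementedError("simulator implements neutral dynamics only")
    record_ages = tuple(sorted(record_ages))
    if not record_ages:
        raise ValueError("need at least one recording age")
    rng = np.random.default_rng(seed)
    mu = model.mu

    N = pool_size_at_age(model.schedule, from_age)
    start = initial if initial is not None else HistoryState(0, 0, 0)
    if start.m1 + start.m2 > N:
        raise ValueError("initial clone sizes exceed pool size")
    h = np.full(n_reps, start.i, dtype=np.int64)
    m1 = np.full(n_reps, start.m1, dtype=np.int64)
    m2 = np.full(n_reps, start.m2, dtype=np.int64)

    out = TrajectoryEnsemble(n_reps, seed, record_ages, {}, {}, {}, {})

    def snapshot(age: float, pool: int) -> None:
        out.pool_sizes[age] = pool
        out.hist[age] = h.copy()
        out.m1[age] = m1.copy()
        out.m2[age] = m2.copy()

    prev_age = from_age
    for age in record_ages:
        events = event_schedule(model.schedule, prev_age, age)
        for ev in events:
            Nf = float(ev.pool_size)
            u_div = rng.random(n_reps)
            u_mut = rng.random(n_reps)
            # who divides: clone 1, clone 2, or a normal cell
            div1 = u_div < m1 / Nf
            div2 = ~div1 & (u_div < (m1 + m2) / Nf)
            divn = ~div1 & ~div2
            mutates = divn & (u_mut < mu) & (h < 2)
            # post-division counts among N+1 cells
            a1 = m1 + div1 + (mutates & (h == 0))
            a2 = m2 + div2 + (mutates & (h == 1))
            h = h + mutates
            if ev.kind == BIRTH_DEATH:
                u_dif = rng.random(n_reps)
                rem1 = u_dif < a1 / (Nf + 1.0)
                rem2 = ~rem1 & (u_dif < (a1 + a2) / (Nf + 1.0))
                m1 = a1 - rem1
                m2 = a2 - rem2
            else:  # growth division: pool grows, nobody leaves
                m1, m2 = a1, a2
            N = ev.pool_size + (1 if ev.kind == GROWTH_DIVISION else 0)
        snapshot(age, N)
        prev_age = age
    return out


def sample_ensemble_from_distribution(
    dist: HistoryDistribution, n_reps: int, seed: int
) -> TrajectoryEnsemble:
    """Draw i.i.d. states from an exact distribution (for calibration tests)."""
    rng = np.random.default_rng(seed)
    p = np.clip(dist.probabilities, 0.0, None)
    idx = rng.choice(len(p), size=n_reps, p=p / p.sum())
    sp_ = dist.space
    age = dist.age
    return TrajectoryEnsemble(
        n_reps,
        seed,
        (age,),
        {age: sp_.N},
        {age: sp_.hist[idx]},
        {age: sp_.m1[idx]},
        {age: sp_.m2[idx]},
    )


def _as_state_probs(dist, N: int) -> np.ndarray:
    """Exact probabilities over StateSpace(N) indices for either chain type."""
    if isinstance(dist, HistoryDistribution):
        if dist.space.N != N:
            raise ValueError("pool size mismatch between ensemble and chain")
        return dist.probabilities
    if isinstance(dist, StateDistribution):
        # single-clone distribution: embed as history-1 marginal over total
        # mutants irrespective of history (compared on m1 + m2)
        raise TypeError(
            "compare_to_chain expects a HistoryDistribution; lump the "
            "single-clone case through the history chain instead"
        )
    raise TypeError(f"unsupported distribution type {type(dist)!r}")


def compare_to_chain(
    ensemble: TrajectoryEnsemble,
    dist: HistoryDistribution,
    age: float,
    min_expected: float = 5.0,
) -> Dict[str, object]:
    """Divergence report between an ensemble and an exact distribution.

    Returns total-variation distance between the empirical and exact state
    distributions, plus a chi-square statistic over states pooled so every
    expected count is at least `min_expected` (remainder pooled into one
    cell).
    """
    if age not in ensemble.ages:
        raise ValueError(f"age {age} not recorded in ensemble")
    p = _as_state_probs(dist, ensemble.pool_sizes[age])
    obs = ensemble.counts(age).astype(float)
    n = obs.sum()
    emp = obs / n
    tv = 0.5 * float(np.abs(emp - p).sum())

    expected = p * n
    big = expected >= min_expected
    obs_cells = list(obs[big])
    exp_cells = list(expected[big])
    rest_o, rest_e = obs[~big].sum(), expected[~big].sum()
    if rest_e > 0:
        obs_cells.append(rest_o)
        exp_cells.append(rest_e)
    obs_arr = np.array(obs_cells)
    exp_arr = np.array(exp_cells) * (obs_arr.sum() / sum(exp_cells))
    if len(obs_arr) > 1:
        chi2, pval = stats.chisquare(obs_arr, exp_arr)
    else:
        chi2, pval = 0.0, 1.0
    return {
        "tv_distance": tv,
        "chi2": float(chi2),
        "p_value": float(pval),
        "n_reps": int(n),
        "n_cells": len(obs_arr),
        "expected": expected,
        "observed": obs,
    }


def enumerate_exact(
    N: int,
    mu: float,
    steps: int,
    start: HistoryState = HistoryState(0, 0, 0),
    kind: str = BIRTH_DEATH,
    max_pool: int = 6,
    max_steps: int = 5,
) -> HistoryDistribution:
    """Exhaustive path enumeration of the two-clone dynamics for tiny pools.

    Every path is enumerated at the level of individual cells: each of the N
    cells is a candidate parent with probability 1/N, normal parents branch
    on mutation (probability mu, histories 0 and 1 only), and each of the
    N+1 post-division cells is a candidate for differentiation with
    probability 1/(N+1).  Sums of path probabilities are exact to floating
    precision and independent of the transition-tensor code.
    """
    if N > max_pool:
        raise ValueError(f"exhaustive enumeration limited to N <= {max_pool}")
    if steps > max_steps:
        raise ValueError(f"exhaustive enumeration limited to {max_steps} steps")
    if start.m1 + start.m2 > N:
        raise ValueError("start state exceeds pool size")

    probs: Dict[Tuple[int, int, int], float] = {tuple(start): 1.0}
    pool = N
    for _ in range(steps):
        nxt: Dict[Tuple[int, int, int], float] = {}
        for (i, s1, s2), prob in probs.items():
            n_normal = pool - s1 - s2
            # division: enumerate each cell as parent (1/pool each)
            for parent in ("c1",) * s1 + ("c2",) * s2 + ("nn",) * n_normal:
                p_div = prob / pool
                if parent == "nn" and i < 2:
                    branches = [(mu, True), (1.0 - mu, False)]
                else:
                    branches = [(1.0, False)]
                for p_mut, mutated in branches:
                    if p_mut == 0.0:
                        continue
                    j = i + (1 if mutated else 0)
                    b1 = s1 + (parent == "c1") + (mutated and i == 0)
                    b2 = s2 + (parent == "c2") + (mutated and i == 1)
                    p_branch = p_div * p_mut
                    if kind == GROWTH_DIVISION:
                        key = (j, b1, b2)
                        nxt[key] = nxt.get(key, 0.0) + p_branch
                        continue
                    # differentiation: each of pool+1 cells leaves (uniform)
                    b_normal = pool + 1 - b1 - b2
                    for leaves, cnt in (("c1", b1), ("c2", b2), ("nn", b_normal)):
                        if cnt == 0:
                            continue
                        key = (
                            j,
                            b1 - (leaves == "c1"),
                            b2 - (leaves == "c2"),
                        )
                        p_leaf = p_branch * cnt / (pool + 1)
                        nxt[key] = nxt.get(key, 0.0) + p_leaf
        probs = nxt
        if kind == GROWTH_DIVISION:
            pool += 1

    space = StateSpace(pool)
    vec = np.zeros(space.size)
    for (i, s1, s2), prob in probs.items():
        vec[space.index(i, s1, s2)] += prob
    return HistoryDistribution(space, vec, float(steps))
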