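"""History-augmented two-clone Markov chain.

To distinguish clonally unrelated PIG-A populations the state space is
augmented with a *history* index i counting how many independent mutation
events have ever occurred (0, 1 or 2).  A state is (i, m1, m2) where m1 is
the size of the first-arisen clone and m2 the second's; "a clone arose and
later died" (i = 1, m1 = 0) is a different state from "no clone ever arose"
(i = 0).  Whenever a normal cell's division produces a mutated daughter the
history advances and the new clone is seeded at size 1 *before* the
differentiation pick, so the tensor stays nearest-neighbour; in the final
history (i = 2) further mutations are disabled, so the two-clone chain is
exact up to the (negligible at mu = 5e-7) probability of a third mutation.

The master equation over this space,

    P^i_{m1,m2}[x+1] = sum_{j,m1',m2'} p^{i,j}_{m1,m2,m1',m2'} P^j_{m1',m2'}[x],

is evolved with the same event schedule as the single-clone chain; only
neutral dynamics are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .moran_chain import (
    MASS_TOL,
    PoolModel,
    _clamp_roundoff,
    clinical_threshold_count,
)
from .ontogeny import (
    BIRTH_DEATH,
    GROWTH_DIVISION,
    compressed_schedule,
    pool_size_at_age,
)

__all__ = [
    "HistoryState",
    "StateSpace",
    "HistoryDistribution",
    "enumerate_state_space",
    "build_history_tensor",
    "evolve_history",
    "run_history_chain",
    "HistoryRun",
    "clinical_clone_count_probabilities",
    "extinct_fraction",
    "clone_arrival_pmf",
]


class HistoryState(NamedTuple):
    """One state of the augmented chain: history index and both clone sizes."""

    i: int
    m1: int
    m2: int


class StateSpace:
    """Indexed enumeration of all valid (i, m1, m2) states for pool size N.

    Ordering: the single i=0 state, then i=1 states by m1 = 0..N, then i=2
    states in lexicographic (m1, m2) order with m1 + m2 <= N.  The mapping is
    a stable bijection; total count is 1 + (N+1) + (N+1)(N+2)/2.
    """

    def __init__(self, N: int):
        if N < 1:
            raise ValueError("pool size must be >= 1")
        self.N = N
        self.size = 1 + (N + 1) + (N + 1) * (N + 2) // 2
        hist = np.empty(self.size, dtype=np.int64)
        m1 = np.empty(self.size, dtype=np.int64)
        m2 = np.empty(self.size, dtype=np.int64)
        hist[0], m1[0], m2[0] = 0, 0, 0
        hist[1 : N + 2] = 1
        m1[1 : N + 2] = np.arange(N + 1)
        m2[1 : N + 2] = 0
        pos = N + 2
        for a in range(N + 1):
            width = N + 1 - a
            hist[pos : pos + width] = 2
            m1[pos : pos + width] = a
            m2[pos : pos + width] = np.arange(width)
            pos += width
        self.hist, self.m1, self.m2 = hist, m1, m2
        self._i2_offset = N + 2

    def index(self, i, m1, m2):
        """Flat index of state(s) (i, m1, m2); vectorized over arrays."""
        i = np.asarray(i)
        m1 = np.asarray(m1)
        m2 = np.asarray(m2)
        N = self.N
        off = self._i2_offset
        # offset of the m1 row inside the i=2 triangle
        row = m1 * (N + 1) - m1 * (m1 - 1) // 2
        idx = np.where(
            i == 0, 0, np.where(i == 1, 1 + m1, off + row + m2)
        )
        return idx if idx.ndim else int(idx)

    def states(self) -> List[HistoryState]:
        return [
            HistoryState(int(i), int(a), int(b))
            for i, a, b in zip(self.hist, self.m1, self.m2)
        ]

    def total_mutants(self) -> np.ndarray:
        return self.m1 + self.m2


def enumerate_state_space(N: int) -> List[HistoryState]:
    """All valid history states for pool size N, in canonical index order."""
    return StateSpace(N).states()


@dataclass
class HistoryDistribution:
    """Probability vector over the history-augmented state space at an age."""

    space: StateSpace
    probabilities: np.ndarray
    age: float

    @property
    def pool_size(self) -> int:
        return self.space.N

    def validate(self, tol: float = MASS_TOL) -> None:
        if abs(self.probabilities.sum() - 1.0) > tol:
            raise ValueError(
                f"probability mass drifted to {self.probabilities.sum()!r}"
            )

    def p_history(self, i: int) -> float:
        return float(self.probabilities[self.space.hist == i].sum())

    def total_mutant_marginal(self) -> np.ndarray:
        """Distribution of m1 + m2, the total mutant count."""
        return np.bincount(
            self.space.total_mutants(),
            weights=self.probabilities,
            minlength=self.space.N + 1,
        )

    def copy(self) -> "HistoryDistribution":
        return HistoryDistribution(self.space, self.probabilities.copy(), self.age)


def initial_history_distribution(N: int, age: float = 0.0) -> HistoryDistribution:
    """All mass on the no-mutation-ever state."""
    space = StateSpace(N)
    p = np.zeros(space.size)
    p[0] = 1.0
    return HistoryDistribution(space, p, age)


def _coo_parts(rows, cols, vals):
    """Concatenate branch arrays, dropping structural zeros."""
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    v = np.concatenate(vals)
    keep = v != 0.0
    return r[keep], c[keep], v[keep]


def build_history_tensor(N: int, mu: float, kind: str) -> sp.csr_matrix:
    """Sparse transition tensor (flattened to a matrix) for one event.

    ``kind="birth_death"`` maps the N-space onto itself; ``kind=
    "growth_division"`` maps the N-space onto the (N+1)-space.  Within a
    history the moves mirror the single-clone operator applied to whichever
    subpopulation divides/differentiates (chosen proportionally to counts,
    neutrally); a mutating normal division advances the history and seeds the
    new clone at size 1 before differentiation; in history 2 the mutation
    channel is off.
    """
    if kind not in (BIRTH_DEATH, GROWTH_DIVISION):
        raise ValueError(f"unknown event kind {kind!r}")
    src = StateSpace(N)
    dst = src if kind == BIRTH_DEATH else StateSpace(N + 1)
    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []

    def add(col_idx, i, m1, m2, prob):
        rows.append(np.asarray(dst.index(i, m1, m2)).ravel())
        cols.append(np.asarray(col_idx).ravel())
        vals.append(np.asarray(prob, dtype=float).ravel())

    Nf = float(N)

    # --- i = 0: the single mutation-free state ---------------------------
    c0 = np.array([0])
    if kind == BIRTH_DEATH:
        # normal divides; daughter mutates with prob mu -> clone 1 seeded at
        # size 1 among N+1 cells, then one cell differentiates.
        add(c0, [0], [0], [0], [1.0 - mu])
        add(c0, [1], [1], [0], [mu * Nf / (Nf + 1.0)])   # a normal leaves
        add(c0, [1], [0], [0], [mu / (Nf + 1.0)])        # the new mutant leaves
    else:
        add(c0, [0], [0], [0], [1.0 - mu])
        add(c0, [1], [1], [0], [mu])

    # --- i = 1: one clone of size m1, n = N - m1 normals ------------------
    m1 = np.arange(N + 1, dtype=np.int64)
    n = N - m1
    cols1 = src.index(np.ones_like(m1), m1, np.zeros_like(m1))
    m1f, nf = m1.astype(float), n.astype(float)
    one = np.ones_like(m1)
    zero = np.zeros_like(m1)
    if kind == BIRTH_DEATH:
        d1 = m1f / Nf                       # clone 1 divides
        dn_no = (nf / Nf) * (1.0 - mu)      # normal divides, no mutation
        dn_mu = (nf / Nf) * mu              # normal divides, daughter mutates
        # clone-1 division: counts (m1+1, n) among N+1
        add(cols1, one, m1, zero, d1 * (m1f + 1.0) / (Nf + 1.0))
        add(cols1, one, m1 + 1, zero, d1 * nf / (Nf + 1.0))
        # normal division without mutation: counts (m1, n+1)
        add(cols1, one, np.maximum(m1 - 1, 0), zero,
            dn_no * m1f / (Nf + 1.0))
        add(cols1, one, m1, zero, dn_no * (nf + 1.0) / (Nf + 1.0))
        # normal division with mutation: counts (m1, 1, n) among N+1 -> i=2
        add(cols1, 2 * one, np.maximum(m1 - 1, 0), one,
            dn_mu * m1f / (Nf + 1.0))
        add(cols1, 2 * one, m1, zero, dn_mu * 1.0 / (Nf + 1.0))
        add(cols1, 2 * one, m1, one, dn_mu * nf / (Nf + 1.0))
    else:
        add(cols1, one, m1 + 1, zero, m1f / Nf)
        add(cols1, one, m1, zero, (nf / Nf) * (1.0 - mu))
        add(cols1, 2 * one, m1, one, (nf / Nf) * mu)

    # --- i = 2: clones m1, m2, n normals; no further mutations ------------
    sel = src.hist == 2
    a = src.m1[sel]
    b = src.m2[sel]
    n2 = N - a - b
    cols2 = src.index(src.hist[sel], a, b)
    af, bf, n2f = a.astype(float), b.astype(float), n2.astype(float)
    two = np.full_like(a, 2)
    if kind == BIRTH_DEATH:
        d1 = af / Nf
        d2 = bf / Nf
        dn = n2f / Nf
        # clone 1 divides: counts (a+1, b, n)
        add(cols2, two, a, b, d1 * (af + 1.0) / (Nf + 1.0))
        add(cols2, two, a + 1, np.maximum(b - 1, 0), d1 * bf / (Nf + 1.0))
        add(cols2, two, a + 1, b, d1 * n2f / (Nf + 1.0))
        # clone 2 divides: counts (a, b+1, n)
        add(cols2, two, np.maximum(a - 1, 0), b + 1, d2 * af / (Nf + 1.0))
        add(cols2, two, a, b, d2 * (bf + 1.0) / (Nf + 1.0))
        add(cols2, two, a, b + 1, d2 * n2f / (Nf + 1.0))
        # normal divides (never mutates in the final history)
        add(cols2, two, np.maximum(a - 1, 0), b, dn * af / (Nf + 1.0))
        add(cols2, two, a, np.maximum(b - 1, 0), dn * bf / (Nf + 1.0))
        add(cols2, two, a, b, dn * (n2f + 1.0) / (Nf + 1.0))
    else:
        add(cols2, two, a + 1, b, af / Nf)
        add(cols2, two, a, b + 1, bf / Nf)
        add(cols2, two, a, b, n2f / Nf)

    r, c, v = _coo_parts(rows, cols, vals)
    T = sp.csr_matrix(
        sp.coo_matrix((v, (r, c)), shape=(dst.size, src.size))
    )
    return T


class _TensorCache:
    def __init__(self, mu: float):
        self.mu = mu
        self._ops: Dict[Tuple[str, int], sp.csr_matrix] = {}

    def get(self, kind: str, N: int) -> sp.csr_matrix:
        key = (kind, N)
        if key not in self._ops:
            self._ops[key] = build_history_tensor(N, self.mu, kind)
            # growth-phase tensors are used briefly; keep the cache small
            if len(self._ops) > 4:
                for k in list(self._ops):
                    if k != key and k[1] != N and len(self._ops) > 2:
                        del self._ops[k]
        return self._ops[key]


def evolve_history(
    model: PoolModel,
    initial: HistoryDistribution,
    from_age: float,
    to_age: float,
    _cache: Optional[_TensorCache] = None,
) -> HistoryDistribution:
    """Evolve the history-augmented master equation between two ages."""
    if not model.selection.is_neutral:
        raise NotImplementedError(
            "the multi-clone chain implements neutral dynamics only"
        )
    expected_N = pool_size_at_age(model.schedule, from_age)
    if initial.pool_size != expected_N:
        raise ValueError(
            f"initial pool size {initial.pool_size} != schedule size "
            f"{expected_N} at age {from_age}"
        )
    cache = _cache or _TensorCache(model.mu)
    p = initial.probabilities.copy()
    N = initial.pool_size
    for kind, size, count in compressed_schedule(model.schedule, from_age, to_age):
        T = cache.get(kind, size)
        for _ in range(count):
            p = T @ p
        if kind == GROWTH_DIVISION:
            N = size + 1
    p = _clamp_roundoff(p)
    out = HistoryDistribution(StateSpace(N), p, to_age)
    out.validate()
    return out


def clinical_clone_count_probabilities(
    dist: HistoryDistribution, threshold_fraction: float = 0.2
) -> Tuple[float, float]:
    """(P(clinical with exactly one live clone), P(clinical with two)).

    Clinical means m1 + m2 >= ceil(threshold * N); the clone count is the
    number of currently non-empty clones, so a patient whose second clone
    already died counts as monoclonal.
    """
    sp_ = dist.space
    m_star = clinical_threshold_count(sp_.N, threshold_fraction)
    clinical = (sp_.m1 + sp_.m2) >= m_star
    live = (sp_.m1 > 0).astype(int) + (sp_.m2 > 0).astype(int)
    p = dist.probabilities
    return (
        float(p[clinical & (live == 1)].sum()),
        float(p[clinical & (live == 2)].sum()),
    )


def extinct_fraction(dist: HistoryDistribution) -> float:
    """Expected extinct arisen clones over expected arisen clones.

    A clone has *arisen* once its mutation event happened (1 clone in history
    1, 2 in history 2) and is *extinct* when its current size is 0.  Raises
    if no clone has ever arisen.
    """
    sp_ = dist.space
    p = dist.probabilities
    arisen = float(p[sp_.hist == 1].sum() + 2.0 * p[sp_.hist == 2].sum())
    if arisen <= 0.0:
        raise ValueError("no clone has ever arisen; extinct fraction undefined")
    dead = (
        ((sp_.hist >= 1) & (sp_.m1 == 0)).astype(int)
        + ((sp_.hist == 2) & (sp_.m2 == 0)).astype(int)
    )
    extinct = float((dead * p).sum())
    return extinct / arisen


@dataclass
class HistoryRun:
    """Yearly record of a history-chain evolution from birth.

    ``summary`` columns: age, pool_size, p_any_clone (P(i >= 1)), p_two
    (P(i = 2)), p_clinical, p_clinical_mono, p_clinical_bi, extinct_fraction.
    ``mutant_marginals[y]`` is the distribution of total mutants m1 + m2 at
    age ``ages[y]`` (length pool_size + 1).  Full distributions are kept only
    at ``record_ages``.
    """

    model: PoolModel
    ages: np.ndarray
    pool_sizes: np.ndarray
    summary: pd.DataFrame
    mutant_marginals: List[np.ndarray]
    distributions: Dict[int, HistoryDistribution]

    def distribution_at(self, age: int) -> HistoryDistribution:
        if age not in self.distributions:
            raise KeyError(f"age {age} was not recorded; use record_ages")
        return self.distributions[age]


def run_history_chain(
    model: PoolModel,
    to_age: int = 100,
    threshold_fraction: float = 0.2,
    record_ages: Sequence[int] = (),
) -> HistoryRun:
    """Evolve the two-clone chain from birth, recording yearly summaries."""
    cache = _TensorCache(model.mu)
    dist = initial_history_distribution(pool_size_at_age(model.schedule, 0.0))
    rows = []
    marginals: List[np.ndarray] = []
    kept: Dict[int, HistoryDistribution] = {}
    ages = np.arange(1, to_age + 1)
    for year in ages:
        dist = evolve_history(model, dist, year - 1.0, float(year), _cache=cache)
        mono, bi = clinical_clone_count_probabilities(dist, threshold_fraction)
        p_any = 1.0 - dist.p_history(0)
        p_two = dist.p_history(2)
        rows.append(
            {
                "age": int(year),
                "pool_size": dist.pool_size,
                "p_any_clone": p_any,
                "p_two": p_two,
                "p_clinical": mono + bi,
                "p_clinical_mono": mono,
                "p_clinical_bi": bi,
                "extinct_fraction": extinct_fraction(dist) if p_any > 0 else np.nan,
            }
        )
        marginals.append(dist.total_mutant_marginal())
        if int(year) in record_ages:
            kept[int(year)] = dist.copy()
    summary = pd.DataFrame(rows)
    return HistoryRun(
        model,
        ages,
        summary["pool_size"].to_numpy(),
        summary,
        marginals,
        kept,
    )


def clone_arrival_pmf(
    source, which: str = "first", max_age: int = 100, **run_kwargs
) -> pd.Series:
    """Per-year probability that the first (or second) clone arises.

    ``source`` is either a PoolModel (the chain is run internally) or an
    existing HistoryRun.  Entries are year-on-year differences of
    P(i >= 1) (first) or P(i = 2) (second); the cumulative sum is the
    existence probability curve.
    """
    if which not in ("first", "second"):
        raise ValueError("which must be 'first' or 'second'")
    if isinstance(source, HistoryRun):
        run = source
    else:
        run = run_history_chain(source, to_age=max_age, **run_kwargs)
    col = "p_any_clone" if which == "first" else "p_two"
    cum = run.summary.set_index("age")[col].loc[:max_age]
    pmf = cum.diff()
    pmf.iloc[0] = cum.iloc[0]
    pmf.name = f"{which}_clone_arrival"
    return pmf
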