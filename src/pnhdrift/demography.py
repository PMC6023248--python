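"""Census folding: population-level prevalence, clone sizes and event ages.

The chain gives per-individual, per-age probabilities; population-level
quantities follow by weighting with an age pyramid q_y (fraction of the
population at age y, ages 1..100).  Prevalence of a condition C is

    sum_y q_y * sum_{m in C} w_{y,m}

with w_{y,m} the probability that an individual of age y carries m mutant
cells in total, and the mean clone size over a size range m >= m0 is the
ratio sum m w q / sum w q restricted to that range (expressed as a fraction
of the pool, since the pool size itself depends on age).

A smooth synthetic pyramid generator and an approximate reconstruction of
the 2010 US single-year-of-age distribution (from published five-year bin
totals) are provided; the latter is a synthetic stand-in, not census data.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .moran_chain import ChainRun, clinical_threshold_count
from .multiclone_chain import HistoryRun

__all__ = [
    "AgePyramid",
    "CloneSizeByAgeTable",
    "read_age_pyramid",
    "synthetic_age_pyramid",
    "us_2010_pyramid_synthetic",
    "fold_prevalence",
    "average_clone_size",
    "mean_event_age",
]

logger = logging.getLogger(__name__)

AGE_MIN, AGE_MAX = 1, 100


@dataclass
class AgePyramid:
    """Population age fractions q_y over ages 1..100."""

    fractions: np.ndarray                  # length 100, sums to 1
    total_population: Optional[float] = None

    def __post_init__(self) -> None:
        q = np.asarray(self.fractions, dtype=float)
        if q.shape != (AGE_MAX,):
            raise ValueError("pyramid must cover ages 1..100")
        if (q < 0).any():
            raise ValueError("age fractions must be non-negative")
        s = q.sum()
        if s <= 0:
            raise ValueError("pyramid has no mass")
        self.fractions = q / s

    @property
    def ages(self) -> np.ndarray:
        return np.arange(AGE_MIN, AGE_MAX + 1)


def read_age_pyramid(path) -> AgePyramid:
    """Read a pyramid from CSV with columns `age` and `count` (or `fraction`).

    Ages outside 1..100 are dropped with a warning; duplicate ages and
    negative counts are errors naming the offending rows.
    """
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "age" not in df.columns:
        raise ValueError(f"{path}: missing 'age' column")
    value_col = "count" if "count" in df.columns else (
        "fraction" if "fraction" in df.columns else None
    )
    if value_col is None:
        raise ValueError(f"{path}: need a 'count' or 'fraction' column")
    ages = df["age"].to_numpy()
    if not np.issubdtype(np.asarray(ages).dtype, np.number):
        raise ValueError(f"{path}: non-numeric ages")
    dup = df["age"][df["age"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate age rows: {sorted(set(dup))}")
    neg = df[df[value_col] < 0]
    if len(neg):
        raise ValueError(
            f"{path}: negative {value_col} at ages {neg['age'].tolist()}"
        )
    in_window = (df["age"] >= AGE_MIN) & (df["age"] <= AGE_MAX)
    if (~in_window).any():
        logger.warning(
            "%s: dropping %d rows outside ages %d-%d",
            path, int((~in_window).sum()), AGE_MIN, AGE_MAX,
        )
        df = df[in_window]
    counts = np.zeros(AGE_MAX)
    counts[df["age"].to_numpy(dtype=int) - 1] = df[value_col].to_numpy(float)
    total = float(counts.sum()) if value_col == "count" else None
    return AgePyramid(counts, total_population=total)


def synthetic_age_pyramid(
    plateau_age: int = 60,
    decline: float = 1.0,
    jitter: float = 0.0,
    seed: int = 0,
    total_population: Optional[float] = None,
) -> AgePyramid:
    """Smooth, roughly US-like synthetic pyramid.

    Constant weight up to `plateau_age`, then a linear decline losing
    `decline` of the plateau height by age 100 (``decline=0`` gives a uniform
    pyramid).  Optional multiplicative jitter (lognormal, deterministic for a
    given seed) roughens the profile.
    """
    if not 0 <= decline <= 1:
        raise ValueError("decline must be in [0, 1]")
    if not AGE_MIN <= plateau_age <= AGE_MAX:
        raise ValueError("plateau_age must be in 1..100")
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    w = np.where(
        ages <= plateau_age,
        1.0,
        1.0 - decline * (ages - plateau_age) / (AGE_MAX - plateau_age),
    )
    w = np.clip(w, 0.0, None)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        w = w * np.exp(rng.normal(0.0, jitter, size=w.shape))
    return AgePyramid(w, total_population=total_population)


def us_2010_pyramid_synthetic() -> AgePyramid:
    """Approximate single-year 2010 US age distribution (synthetic stand-in).

    Reconstructed from published five-year-bin totals, spread uniformly
    within bins; not the Census Bureau's single-year table.
    """
    ref = importlib.resources.files("pnhdrift.data").joinpath(
        "us_age_pyramid_2010_synthetic.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return read_age_pyramid(path)


@dataclass
class CloneSizeByAgeTable:
    """w_{y,m}: probability an individual of age y carries m mutants in total.

    Rows are ages 1..100; row y has support 0..pool_sizes[y-1] and is padded
    with zeros up to the adult pool size.  Built from a yearly chain run
    (single-clone or history-augmented).
    """

    w: np.ndarray               # shape (100, n_adult + 1)
    pool_sizes: np.ndarray      # shape (100,)

    @classmethod
    def from_run(cls, run: Union[ChainRun, HistoryRun]) -> "CloneSizeByAgeTable":
        marginals = (
            run.mutant_marginals if isinstance(run, HistoryRun) else run.marginals
        )
        if len(run.ages) < AGE_MAX or run.ages[0] != AGE_MIN:
            raise ValueError("run must record every age 1..100")
        n_adult = int(run.pool_sizes.max())
        w = np.zeros((AGE_MAX, n_adult + 1))
        for row, marg in zip(w, marginals[:AGE_MAX]):
            row[: len(marg)] = marg
        return cls(w, run.pool_sizes[:AGE_MAX].astype(int))

    def validate(self, tol: float = 1e-10) -> None:
        err = np.abs(self.w.sum(axis=1) - 1.0).max()
        if err > tol:
            raise ValueError(f"table rows drift from 1 by {err:.2e}")


Condition = Callable[[np.ndarray, int], np.ndarray]


def fold_prevalence(
    table: CloneSizeByAgeTable,
    pyramid: AgePyramid,
    condition: Condition,
):
    """Per-capita prevalence of a condition on (mutant count, pool size).

    ``condition(m_array, N)`` returns a boolean mask over mutant counts
    0..N.  Returns the prevalence, or ``(prevalence, expected_count)`` when
    the pyramid carries a total population size.
    """
    q = pyramid.fractions
    prev = 0.0
    for y in range(AGE_MAX):
        N = int(table.pool_sizes[y])
        mask = np.asarray(condition(np.arange(N + 1), N), dtype=bool)
        prev += q[y] * float(table.w[y, : N + 1][mask].sum())
    if pyramid.total_population is not None:
        return prev, prev * pyramid.total_population
    return prev


def clinical_condition(threshold_fraction: float = 0.2) -> Condition:
    """Condition selecting clinical PNH: m >= ceil(threshold * N)."""
    def cond(m: np.ndarray, N: int) -> np.ndarray:
        return m >= clinical_threshold_count(N, threshold_fraction)
    return cond


def subclinical_condition(threshold_fraction: float = 0.2) -> Condition:
    """Condition selecting carriers below the clinical threshold."""
    def cond(m: np.ndarray, N: int) -> np.ndarray:
        return (m >= 1) & (m < clinical_threshold_count(N, threshold_fraction))
    return cond


def average_clone_size(
    table: CloneSizeByAgeTable,
    pyramid: AgePyramid,
    m0: Union[int, float] = 0,
) -> float:
    """Mean clone size, as a fraction of the pool, over clones of size >= m0.

    Implements the census-weighted ratio sum(m w q) / sum(w q) with both sums
    restricted to m >= m0; a float m0 in (0, 1) is interpreted per age as the
    fraction ceil(m0 * N).  With m0 = 0 the denominator is exactly 1 (each
    row of w sums to one).  Raises when no mass satisfies the condition.
    """
    q = pyramid.fractions
    num = 0.0
    den = 0.0
    for y in range(AGE_MAX):
        N = int(table.pool_sizes[y])
        lo = (
            clinical_threshold_count(N, m0)
            if isinstance(m0, float) and 0.0 < m0 < 1.0
            else int(m0)
        )
        m = np.arange(lo, N + 1)
        wy = table.w[y, lo : N + 1]
        num += q[y] * float((m / N * wy).sum())
        den += q[y] * float(wy.sum())
    if den <= 0.0:
        raise ValueError("no probability mass above m0; mean size undefined")
    return num / den


def mean_event_age(event_pmf: pd.Series, pyramid: AgePyramid):
    """Age distribution of an event in the population, and its mean.

    ``event_pmf`` gives the per-year probability of the event (e.g. first
    clone arrival or diagnosis) for an individual, indexed by age 1..100.
    The population age-at-event distribution is proportional to
    pmf(y) * q_y, normalized to 1; returns (distribution, mean age).
    """
    pmf = event_pmf.reindex(np.arange(AGE_MIN, AGE_MAX + 1), fill_value=0.0)
    w = pmf.to_numpy(dtype=float) * pyramid.fractions
    total = w.sum()
    if total <= 0.0:
        raise ValueError("event pmf has no mass on ages 1..100")
    dist = pd.Series(
        w / total, index=pd.RangeIndex(AGE_MIN, AGE_MAX + 1, name="age"),
        name="age_at_event",
    )
    mean = float((dist.index.to_numpy() * dist.to_numpy()).sum())
    return dist, mean
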