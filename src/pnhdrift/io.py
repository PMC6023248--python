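"""CSV/JSON serialization of distributions and summaries.

All writers have matching readers so outputs round-trip without loss; JSON
is written with sorted keys and no timestamps so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .moran_chain import StateDistribution
from .multiclone_chain import HistoryDistribution, StateSpace

__all__ = [
    "write_state_distribution",
    "read_state_distribution",
    "write_history_distribution",
    "read_history_distribution",
    "write_json",
]


def write_state_distribution(dist: StateDistribution, path) -> None:
    """CSV with columns age, m, probability (all states, including zeros)."""
    pd.DataFrame(
        {
            "age": dist.age,
            "m": np.arange(dist.pool_size + 1),
            "probability": dist.probabilities,
        }
    ).to_csv(path, index=False)


def read_state_distribution(path) -> StateDistribution:
    df = pd.read_csv(path)
    df = df.sort_values("m")
    if not (df["m"].to_numpy() == np.arange(len(df))).all():
        raise ValueError(f"{path}: state column m is not contiguous from 0")
    return StateDistribution(df["probability"].to_numpy(float),
                             float(df["age"].iloc[0]))


def write_history_distribution(dist: HistoryDistribution, path) -> None:
    """CSV with columns age, i, m1, m2, probability."""
    sp_ = dist.space
    pd.DataFrame(
        {
            "age": dist.age,
            "i": sp_.hist,
            "m1": sp_.m1,
            "m2": sp_.m2,
            "probability": dist.probabilities,
        }
    ).to_csv(path, index=False)


def read_history_distribution(path) -> HistoryDistribution:
    df = pd.read_csv(path)
    N = int((df["m1"] + df["m2"]).max())
    space = StateSpace(N)
    if len(df) != space.size:
        raise ValueError(f"{path}: expected {space.size} states, got {len(df)}")
    p = np.zeros(space.size)
    idx = space.index(df["i"].to_numpy(), df["m1"].to_numpy(), df["m2"].to_numpy())
    p[idx] = df["probability"].to_numpy(float)
    return HistoryDistribution(space, p, float(df["age"].iloc[0]))


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
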