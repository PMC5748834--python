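"""Train/test splitting.

Two entry points: an explicit list of 1-based test indices, or a seeded
activity-stratified draw ("selection based on the activities"): compounds are
ranked by activity, binned into quantile strata, and a fixed fraction of each
stratum is drawn into the test set. The compounds with the global minimum and
maximum activity are always kept in training so the test set never requires
extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem_io import ActivityRecord


@dataclass
class Partition:
    """A disjoint cover of compounds 1..n by training and test indices."""

    train_indices: list[int]
    test_indices: list[int]
    seed: int | None
    ratio: float

    def __post_init__(self):
        train, test = set(self.train_indices), set(self.test_indices)
        if not train or not test:
            raise ValueError("both train and test sets must be non-empty")
        if train & test:
            raise ValueError("train and test sets overlap")
        n = len(self.train_indices) + len(self.test_indices)
        if train | test != set(range(1, n + 1)):
            raise ValueError("partition does not cover compounds 1..n exactly once")

    @property
    def n(self) -> int:
        return len(self.train_indices) + len(self.test_indices)

    def train_positions(self) -> list[int]:
        """0-based row positions of the training compounds."""
        return [i - 1 for i in self.train_indices]

    def test_positions(self) -> list[int]:
        return [i - 1 for i in self.test_indices]


def _activity_array(activities: Sequence[ActivityRecord] | Sequence[float]) -> np.ndarray:
    vals = [a.value if isinstance(a, ActivityRecord) else float(a)
            for a in activities]
    return np.asarray(vals, dtype=float)


def split_by_activity(
    activities: Sequence[ActivityRecord] | Sequence[float],
    ratio: float = 0.2,
    seed: int = 0,
) -> Partition:
    """Seeded, activity-stratified split.

    Compounds are sorted by activity and cut into ``min(5, n // 5)`` quantile
    strata; within each stratum ``round(ratio × stratum size)`` compounds are
    drawn uniformly (without replacement) into the test set from a dedicated
    random stream. The global activity minimum and maximum are excluded from
    the draw. Same seed, same partition.
    """
    y = _activity_array(activities)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 compounds to split, got {n}")
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"test ratio must be in (0, 1), got {ratio}")

    order = np.argsort(y, kind="stable")
    forced_train = {int(order[0]), int(order[-1])}  # extremes stay in training

    n_strata = min(5, n // 5)
    strata = np.array_split(order, n_strata)

    rng = np.random.default_rng(seed)
    test_pos: list[int] = []
    for stratum in strata:
        k = int(np.floor(ratio * len(stratum) + 0.5))
        candidates = sorted(int(i) for i in stratum if int(i) not in forced_train)
        k = min(k, len(candidates))
        if k > 0:
            picked = rng.choice(candidates, size=k, replace=False)
            test_pos.extend(int(i) for i in picked)

    test_idx = sorted(p + 1 for p in test_pos)
    if not test_idx:
        raise ValueError("ratio too small: empty test set")
    if len(test_idx) >= n:
        raise ValueError("ratio too large: empty training set")
    train_idx = sorted(set(range(1, n + 1)) - set(test_idx))
    return Partition(train_indices=train_idx, test_indices=test_idx,
                     seed=seed, ratio=ratio)


def split_explicit(n: int, test_indices: Sequence[int]) -> Partition:
    """Partition with exactly the given 1-based test indices."""
    test = [int(i) for i in test_indices]
    if not test:
        raise ValueError("explicit test set must be non-empty")
    if len(set(test)) != len(test):
        raise ValueError(f"duplicate test indices: {sorted(test)}")
    bad = [i for i in test if not (1 <= i <= n)]
    if bad:
        raise ValueError(f"test indices out of range 1..{n}: {bad}")
    train = sorted(set(range(1, n + 1)) - set(test))
    if len(train) < 2:
        raise ValueError("explicit test set leaves fewer than 2 training compounds")
    ratio = len(test) / n
    return Partition(train_indices=train, test_indices=sorted(test),
                     seed=None, ratio=ratio)
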