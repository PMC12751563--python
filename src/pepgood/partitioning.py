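"""Similarity-threshold out-of-distribution partitioning (CCPart style).

At a threshold ``t`` the dataset is viewed as a graph with an edge wherever
pairwise similarity >= t.  Connected components are indivisible: each goes
wholly to train or test, which guarantees that no train-test pair reaches
the threshold.  Components are moved to the test side smallest-first until
the test fraction reaches its target (default 20%); a partition is *valid*
when the test side holds at least 18.5% of the data (20% with a 1.5%
margin) and the train side is non-empty.

Sweeping a grid of thresholds yields the partition sweep from which the
*dynamic range* is read: the spread (in percentage points of similarity)
between the smallest and largest thresholds that admit a valid partition.
The count of valid partitions is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .similarity import SimilarityMatrix

MIN_TEST_FRACTION = 0.185


@dataclass(frozen=True)
class ThresholdGrid:
    """Evenly spaced similarity thresholds in [start, stop]."""

    start: float = 0.0
    stop: float = 1.0
    step: float = 0.05

    def __post_init__(self):
        if not (0 <= self.start < self.stop <= 1):
            raise ValueError("need 0 <= start < stop <= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def thresholds(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        ts = self.start + self.step * np.arange(n)
        return np.round(ts[ts <= self.stop + 1e-9], 10)


@dataclass
class Partition:
    """One train/test split at a similarity threshold."""

    threshold: float
    train_ids: List[str]
    test_ids: List[str]
    valid: bool
    test_fraction: float

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test overlap")


@dataclass
class PartitionSweep:
    """Partitions over an ordered threshold grid."""

    grid: ThresholdGrid
    partitions: List[Partition] = field(default_factory=list)

    def valid_partitions(self) -> List[Partition]:
        return [p for p in self.partitions if p.valid]

    def valid_thresholds(self) -> List[float]:
        return [p.threshold for p in self.valid_partitions()]


def _components(values: np.ndarray, threshold: float) -> np.ndarray:
    adj = values >= threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def ccpart(sim: SimilarityMatrix, threshold: float, test_target: float = 0.20,
           min_test: float = MIN_TEST_FRACTION) -> Partition:
    """Split a dataset at one similarity threshold via connected components.

    Components (similarity-linked groups at >= threshold) are assigned to
    the test set in ascending size order — ties broken by lexicographically
    smallest member id — until the test fraction reaches ``test_target`` or
    only one component remains, which is always reserved for train.  The
    split therefore never places a pair with similarity >= threshold across
    the train/test boundary.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    if not (0 < min_test <= test_target < 1):
        raise ValueError("need 0 < min_test <= test_target < 1")
    n = len(sim)
    if n < 2:
        raise ValueError("cannot partition fewer than 2 records")
    ids = list(sim.ids)
    labels = _components(sim.values, threshold)
    comp_members: dict = {}
    for idx, lab in enumerate(labels):
        comp_members.setdefault(int(lab), []).append(idx)
    comps = sorted(comp_members.values(),
                   key=lambda m: (len(m), min(ids[i] for i in m)))
    test_idx: List[int] = []
    n_test = 0
    for ci, members in enumerate(comps):
        if n_test / n >= test_target:
            break
        if ci == len(comps) - 1:
            break  # the largest component is always reserved for train
        test_idx.extend(members)
        n_test += len(members)
    test_set = set(test_idx)
    train_ids = [ids[i] for i in range(n) if i not in test_set]
    test_ids = [ids[i] for i in sorted(test_set)]
    frac = len(test_ids) / n
    valid = frac >= min_test and len(train_ids) > 0
    return Partition(threshold=float(threshold), train_ids=train_ids,
                     test_ids=test_ids, valid=valid, test_fraction=frac)


def partition_sweep(sim: SimilarityMatrix, grid: ThresholdGrid = ThresholdGrid(),
                    test_target: float = 0.20,
                    min_test: float = MIN_TEST_FRACTION) -> PartitionSweep:
    """CCPart at every grid threshold (deterministic)."""
    parts = [ccpart(sim, float(t), test_target, min_test)
             for t in grid.thresholds]
    return PartitionSweep(grid=grid, partitions=parts)


def dynamic_range(sweep: PartitionSweep) -> Tuple[float, int]:
    """(max - min valid threshold) x 100, and the count of valid partitions.

    With fewer than two valid partitions the spread is 0 (the count still
    reports 0 or 1).
    """
    ts = sweep.valid_thresholds()
    if len(ts) < 2:
        return 0.0, len(ts)
    return 100.0 * (max(ts) - min(ts)), len(ts)


def leakage(sim: SimilarityMatrix, p: Partition) -> float:
    """Largest train-test similarity of a partition (diagnostic)."""
    idx = {i: k for k, i in enumerate(sim.ids)}
    tr = [idx[i] for i in p.train_ids]
    te = [idx[i] for i in p.test_ids]
    if not tr or not te:
        return 0.0
    return float(sim.values[np.ix_(tr, te)].max())


def partition_to_frame(p: Partition):
    import pandas as pd

    rows = [{"id": i, "split": "train", "threshold": p.threshold}
            for i in p.train_ids]
    rows += [{"id": i, "split": "test", "threshold": p.threshold}
             for i in p.test_ids]
    return pd.DataFrame(rows)
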