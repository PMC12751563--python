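"""Molecular-weight-matched negative sampling.

Bioactivity datasets published with positives only need negatives drawn
from peptides with other activities.  To avoid the classifier learning a
trivial size signal, the negatives are sampled so their molecular-weight
distribution matches the positives': the positives' MW distribution is
split into quantile bins and the pool is sampled per bin, falling back to
the nearest-MW unused pool records when a bin is underpopulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .monomers import seq_to_smiles
from .peptides import PeptideDataset, PeptideRecord

logger = logging.getLogger(__name__)

N_BINS = 10


def molecular_weight(smiles: str) -> float:
    """Average molecular weight in Daltons (implicit hydrogens included)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return float(Descriptors.MolWt(mol))


def record_weight(rec: PeptideRecord) -> float:
    smi = rec.smiles if rec.smiles is not None else seq_to_smiles(rec.sequence)
    return molecular_weight(smi)


@dataclass
class MWProfile:
    """Molecular weights of a record set with quantile bin edges."""

    weights: np.ndarray
    edges: np.ndarray

    @classmethod
    def from_dataset(cls, ds: PeptideDataset, n_bins: int = N_BINS) -> "MWProfile":
        w = np.array([record_weight(r) for r in ds])
        qs = np.linspace(0, 1, n_bins + 1)
        edges = np.quantile(w, qs)
        edges[0] -= 1e-9  # make the lowest weight fall inside bin 0
        return cls(weights=w, edges=edges)

    def bin_of(self, weight: float) -> int:
        idx = int(np.searchsorted(self.edges, weight, side="right")) - 1
        return int(np.clip(idx, 0, len(self.edges) - 2))

    def bin_counts(self) -> np.ndarray:
        counts = np.zeros(len(self.edges) - 1, dtype=int)
        for w in self.weights:
            counts[self.bin_of(w)] += 1
        return counts


def sample_mw_matched_negatives(positives: PeptideDataset,
                                pool: PeptideDataset, seed: int = 0,
                                n_bins: int = N_BINS
                                ) -> Tuple[PeptideDataset, int]:
    """Draw |positives| negatives from the pool, matched on molecular weight.

    Sampling is without replacement, per quantile bin of the positives' MW
    distribution, deterministic given the seed.  Pool records sharing a
    sequence or SMILES with a positive are excluded (leakage prevention).
    Bins the pool cannot fill are topped up with the nearest-MW unused pool
    records; the fallback count is returned alongside the dataset, whose
    labels are all set to 0.
    """
    pos_ids = set(positives.ids)
    overlap = pos_ids & set(pool.ids)
    if overlap:
        raise ValueError(f"pool shares ids with positives: {sorted(overlap)[:5]}")
    pos_keys = {(r.sequence, r.smiles) for r in positives}
    candidates = [r for r in pool
                  if (r.sequence, r.smiles) not in pos_keys]
    if len(candidates) < len(positives):
        raise ValueError(
            f"pool too small: {len(candidates)} usable candidates for "
            f"{len(positives)} positives")
    rng = np.random.default_rng(seed)
    profile = MWProfile.from_dataset(positives, n_bins=n_bins)
    target = profile.bin_counts()
    pool_w = np.array([record_weight(r) for r in candidates])
    pool_bins = np.array([profile.bin_of(w) for w in pool_w])
    chosen: List[int] = []
    chosen_set: set = set()
    deficit_bins: List[Tuple[int, int]] = []
    for b in range(len(target)):
        members = np.flatnonzero(pool_bins == b)
        take = min(target[b], members.size)
        if take:
            picked = rng.choice(members, size=take, replace=False)
            chosen.extend(int(i) for i in picked)
            chosen_set.update(int(i) for i in picked)
        if take < target[b]:
            deficit_bins.append((b, int(target[b] - take)))
    fallback = 0
    for b, need in deficit_bins:
        center = (profile.edges[b] + profile.edges[b + 1]) / 2
        unused = [i for i in range(len(candidates)) if i not in chosen_set]
        unused.sort(key=lambda i: abs(pool_w[i] - center))
        for i in unused[:need]:
            chosen.append(i)
            chosen_set.add(i)
            fallback += 1
    if fallback:
        logger.info("negative sampling: %d records filled by nearest-MW "
                    "fallback", fallback)
    records = [replace(candidates[i], label=0.0) for i in sorted(chosen)]
    ds = PeptideDataset(f"{positives.name}-negatives", positives.task, records)
    return ds, fallback
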