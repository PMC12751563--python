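"""Synthetic peptide benchmarks with a planted structure-activity rule.

The generator emulates the shape of small peptide bioactivity datasets:
short sequences (<= 50 residues), an optional fraction of chemically
modified records rendered as SMILES, and binary or continuous labels that
follow a smooth rule so that molecular similarity correlates with label
similarity — the property the partitioning framework assumes.

Construction: ``K`` cluster motif templates are drawn at random; each
record copies its cluster's motif with independent per-position mutations
(rate ``mutation_rate``), which plants block structure in any sensible
similarity function.  The latent score is

    score = hydrophobic fraction + cluster effect + N(0, noise_sd)

so labels vary smoothly within clusters and jump between them.  Regression
keeps the score; classification thresholds it at the dataset median.
Modified records substitute 1-2 monomers with templates from the modified
monomer library before SMILES assembly; the substitution is label-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .monomers import (CANONICAL_FRAGMENTS, CANONICAL_LETTERS,
                       MODIFIED_FRAGMENTS, assemble_smiles, seq_to_smiles)
from .peptides import (CLASSIFICATION, MODIFIED, REGRESSION, STANDARD,
                       PeptideDataset, PeptideRecord)

HYDROPHOBIC = set("AVLIMFC")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic benchmark generator."""

    n: int = 300
    length_range: Tuple[int, int] = (8, 25)
    modified_fraction: float = 0.0
    task: str = CLASSIFICATION
    noise_sd: float = 0.2
    seed: int = 0
    n_clusters: int = 8
    mutation_rate: float = 0.15
    monomer_library: List[str] = field(
        default_factory=lambda: sorted(MODIFIED_FRAGMENTS))

    def __post_init__(self):
        lo, hi = self.length_range
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if not (2 <= lo <= hi <= 50):
            raise ValueError("length_range must satisfy 2 <= min <= max <= 50")
        if not 0 <= self.modified_fraction <= 1:
            raise ValueError("modified_fraction must lie in [0, 1]")
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ValueError(f"unknown task {self.task!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    letters = list(seq)
    for i in range(len(letters)):
        if rng.random() < rate:
            letters[i] = CANONICAL_LETTERS[rng.integers(len(CANONICAL_LETTERS))]
    return "".join(letters)


def generate_dataset(cfg: GeneratorConfig,
                     name: Optional[str] = None) -> PeptideDataset:
    """Generate a labeled peptide dataset under the planted rule.

    Deterministic given ``cfg.seed``.  Standard records carry both sequence
    and SMILES; modified records carry SMILES only (their monomers have no
    faithful one-letter form).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    motifs = []
    for _ in range(cfg.n_clusters):
        length = int(rng.integers(lo, hi + 1))
        motifs.append("".join(
            CANONICAL_LETTERS[i]
            for i in rng.integers(len(CANONICAL_LETTERS), size=length)))
    cluster_effect = rng.normal(0.0, 0.5, size=cfg.n_clusters)
    cluster_of = rng.integers(cfg.n_clusters, size=cfg.n)
    sequences = [_mutate(motifs[c], cfg.mutation_rate, rng)
                 for c in cluster_of]
    hydro = np.array([sum(ch in HYDROPHOBIC for ch in s) / len(s)
                      for s in sequences])
    scores = (hydro + cluster_effect[cluster_of]
              + rng.normal(0.0, cfg.noise_sd, size=cfg.n))
    if cfg.task == CLASSIFICATION:
        labels = (scores > np.median(scores)).astype(float)
    else:
        labels = scores
    is_modified = rng.random(cfg.n) < cfg.modified_fraction
    records = []
    width = len(str(cfg.n))
    for i, seq in enumerate(sequences):
        rec_id = f"pep{i:0{width}d}"
        if is_modified[i]:
            frags = [CANONICAL_FRAGMENTS[ch] for ch in seq]
            n_subs = int(rng.integers(1, 3))
            positions = rng.choice(len(frags), size=min(n_subs, len(frags)),
                                   replace=False)
            for pos in positions:
                mono = cfg.monomer_library[
                    rng.integers(len(cfg.monomer_library))]
                frags[pos] = MODIFIED_FRAGMENTS[mono][0]
            records.append(PeptideRecord(
                id=rec_id, label=float(labels[i]), sequence=None,
                smiles=assemble_smiles(frags), peptide_class=MODIFIED))
        else:
            records.append(PeptideRecord(
                id=rec_id, label=float(labels[i]), sequence=seq,
                smiles=seq_to_smiles(seq), peptide_class=STANDARD))
    return PeptideDataset(name or f"synthetic-seed{cfg.seed}", cfg.task,
                          records)


def modify_record(rec: PeptideRecord, rng: np.random.Generator,
                  monomer_library: Optional[List[str]] = None,
                  max_substitutions: int = 2) -> PeptideRecord:
    """Chemically modify a standard record (1-2 monomer substitutions).

    The label is kept: the modification is label-neutral, emulating
    modified analogs of peptides with a known activity.
    """
    if rec.sequence is None:
        raise ValueError(f"record {rec.id!r} has no sequence to modify")
    library = monomer_library or sorted(MODIFIED_FRAGMENTS)
    frags = [CANONICAL_FRAGMENTS[ch] for ch in rec.sequence]
    n_subs = int(rng.integers(1, max_substitutions + 1))
    for pos in rng.choice(len(frags), size=min(n_subs, len(frags)),
                          replace=False):
        mono = library[rng.integers(len(library))]
        frags[pos] = MODIFIED_FRAGMENTS[mono][0]
    return PeptideRecord(id=rec.id, label=rec.label, sequence=None,
                         smiles=assemble_smiles(frags),
                         peptide_class=MODIFIED)


def generate_paired(cfg: GeneratorConfig
                    ) -> Tuple[PeptideDataset, PeptideDataset]:
    """A standard dataset and a modified counterpart sharing one task.

    One population of 2n records is generated under a single planted rule
    (shared motifs, shared label construction); half stays standard, the
    other half is chemically modified record by record, keeping labels.
    This mirrors paired benchmarks where standard and modified peptides
    measure the same bioactivity.
    """
    big_cfg = GeneratorConfig(**{**vars(cfg), "n": 2 * cfg.n,
                                 "modified_fraction": 0.0})
    big = generate_dataset(big_cfg)
    rng = np.random.default_rng(cfg.seed + 10_000)
    std = PeptideDataset("synthetic-standard", big.task,
                         big.records[:cfg.n])
    modified = [modify_record(
        PeptideRecord(f"m{r.id}", r.label, r.sequence, r.smiles,
                      r.peptide_class),
        rng, cfg.monomer_library) for r in big.records[cfg.n:]]
    return std, PeptideDataset("synthetic-modified", big.task, modified)
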