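"""Peptide records and datasets: validated containers plus table/FASTA I/O.

A record carries a sequence (standard peptides), a SMILES string (modified
peptides, which have no faithful one-letter rendering), or both, together
with a task label.  Datasets are ordered collections with unique ids and a
single task type (binary classification or regression).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .monomers import CANONICAL_LETTERS

logger = logging.getLogger(__name__)

STANDARD = "standard"
MODIFIED = "modified"
CLASSIFICATION = "classification"
REGRESSION = "regression"

_SEQ_ALPHABET = set(CANONICAL_LETTERS) | {"X"}


@dataclass(frozen=True)
class PeptideRecord:
    """One labeled peptide.

    At least one of ``sequence`` / ``smiles`` must be present.  Standard
    peptides must have a sequence over the 20 canonical letters; modified
    peptides are primarily defined by their SMILES.
    """

    id: str
    label: float
    sequence: Optional[str] = None
    smiles: Optional[str] = None
    peptide_class: str = STANDARD

    def validate(self, task: str) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.sequence is None and self.smiles is None:
            raise ValueError(f"record {self.id!r}: needs sequence or smiles")
        if self.peptide_class not in (STANDARD, MODIFIED):
            raise ValueError(
                f"record {self.id!r}: unknown class {self.peptide_class!r}")
        if self.peptide_class == STANDARD:
            if not self.sequence:
                raise ValueError(
                    f"record {self.id!r}: standard peptide without sequence")
            bad = set(self.sequence) - set(CANONICAL_LETTERS)
            if bad:
                raise ValueError(
                    f"record {self.id!r}: non-canonical letters {sorted(bad)}")
        elif self.sequence is not None:
            bad = set(self.sequence) - _SEQ_ALPHABET
            if bad:
                raise ValueError(
                    f"record {self.id!r}: invalid letters {sorted(bad)}")
        import math
        if not math.isfinite(self.label):
            raise ValueError(f"record {self.id!r}: non-finite label")
        if task == CLASSIFICATION and self.label not in (0.0, 1.0):
            raise ValueError(
                f"record {self.id!r}: classification label must be 0/1, "
                f"got {self.label}")


@dataclass
class PeptideDataset:
    """An ordered, id-unique collection of peptides sharing one task type."""

    name: str
    task: str
    records: List[PeptideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ValueError(f"unknown task {self.task!r}")
        if not self.records:
            raise ValueError(f"dataset {self.name!r} is empty")
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate id {rec.id!r}")
            seen.add(rec.id)
            rec.validate(self.task)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self.records]

    def labels(self) -> List[float]:
        return [r.label for r in self.records]

    def subset(self, ids: Sequence[str], name: Optional[str] = None) -> "PeptideDataset":
        wanted = set(ids)
        recs = [r for r in self.records if r.id in wanted]
        missing = wanted - {r.id for r in recs}
        if missing:
            raise KeyError(f"ids not in dataset: {sorted(missing)[:5]}")
        return PeptideDataset(name or self.name, self.task, recs)

    def get(self, rec_id: str) -> PeptideRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "label": [r.label for r in self.records],
                "class": [r.peptide_class for r in self.records],
            }
        )


def _records_from_frame(df: pd.DataFrame, task: str) -> List[PeptideRecord]:
    bad_rows = []
    records = []
    for i, row in df.iterrows():
        seq = row.get("sequence")
        smi = row.get("smiles")
        seq = None if (seq is None or pd.isna(seq) or seq == "") else str(seq)
        smi = None if (smi is None or pd.isna(smi) or smi == "") else str(smi)
        cls = row.get("class")
        if cls is None or pd.isna(cls) or cls == "":
            cls = STANDARD if seq is not None else MODIFIED
        rec = PeptideRecord(id=str(row["id"]), label=float(row["label"]),
                            sequence=seq, smiles=smi, peptide_class=str(cls))
        try:
            rec.validate(task)
        except ValueError as exc:
            bad_rows.append((i, str(exc)))
            continue
        records.append(rec)
    if bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10])
        if not records:
            raise ValueError(f"all rows invalid: {detail}")
        warnings.warn(f"{len(bad_rows)} invalid rows rejected: {detail}")
    return records


def infer_task(labels: Iterable[float]) -> str:
    vals = set(float(v) for v in labels)
    return CLASSIFICATION if vals <= {0.0, 1.0} else REGRESSION


def read_dataset(path, fmt: str = "table", task: Optional[str] = None,
                 name: Optional[str] = None, sep: str = ",",
                 labels: Optional[dict] = None) -> PeptideDataset:
    """Read a peptide dataset from a delimited table or FASTA file.

    Tables need columns ``id`` and ``label`` plus ``sequence`` and/or
    ``smiles`` (optional ``class``).  FASTA carries no labels, so a
    ``labels`` sidecar mapping id -> label is required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = name or path.stem
    if fmt == "table":
        df = pd.read_csv(path, sep=sep, dtype={"id": str})
        if df.empty:
            raise ValueError(f"{path}: empty table")
        required = {"id", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        if "sequence" not in df.columns and "smiles" not in df.columns:
            raise ValueError(f"{path}: needs a sequence or smiles column")
        dupes = df["id"][df["id"].duplicated()].tolist()
        if dupes:
            raise ValueError(f"{path}: duplicate ids {dupes[:5]}")
        task = task or infer_task(df["label"])
        return PeptideDataset(name, task, _records_from_frame(df, task))
    if fmt == "fasta":
        seqs = list(SeqIO.parse(str(path), "fasta"))
        if not seqs:
            raise ValueError(f"{path}: empty FASTA")
        if labels is None:
            raise ValueError(
                f"{path}: FASTA carries no labels; provide a label sidecar")
        records = []
        for s in seqs:
            if s.id not in labels:
                raise ValueError(f"{path}: no label for {s.id!r}")
            records.append(PeptideRecord(id=s.id, label=float(labels[s.id]),
                                         sequence=str(s.seq).upper()))
        task = task or infer_task(r.label for r in records)
        return PeptideDataset(name, task, records)
    raise ValueError(f"unknown format {fmt!r}")


def write_dataset(ds: PeptideDataset, path, sep: str = ",") -> None:
    """Write a dataset as a delimited table (columns id, sequence, smiles,
    label, class)."""
    ds.to_frame().to_csv(path, sep=sep, index=False)


def filter_by_length(ds: PeptideDataset, max_len: int = 50) -> PeptideDataset:
    """Drop records whose sequence exceeds ``max_len`` residues.

    The 50-residue default is the conventional upper bound for calling a
    polymer a peptide rather than a protein.  Records without a sequence are
    kept (length is undefined for them).  Order is preserved; the removal
    count is logged.  An all-removed result raises no error but warns.
    """
    kept = [r for r in ds.records
            if r.sequence is None or len(r.sequence) <= max_len]
    removed = len(ds.records) - len(kept)
    if removed:
        logger.info("filter_by_length: removed %d of %d records (> %d residues)",
                    removed, len(ds.records), max_len)
    if not kept:
        warnings.warn(f"filter_by_length: no records remain at max_len={max_len}")
        empty = PeptideDataset.__new__(PeptideDataset)  # skip non-empty check
        empty.name, empty.task, empty.records = ds.name, ds.task, []
        return empty
    return PeptideDataset(ds.name, ds.task, kept)
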