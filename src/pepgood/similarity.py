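"""Pairwise similarity matrices over peptide datasets.

A :class:`SimilarityMatrix` is the common currency between the similarity
functions (fingerprint, alignment or embedding based) and the partitioning
machinery: a symmetric matrix in [0, 1] with unit diagonal, tagged with the
specification of the function that produced it.

Registered similarity functions:

``ecfp`` / ``ecfp-count``
    Jaccard (Tanimoto) similarity of binary / counted extended-connectivity
    fingerprints; applies to any record with a SMILES (sequences are
    rendered to SMILES on the fly).
``mapc``
    MinHash-estimated Jaccard of chirality-aware atom-pair shingles.
``nw``
    Global-alignment identity (sequence records only).
``sw-prefilter``
    k-mer-prefiltered local-alignment identity (sequence records only).
``embedding``
    Euclidean similarity 1 / (1 + d) over a precomputed embedding matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import alignment as _align
from . import fingerprints as _fp
from .monomers import reconstruct_sequence, seq_to_smiles
from .peptides import PeptideDataset


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity over a dataset, values in [0, 1]."""

    values: np.ndarray
    ids: Sequence[str]
    function_spec: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.all(np.isfinite(v)):
            raise ValueError("similarities must be finite")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("similarities must lie in [0, 1]")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("diagonal must be 1")
        self.values = np.clip(v, 0.0, 1.0)

    def __len__(self):
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids),
                            columns=list(self.ids))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, function_spec: str = "file") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns],
                   function_spec)


def _record_smiles(rec) -> str:
    if rec.smiles is not None:
        return rec.smiles
    return seq_to_smiles(rec.sequence)


def _record_sequence(rec, reconstruct_mode: str = "x") -> str:
    if rec.sequence is not None:
        return rec.sequence
    return reconstruct_sequence(rec.smiles, mode=reconstruct_mode)


def _pairwise_from_fps(fps, sim) -> np.ndarray:
    n = len(fps)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = sim(fps[i], fps[j])
    return m


def pairwise_similarity(ds: PeptideDataset, function: str = "ecfp",
                        diameter: int = 16, nbits: int = 2048,
                        n_perm: int = 2048, k: int = 3,
                        params: Optional[_align.AlignmentParams] = None,
                        embeddings: Optional[Dict[str, np.ndarray]] = None,
                        reconstruct_mode: str = "x") -> SimilarityMatrix:
    """Compute the full pairwise similarity matrix for one function spec."""
    params = params or _align.DEFAULT_PARAMS
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 records")
    if function in ("ecfp", "ecfp-count"):
        counted = function == "ecfp-count"
        fps = [_fp.ecfp(_record_smiles(r), diameter=diameter, nbits=nbits,
                        counted=counted) for r in ds]
        values = _pairwise_from_fps(fps, _fp.jaccard)
        spec = f"{function}-{diameter}"
    elif function == "mapc":
        sigs = [_fp.mapc(_record_smiles(r), diameter=diameter, n_perm=n_perm)
                for r in ds]
        arr = np.array([s.values for s in sigs], dtype=np.uint64)
        values = np.eye(n)
        for i in range(n):
            eq = (arr[i + 1:] == arr[i]).mean(axis=1)
            values[i, i + 1:] = eq
            values[i + 1:, i] = eq
        spec = f"mapc-{diameter}"
    elif function == "nw":
        seqs = [_record_sequence(r, reconstruct_mode) for r in ds]
        values = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                s = _align.nw_similarity(seqs[i], seqs[j], params)
                values[i, j] = values[j, i] = s
        spec = f"nw-{params.matrix}"
    elif function == "sw-prefilter":
        seqs = [_record_sequence(r, reconstruct_mode) for r in ds]
        values = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                s = _align.sw_prefilter_similarity(seqs[i], seqs[j], k, params)
                values[i, j] = values[j, i] = s
        spec = f"sw-prefilter-k{k} (mmseqs2-emulation)"
    elif function == "embedding":
        if embeddings is None:
            raise ValueError("embedding similarity needs an embeddings map")
        values = embedding_similarity(ds.ids, embeddings)
        spec = "embedding-euclidean"
    else:
        raise ValueError(f"unknown similarity function {function!r}")
    return SimilarityMatrix(values, list(ds.ids), spec)


def embedding_similarity(ids: Sequence[str],
                         embeddings: Dict[str, np.ndarray]) -> np.ndarray:
    """Euclidean similarity 1 / (1 + d) from precomputed embedding vectors."""
    missing = [i for i in ids if i not in embeddings]
    if missing:
        raise KeyError(f"no embedding for ids {missing[:5]}")
    x = np.array([np.asarray(embeddings[i], dtype=float) for i in ids])
    sq = np.sum(x ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0)
    values = 1.0 / (1.0 + np.sqrt(d2))
    np.fill_diagonal(values, 1.0)
    return values


def read_embeddings(path) -> Dict[str, np.ndarray]:
    """Load per-id embedding vectors from a TSV (first column id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {str(i): row.to_numpy(dtype=float) for i, row in df.iterrows()}
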