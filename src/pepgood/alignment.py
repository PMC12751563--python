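"""Sequence-alignment similarity for standard peptides.

Global similarity follows the EMBOSS needle convention: optimal
Needleman-Wunsch alignment under BLOSUM62 with affine gaps (open 10,
extend 0.5), identity normalized by the full alignment length including gap
columns.  Local similarity emulates a k-mer-prefiltered Smith-Waterman
(MMseqs2-style): pairs sharing no k-mer are scored 0 without aligning.
The emulation does not reproduce MMseqs2 internals (profile k-mers,
ungapped prescore) and is labelled as an emulation in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .monomers import CANONICAL_LETTERS

_VALID = set(CANONICAL_LETTERS) | {"X"}


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment scoring parameters (EMBOSS needle defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    normalization: str = "identity_over_alignment_length"

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


DEFAULT_PARAMS = AlignmentParams()


def _check(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"unknown letters {sorted(bad)}")


@lru_cache(maxsize=16)
def _aligner(matrix: str, gap_open: float, gap_extend: float, mode: str):
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load(matrix)
    # affine gaps: opening a gap costs open+extend in EMBOSS terms
    al.open_gap_score = -gap_open
    al.extend_gap_score = -gap_extend
    al.mode = mode
    return al


def _identity_fraction(alignment) -> float:
    counts = alignment.counts()
    length = alignment.length
    if length == 0:
        return 0.0
    return counts.identities / length


def nw_similarity(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Global-alignment similarity in [0, 1].

    Identical positions of the optimal global alignment divided by the
    alignment length (gap columns included).
    """
    _check(a)
    _check(b)
    aligner = _aligner(params.matrix, params.gap_open, params.gap_extend,
                       "global")
    alignment = next(iter(aligner.align(a, b)))
    return _identity_fraction(alignment)


def _kmers(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def sw_prefilter_similarity(a: str, b: str, k: int = 3,
                            params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Local-alignment similarity with a shared-k-mer prefilter.

    If the sequences share no length-``k`` substring the pair is scored 0
    without aligning; otherwise the optimal Smith-Waterman local alignment
    is computed and identity is normalized by the local alignment length.
    ``k=0`` disables the prefilter.
    """
    _check(a)
    _check(b)
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > 0 and not (_kmers(a, k) & _kmers(b, k)):
        return 0.0
    aligner = _aligner(params.matrix, params.gap_open, params.gap_extend,
                       "local")
    alignments = aligner.align(a, b)
    try:
        alignment = next(iter(alignments))
    except (StopIteration, IndexError):
        return 0.0
    return _identity_fraction(alignment)
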