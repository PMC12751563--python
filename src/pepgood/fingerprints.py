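"""Chemical fingerprints and their similarities.

Two families are provided:

* extended-connectivity fingerprints (ECFP) hashed to a fixed number of
  bits, binary or counted, compared with (generalized) Jaccard similarity;
* MinHashed atom-pair fingerprints with chirality-aware environments
  (MAPc-style), compared by signature agreement, which estimates the
  Jaccard similarity of the underlying shingle sets.

Fingerprint *diameter* follows the ECFP naming convention: ECFP-16 hashes
circular environments up to radius 8.

The MinHash permutation family is a fixed, seeded universal-hash scheme
(h(x) = (a*x + b) mod p with p prime > 2^32), so signatures are
reproducible across runs and machines.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, FrozenSet, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

_HASH_PRIME = 4294967311  # smallest prime > 2^32; a*x+b stays within uint64
_SCHEME_SEED = 0x5EED  # fixed so signatures are stable across processes


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


@dataclass(frozen=True)
class BitFingerprint:
    """Binary hashed fingerprint: the set of on bits in ``[0, nbits)``."""

    bits: FrozenSet[int]
    nbits: int = 2048

    def __post_init__(self):
        if any(b < 0 or b >= self.nbits for b in self.bits):
            raise ValueError("bit index out of range")


@dataclass(frozen=True)
class CountFingerprint:
    """Counted hashed fingerprint: bit index -> multiplicity (>= 1)."""

    counts: tuple  # sorted tuple of (bit, count) pairs; hashable
    nbits: int = 2048

    def __post_init__(self):
        for b, c in self.counts:
            if b < 0 or b >= self.nbits:
                raise ValueError("bit index out of range")
            if c < 1:
                raise ValueError("counts must be >= 1")

    def as_dict(self) -> Dict[int, int]:
        return dict(self.counts)

    @property
    def bits(self) -> FrozenSet[int]:
        return frozenset(b for b, _ in self.counts)


@dataclass(frozen=True)
class MinHashSignature:
    """Vector of per-permutation hash minima over a molecule's shingle set."""

    values: tuple
    n_perm: int
    diameter: int

    def __post_init__(self):
        if self.n_perm < 1 or len(self.values) != self.n_perm:
            raise ValueError("signature length must equal n_perm")


Fingerprint = Union[BitFingerprint, CountFingerprint]


def ecfp(smiles: str, diameter: int = 16, nbits: int = 2048,
         counted: bool = False) -> Fingerprint:
    """Extended-connectivity fingerprint of the given even diameter.

    ``diameter=16`` with 2048 bits is the ECFP-16 configuration used
    throughout this package as the default chemical representation.
    """
    if diameter < 0 or diameter % 2:
        raise ValueError(f"diameter must be even and >= 0, got {diameter}")
    mol = _mol(smiles)
    gen = _morgan_generator(diameter // 2, nbits)
    if counted:
        cf = gen.GetCountFingerprint(mol)
        items = tuple(sorted(cf.GetNonzeroElements().items()))
        return CountFingerprint(items, nbits=nbits)
    bv = gen.GetFingerprint(mol)
    return BitFingerprint(frozenset(bv.GetOnBits()), nbits=nbits)


@lru_cache(maxsize=32)
def _morgan_generator(radius: int, nbits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)


def jaccard(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard/Tanimoto similarity of two fingerprints of the same type.

    Binary: |A n B| / |A u B|.  Counted: sum of per-bit minima over sum of
    per-bit maxima (generalized Jaccard).  Two empty fingerprints are
    identical by convention, similarity 1.
    """
    if type(a) is not type(b):
        raise TypeError("fingerprint types differ")
    if a.nbits != b.nbits:
        raise ValueError("fingerprint sizes differ")
    if isinstance(a, BitFingerprint):
        union = len(a.bits | b.bits)
        if union == 0:
            return 1.0
        return len(a.bits & b.bits) / union
    ca, cb = a.as_dict(), b.as_dict()
    keys = set(ca) | set(cb)
    if not keys:
        return 1.0
    num = sum(min(ca.get(k, 0), cb.get(k, 0)) for k in keys)
    den = sum(max(ca.get(k, 0), cb.get(k, 0)) for k in keys)
    return num / den


# ---------------------------------------------------------------------------
# MinHashed atom pairs


def _shingle_hash(shingle: str) -> int:
    """Stable 32-bit hash of a shingle string (process-independent)."""
    return int.from_bytes(hashlib.sha1(shingle.encode()).digest()[:4], "big")


def mapc_shingles(smiles: str, diameter: int) -> FrozenSet[str]:
    """Atom-pair shingle set underlying the MinHash signature.

    For every unordered heavy-atom pair (i, j) and every radius
    r <= diameter/2, the shingle is ``"A|d|B"`` where A and B are the
    canonical (chirality-aware) SMILES of the circular environments of the
    two atoms at radius r — lexicographically ordered so the pair is
    orientation-free — and d is their topological distance.
    """
    if diameter < 2 or diameter % 2:
        raise ValueError(f"diameter must be even and >= 2, got {diameter}")
    mol = _mol(smiles)
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError("empty molecule")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    radius = diameter // 2
    dmat = Chem.GetDistanceMatrix(mol)
    # canonical environment string per (atom, radius)
    env: Dict[tuple, str] = {}
    for idx in range(n):
        for r in range(radius + 1):
            if r == 0:
                atom = mol.GetAtomWithIdx(idx)
                s = atom.GetSmarts()
            else:
                bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, r, idx)
                if not bond_ids:
                    env[(idx, r)] = env[(idx, r - 1)]
                    continue
                atoms = set()
                for bid in bond_ids:
                    bond = mol.GetBondWithIdx(bid)
                    atoms.add(bond.GetBeginAtomIdx())
                    atoms.add(bond.GetEndAtomIdx())
                s = Chem.MolFragmentToSmiles(
                    mol, atomsToUse=sorted(atoms), bondsToUse=list(bond_ids),
                    rootedAtAtom=idx, canonical=True, isomericSmiles=True)
            env[(idx, r)] = s
    shingles = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dmat[i, j])
            for r in range(radius + 1):
                a, b = sorted((env[(i, r)], env[(j, r)]))
                shingles.add(f"{a}|{d}|{b}")
    return frozenset(shingles)


@lru_cache(maxsize=8)
def _perm_coeffs(n_perm: int):
    rng = np.random.default_rng(_SCHEME_SEED)
    a = rng.integers(1, _HASH_PRIME, size=n_perm, dtype=np.uint64)
    b = rng.integers(0, _HASH_PRIME, size=n_perm, dtype=np.uint64)
    return a, b


def minhash(shingles: FrozenSet[str], n_perm: int, diameter: int) -> MinHashSignature:
    """MinHash signature of a shingle set under the package's fixed
    permutation family."""
    if not shingles:
        raise ValueError("empty shingle set")
    a, b = _perm_coeffs(n_perm)
    x = np.array(sorted(_shingle_hash(s) for s in shingles), dtype=np.uint64)
    p = np.uint64(_HASH_PRIME)
    mins = np.empty(n_perm, dtype=np.uint64)
    # chunk over permutations to bound the (n_perm x n_shingles) workspace
    chunk = max(1, (1 << 22) // max(1, x.size))
    for start in range(0, n_perm, chunk):
        sl = slice(start, min(start + chunk, n_perm))
        h = (a[sl, None] * x[None, :] + b[sl, None]) % p
        mins[sl] = h.min(axis=1)
    return MinHashSignature(tuple(int(v) for v in mins), n_perm=n_perm,
                            diameter=diameter)


def mapc(smiles: str, diameter: int = 8, n_perm: int = 2048) -> MinHashSignature:
    """MinHashed chirality-aware atom-pair fingerprint.

    Practical diameters run from 4 to 20 (even).  The similarity between two
    signatures is read off with :func:`minhash_estimate`.
    """
    if not (4 <= diameter <= 20) or diameter % 2:
        raise ValueError(f"diameter must be even in [4, 20], got {diameter}")
    return minhash(mapc_shingles(smiles, diameter), n_perm, diameter)


def minhash_estimate(a: MinHashSignature, b: MinHashSignature) -> float:
    """Estimated Jaccard similarity: fraction of agreeing signature slots."""
    if a.n_perm != b.n_perm or a.diameter != b.diameter:
        raise ValueError("signature parameters differ")
    av = np.asarray(a.values)
    bv = np.asarray(b.values)
    return float(np.mean(av == bv))


def export_sparse(fp: Fingerprint) -> str:
    """Text form of a fingerprint for caching (bit[:count] per line)."""
    if isinstance(fp, BitFingerprint):
        return "\n".join(str(b) for b in sorted(fp.bits))
    return "\n".join(f"{b}:{c}" for b, c in fp.counts)
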