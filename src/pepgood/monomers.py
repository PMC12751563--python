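"""Monomer chemistry: sequence -> SMILES assembly and SMILES -> sequence recovery.

Peptides are assembled by condensing per-residue SMILES fragments; each
fragment starts at the backbone nitrogen and ends at the carbonyl carbon, so
string concatenation forms the amide bonds and a trailing ``O`` caps the
C-terminus as a free acid.  The reverse direction locates the backbone as the
longest chain of amide-linked alpha-carbon units, breaks the backbone amides,
and identifies each released monomer by canonical-SMILES lookup.

Non-canonical monomers are translated to the one-letter alphabet either as the
unknown residue ``X`` or as their natural-analog letter from a small editable
monomer table (see ``data/monomer_analogs.csv``).
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources
from typing import Dict, Iterable, List, Optional, Tuple

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

CANONICAL_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

# Backbone fragments for the 20 canonical L-amino acids.  Each fragment runs
# N -> C-alpha -> carbonyl so that concatenation condenses the amide bonds;
# "<frag>O" is the free amino acid.
CANONICAL_FRAGMENTS: Dict[str, str] = {
    "A": "N[C@@H](C)C(=O)",
    "R": "N[C@@H](CCCNC(=N)N)C(=O)",
    "N": "N[C@@H](CC(N)=O)C(=O)",
    "D": "N[C@@H](CC(=O)O)C(=O)",
    "C": "N[C@@H](CS)C(=O)",
    "E": "N[C@@H](CCC(=O)O)C(=O)",
    "Q": "N[C@@H](CCC(N)=O)C(=O)",
    "G": "NCC(=O)",
    "H": "N[C@@H](Cc1c[nH]cn1)C(=O)",
    "I": "N[C@@H]([C@@H](C)CC)C(=O)",
    "L": "N[C@@H](CC(C)C)C(=O)",
    "K": "N[C@@H](CCCCN)C(=O)",
    "M": "N[C@@H](CCSC)C(=O)",
    "F": "N[C@@H](Cc1ccccc1)C(=O)",
    "P": "N1[C@@H](CCC1)C(=O)",
    "S": "N[C@@H](CO)C(=O)",
    "T": "N[C@@H]([C@@H](C)O)C(=O)",
    "W": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)",
    "Y": "N[C@@H](Cc1ccc(O)cc1)C(=O)",
    "V": "N[C@@H](C(C)C)C(=O)",
}

# Common modified monomers: N-methylations, D-configurations, side-chain
# modifications and backbone analogs.  ``analog`` is the natural-analog letter.
MODIFIED_FRAGMENTS: Dict[str, Tuple[str, str]] = {
    # name: (fragment, analog letter)
    "N-methyl-alanine": ("N(C)[C@@H](C)C(=O)", "A"),
    "sarcosine": ("N(C)CC(=O)", "G"),
    "N-methyl-leucine": ("N(C)[C@@H](CC(C)C)C(=O)", "L"),
    "N-methyl-phenylalanine": ("N(C)[C@@H](Cc1ccccc1)C(=O)", "F"),
    "D-alanine": ("N[C@H](C)C(=O)", "A"),
    "D-valine": ("N[C@H](C(C)C)C(=O)", "V"),
    "D-lysine": ("N[C@H](CCCCN)C(=O)", "K"),
    "D-phenylalanine": ("N[C@H](Cc1ccccc1)C(=O)", "F"),
    "N6-acetyl-lysine": ("N[C@@H](CCCCNC(C)=O)C(=O)", "K"),
    "4-hydroxy-proline": ("N1[C@@H](C[C@H](O)C1)C(=O)", "P"),
    "norleucine": ("N[C@@H](CCCC)C(=O)", "L"),
    "ornithine": ("N[C@@H](CCCN)C(=O)", "K"),
    "2-aminobutyric-acid": ("N[C@@H](CC)C(=O)", "A"),
    "2-aminoisobutyric-acid": ("NC(C)(C)C(=O)", "A"),
}

_ANALOG_MAP_RESOURCE = "monomer_analogs.csv"

# N -> C-alpha -> carbonyl-C unit; matched atoms index the backbone.
_UNIT_SMARTS = Chem.MolFromSmarts("[NX3][CX4][CX3](=[OX1])")


def canonical_smiles(smiles: str) -> str:
    """Canonical isomeric SMILES, or raise ``ValueError`` if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def monomer_smiles(fragment: str) -> str:
    """Free-monomer canonical SMILES for a backbone fragment."""
    return canonical_smiles(fragment + "O")


def seq_to_smiles(sequence: str, fragments: Optional[Dict[str, str]] = None) -> str:
    """Render a canonical amino-acid sequence as a linear-peptide SMILES.

    The peptide carries a free N-terminal amine and free C-terminal acid.
    The output is canonical, so equal sequences give identical strings.

    Parameters
    ----------
    sequence:
        Non-empty string over the 20 canonical one-letter codes.
    fragments:
        Optional per-letter fragment override (used by the synthetic
        generator to splice modified monomers into a chain).
    """
    if not sequence:
        raise ValueError("empty sequence")
    frags = fragments or CANONICAL_FRAGMENTS
    parts = []
    for i, letter in enumerate(sequence):
        if letter not in frags:
            raise ValueError(f"unknown residue {letter!r} at position {i}")
        parts.append(frags[letter])
    return canonical_smiles("".join(parts) + "O")


def assemble_smiles(fragment_list: Iterable[str]) -> str:
    """Condense an explicit list of backbone fragments into a peptide SMILES."""
    parts = list(fragment_list)
    if not parts:
        raise ValueError("no fragments")
    return canonical_smiles("".join(parts) + "O")


class AnalogMap:
    """Monomer -> one-letter lookup keyed on canonical free-monomer SMILES."""

    def __init__(self, entries: Iterable[Tuple[str, str, str]]):
        # entries: (name, smiles, letter)
        self.by_smiles: Dict[str, str] = {}
        self.names: Dict[str, str] = {}
        for name, smi, letter in entries:
            can = canonical_smiles(smi)
            self.by_smiles[can] = letter
            self.names[can] = name

    def lookup(self, can_smiles: str) -> Optional[str]:
        return self.by_smiles.get(can_smiles)

    @classmethod
    def from_csv(cls, path) -> "AnalogMap":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls((r["name"], r["smiles"], r["letter"]) for r in rows)


@lru_cache(maxsize=1)
def default_analog_map() -> AnalogMap:
    """The analog map shipped with the package (canonical + common modified)."""
    ref = resources.files("pepgood") / "data" / _ANALOG_MAP_RESOURCE
    with resources.as_file(ref) as path:
        return AnalogMap.from_csv(path)


@lru_cache(maxsize=1)
def _canonical_monomer_maps() -> Tuple[Dict[str, str], Dict[str, str]]:
    """(isomeric-canonical SMILES -> letter, achiral-canonical -> letter)."""
    iso: Dict[str, str] = {}
    flat: Dict[str, str] = {}
    for letter, frag in CANONICAL_FRAGMENTS.items():
        smi = monomer_smiles(frag)
        iso[smi] = letter
        mol = Chem.MolFromSmiles(smi)
        flat[Chem.MolToSmiles(mol, isomericSmiles=False)] = letter
    return iso, flat


def _backbone_units(mol: Chem.Mol) -> List[Tuple[int, int, int]]:
    """All (N, CA, C) backbone units in the molecule."""
    seen = set()
    units = []
    for n_idx, ca_idx, c_idx, _o in mol.GetSubstructMatches(_UNIT_SMARTS):
        key = (n_idx, ca_idx, c_idx)
        if key not in seen:
            seen.add(key)
            units.append(key)
    return units


def _chain_order(mol: Chem.Mol, units: List[Tuple[int, int, int]]) -> List[int]:
    """Order unit indices N-terminus -> C-terminus along the longest backbone.

    Units are linked where one unit's carbonyl carbon bonds the next unit's
    nitrogen.  For linear peptides the link graph is a path; the longest path
    is taken, with ties broken by the smallest carbonyl atom index.  Cyclic
    backbones are opened at the amide whose carbonyl has the smallest index.
    """
    n_of = {i: u[0] for i, u in enumerate(units)}
    succ: Dict[int, int] = {}
    pred: Dict[int, int] = {}
    for i, (_, _, c_idx) in enumerate(units):
        atom = mol.GetAtomWithIdx(c_idx)
        for nb in atom.GetNeighbors():
            for j, n_idx in n_of.items():
                if j != i and nb.GetIdx() == n_idx:
                    succ[i] = j
                    pred[j] = i
    starts = [i for i in range(len(units)) if i not in pred]
    if not starts:  # cyclic backbone: open at the smallest carbonyl index
        start_unit = min(succ, key=lambda i: units[i][2])
        starts = [succ[start_unit]]
        del succ[start_unit]
    chains = []
    for s in starts:
        chain = [s]
        while chain[-1] in succ:
            nxt = succ[chain[-1]]
            if nxt in chain:
                break
            chain.append(nxt)
        chains.append(chain)
    chains.sort(key=lambda ch: (-len(ch), units[ch[0]][2]))
    return chains[0]


def _monomer_fragments(mol: Chem.Mol, chain: List[int],
                       units: List[Tuple[int, int, int]]) -> List[str]:
    """Break the chain's backbone amides; return free-monomer canonical SMILES."""
    bonds = []
    for a, b in zip(chain, chain[1:]):
        c_idx = units[a][2]
        n_idx = units[b][0]
        bond = mol.GetBondBetweenAtoms(c_idx, n_idx)
        bonds.append(bond.GetIdx())
    if bonds:
        frag_mol = Chem.FragmentOnBonds(mol, bonds, addDummies=True)
    else:
        frag_mol = Chem.Mol(mol)
    frag_ids = Chem.GetMolFrags(frag_mol)
    ca_to_frag = {}
    for fi, atom_ids in enumerate(frag_ids):
        for aid in atom_ids:
            ca_to_frag[aid] = fi
    frag_mols = Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=False)
    out = []
    for ui in chain:
        ca_idx = units[ui][1]
        sub = Chem.RWMol(frag_mols[ca_to_frag[ca_idx]])
        # Cap the cut points: dummy on N -> hydrogen (drop the dummy);
        # dummy on carbonyl C -> hydroxyl oxygen (free acid).
        to_remove = []
        for atom in sub.GetAtoms():
            if atom.GetAtomicNum() != 0:
                continue
            nb = atom.GetNeighbors()[0]
            if nb.GetAtomicNum() == 7:
                to_remove.append(atom.GetIdx())
            else:
                atom.SetAtomicNum(8)
                atom.SetIsotope(0)
        for idx in sorted(to_remove, reverse=True):
            sub.RemoveAtom(idx)
        m = sub.GetMol()
        Chem.SanitizeMol(m)
        out.append(Chem.MolToSmiles(m))
    return out


def smiles_to_monomers(smiles: str) -> List[str]:
    """Split a peptide SMILES into free-monomer canonical SMILES, N to C.

    Backbone amides are detected as bonds between consecutive
    N-C-alpha-carbonyl units; side-chain amides (Asn/Gln, acylated side
    chains) are left intact.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    units = _backbone_units(mol)
    if not units:
        raise ValueError("no backbone alpha-carbon unit found")
    chain = _chain_order(mol, units)
    return _monomer_fragments(mol, chain, units)


def _has_stereo(smiles: str) -> bool:
    return "@" in smiles


def monomers_to_letters(monomers: List[str], mode: str = "x",
                        analog_map: Optional[AnalogMap] = None) -> str:
    """Translate free-monomer SMILES to one-letter codes.

    Canonical monomers map to their own letter.  Non-canonical monomers map
    to ``'X'`` (``mode='x'``) or to their analog letter when present in the
    map (``mode='analog'``, falling back to ``'X'``).
    """
    if mode not in ("x", "analog"):
        raise ValueError(f"unknown mode {mode!r}")
    iso, flat = _canonical_monomer_maps()
    amap = analog_map if analog_map is not None else default_analog_map()
    letters = []
    for smi in monomers:
        letter = iso.get(smi)
        if letter is None and not _has_stereo(smi):
            # stereo-free input (e.g. achiral source SMILES) still counts
            # as the canonical residue
            letter = flat.get(smi)
        if letter is None:
            if mode == "analog":
                letter = amap.lookup(smi) or "X"
            else:
                letter = "X"
        letters.append(letter)
    return "".join(letters)


def reconstruct_sequence(smiles: str, mode: str = "x",
                         analog_map: Optional[AnalogMap] = None) -> str:
    """Recover a one-letter sequence from a peptide SMILES.

    The backbone amides are computationally broken and the sequence is
    rebuilt from the released monomers, writing non-canonical monomers as
    ``'X'`` or as their natural-analog letter.  A single monomer (no backbone
    amide) yields a length-1 string.
    """
    return monomers_to_letters(smiles_to_monomers(smiles), mode=mode,
                               analog_map=analog_map)
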