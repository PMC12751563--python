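"""Fingerprints: hashing invariance, Jaccard arithmetic, MinHash accuracy."""

import numpy as np
import pytest
from rdkit import Chem

from pepgood import seq_to_smiles
from pepgood.fingerprints import (BitFingerprint, CountFingerprint, ecfp,
                                  jaccard, mapc, mapc_shingles, minhash,
                                  minhash_estimate)

from conftest import random_sequence


def bits(*idx, nbits=2048):
    return BitFingerprint(frozenset(idx), nbits=nbits)


class TestEcfp:
    def test_spelling_invariance(self):
        a = ecfp("OC(=O)CN")  # glycine, scrambled atom order
        b = ecfp("NCC(=O)O")
        assert a == b

    def test_counted_and_binary_share_support(self):
        smi = seq_to_smiles("GAVGAV")
        cb = ecfp(smi, counted=True)
        bb = ecfp(smi, counted=False)
        assert cb.bits == bb.bits

    def test_diameter_zero_single_heavy_atom(self):
        fp = ecfp("C", diameter=0)
        assert len(fp.bits) == 1  # methane has one atomic environment

    def test_count_multiplicity(self):
        # glycylglycine repeats the glycine unit: some environment occurs twice
        cf = ecfp(seq_to_smiles("GG"), counted=True, diameter=2)
        assert max(c for _, c in cf.counts) >= 2

    def test_odd_diameter_rejected(self):
        with pytest.raises(ValueError):
            ecfp("C", diameter=3)

    def test_unparseable_smiles(self):
        with pytest.raises(ValueError):
            ecfp("][")

    def test_atom_reindexing_invariance(self, rng):
        for _ in range(10):
            smi = seq_to_smiles(random_sequence(rng, 2, 6))
            mol = Chem.MolFromSmiles(smi)
            order = rng.permutation(mol.GetNumAtoms())
            renum = Chem.RenumberAtoms(mol, [int(i) for i in order])
            assert ecfp(Chem.MolToSmiles(renum)) == ecfp(smi)


class TestJaccard:
    def test_identical_is_one(self):
        assert jaccard(bits(1, 5, 9), bits(1, 5, 9)) == 1.0

    def test_disjoint_is_zero(self):
        assert jaccard(bits(1, 2), bits(3, 4)) == 0.0

    def test_three_of_four_shared(self):
        assert jaccard(bits(1, 2, 3), bits(2, 3, 4)) == 0.5

    def test_both_empty_is_one_by_convention(self):
        assert jaccard(bits(), bits()) == 1.0

    def test_counted_uses_min_over_max(self):
        a = CountFingerprint(((0, 2), (1, 1)), nbits=8)
        b = CountFingerprint(((0, 1), (1, 3)), nbits=8)
        assert jaccard(a, b) == (1 + 1) / (2 + 3)

    def test_type_and_size_mismatch(self):
        with pytest.raises(TypeError):
            jaccard(bits(1), CountFingerprint(((1, 1),), nbits=2048))
        with pytest.raises(ValueError):
            jaccard(bits(1), bits(1, nbits=1024))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            a = frozenset(rng.integers(0, 64, size=rng.integers(0, 20)).tolist())
            b = frozenset(rng.integers(0, 64, size=rng.integers(0, 20)).tolist())
            expected = 1.0 if not (a | b) else len(a & b) / len(a | b)
            got = jaccard(BitFingerprint(a, 64), BitFingerprint(b, 64))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(100):
            a = bits(*rng.integers(0, 2048, size=10).tolist())
            b = bits(*rng.integers(0, 2048, size=10).tolist())
            assert jaccard(a, b) == jaccard(b, a)
            assert 0.0 <= jaccard(a, b) <= 1.0

    def test_counted_support_equals_binary_jaccard(self, rng):
        for _ in range(50):
            smi1 = seq_to_smiles(random_sequence(rng, 2, 6))
            smi2 = seq_to_smiles(random_sequence(rng, 2, 6))
            c1, c2 = ecfp(smi1, counted=True), ecfp(smi2, counted=True)
            b1, b2 = ecfp(smi1), ecfp(smi2)
            support = jaccard(BitFingerprint(c1.bits), BitFingerprint(c2.bits))
            assert support == pytest.approx(jaccard(b1, b2), abs=1e-12)


class TestMapc:
    def test_identical_molecules_identical_signatures(self):
        smi = seq_to_smiles("GAVLK")
        assert mapc(smi).values == mapc(smi).values

    def test_signature_length_is_n_perm(self):
        sig = mapc(seq_to_smiles("GA"), n_perm=128)
        assert len(sig.values) == 128

    def test_chirality_changes_shingles(self):
        l_ala = "N[C@@H](C)C(=O)O"
        d_ala = "N[C@H](C)C(=O)O"
        assert mapc_shingles(l_ala, 4) != mapc_shingles(d_ala, 4)

    def test_diameter_bounds(self):
        with pytest.raises(ValueError):
            mapc("CC", diameter=3)
        with pytest.raises(ValueError):
            mapc("CC", diameter=22)

    def test_estimate_close_to_exact_jaccard(self, rng):
        # MinHash estimate vs the exact shingle-set Jaccard oracle
        for _ in range(30):
            s1 = seq_to_smiles(random_sequence(rng, 3, 6))
            s2 = seq_to_smiles(random_sequence(rng, 3, 6))
            sh1, sh2 = mapc_shingles(s1, 4), mapc_shingles(s2, 4)
            exact = len(sh1 & sh2) / len(sh1 | sh2)
            est = minhash_estimate(minhash(sh1, 2048, 4), minhash(sh2, 2048, 4))
            assert abs(est - exact) <= 0.05

    def test_error_decreases_with_more_permutations(self, rng):
        pairs = []
        for _ in range(20):
            s1 = seq_to_smiles(random_sequence(rng, 3, 5))
            s2 = seq_to_smiles(random_sequence(rng, 3, 5))
            pairs.append((mapc_shingles(s1, 4), mapc_shingles(s2, 4)))
        maes = []
        for n_perm in (64, 2048):
            errs = []
            for sh1, sh2 in pairs:
                exact = len(sh1 & sh2) / len(sh1 | sh2)
                est = minhash_estimate(minhash(sh1, n_perm, 4),
                                       minhash(sh2, n_perm, 4))
                errs.append(abs(est - exact))
            maes.append(np.mean(errs))
        assert maes[1] < maes[0]

    def test_estimate_arithmetic(self):
        a = minhash(frozenset("abcdefgh"), 64, 4)
        assert minhash_estimate(a, a) == 1.0

    def test_parameter_mismatch(self):
        a = minhash(frozenset("abc"), 64, 4)
        b = minhash(frozenset("abc"), 128, 4)
        with pytest.raises(ValueError):
            minhash_estimate(a, b)
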