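import random

import numpy as np
import pytest

from entrofold.energy import (
    hairpin_energy,
    internal_loop_energy,
    multiloop_energy,
    structure_energy,
    turner_enthalpy_of_structure,
    turner_entropy_of_structure,
)
from entrofold.params import T37
from entrofold.sequence import NucleotideSequence, SecondaryStructure, StructureError

from conftest import random_rna_str


def random_structure(rng: random.Random, seq: str, theta: int = 3):
    """A random valid nested structure (biased toward some pairing)."""
    pairs = []

    def rec(i, j):
        if j - i <= theta:
            return
        if rng.random() < 0.5:
            rec(i, j - 1)
            return
        ks = [k for k in range(i, j - theta)
              if seq[k] + seq[j] in ("AU", "UA", "CG", "GC", "GU", "UG")]
        if not ks:
            rec(i, j - 1)
            return
        k = rng.choice(ks)
        pairs.append((k, j))
        if k > i:
            rec(i, k - 1)
        rec(k + 1, j - 1)

    rec(0, len(seq) - 1)
    return SecondaryStructure(n=len(seq), pairs=frozenset(pairs))


class TestLoopEnergies:
    def test_stack_gc_cg(self, turner):
        seq = NucleotideSequence("GCGC")
        assert internal_loop_energy(seq, 0, 3, 1, 2, turner) == pytest.approx(-3.4)

    def test_nussinov_loops_are_free(self, nussinov):
        seq = NucleotideSequence("GCAAAAGC")
        assert hairpin_energy(seq, 1, 6, nussinov) == 0.0
        assert internal_loop_energy(seq, 0, 7, 1, 6, nussinov) == 0.0
        assert multiloop_energy(3, 4, nussinov) == 0.0

    def test_hairpin_of_three_uses_length_table(self, turner):
        # generic triloop closed by C-G: pure length term, 5.4 kcal/mol
        seq = NucleotideSequence("CAAAG")
        assert hairpin_energy(seq, 0, 4, turner) == pytest.approx(5.4)

    def test_special_tetraloop_lookup(self, turner):
        # CUUCGG is in the Turner 2004 tetraloop table at 3.7 kcal/mol
        seq = NucleotideSequence("CUUCGG")
        assert hairpin_energy(seq, 0, 5, turner) == pytest.approx(3.7)

    def test_multiloop_affine_formula(self, turner):
        a, b, c = turner.a / 100, turner.b / 100, turner.c / 100
        assert multiloop_energy(2, 3, turner) == pytest.approx(a + 2 * b + 3 * c)
        with pytest.raises(ValueError):
            multiloop_energy(-1, 0, turner)

    def test_unpairable_closing_pair_rejected(self, turner):
        with pytest.raises(StructureError):
            hairpin_energy(NucleotideSequence("AAAAA"), 0, 4, turner)

    def test_oversized_internal_loop_rejected(self, turner):
        seq = NucleotideSequence("G" + "A" * 20 + "GAAAAC" + "A" * 20 + "C")
        with pytest.raises(StructureError, match="cap"):
            internal_loop_energy(seq, 0, len(seq) - 1, 21, 26, turner)


class TestStructureEnergy:
    def test_empty_structure_is_zero(self, turner):
        seq = NucleotideSequence("GGGAAAACCC")
        s = SecondaryStructure(n=10)
        assert structure_energy(seq, s, turner) == 0.0

    def test_nussinov_counts_pairs(self, nussinov, pyrng):
        for _ in range(20):
            seq = random_rna_str(pyrng, pyrng.randint(8, 40))
            s = random_structure(pyrng, seq)
            e = structure_energy(NucleotideSequence(seq), s, nussinov)
            assert e == pytest.approx(-len(s.pairs))

    def test_hairpin_helix_decomposition_by_hand(self, turner):
        # ((((....)))) on GGGCUUCGGCCC: three stacks + CUUCGG tetraloop
        seq = NucleotideSequence("GGGCUUCGGCCC")
        s = SecondaryStructure.from_dot_bracket("((((....))))")
        expect = (internal_loop_energy(seq, 0, 11, 1, 10, turner)
                  + internal_loop_energy(seq, 1, 10, 2, 9, turner)
                  + internal_loop_energy(seq, 2, 9, 3, 8, turner)
                  + hairpin_energy(seq, 3, 8, turner))
        assert structure_energy(seq, s, turner) == pytest.approx(expect)

    def test_cross_validation_against_independent_evaluator(self, turner, pyrng):
        """Dual-route check: loop-decomposition sum vs ViennaRNA RNAeval (d0)."""
        RNA = pytest.importorskip("RNA")
        RNA.params_load_RNA_Turner2004()
        md = RNA.md()
        md.dangles = 0
        md.special_hp = 1
        md.temperature = 37.0
        for _ in range(150):
            n = pyrng.randint(8, 70)
            seq = random_rna_str(pyrng, n)
            s = random_structure(pyrng, seq)
            ours = structure_energy(NucleotideSequence(seq), s, turner)
            ref = RNA.fold_compound(seq, md).eval_structure(s.dot_bracket())
            assert ours == pytest.approx(ref, abs=5e-3), (seq, s.dot_bracket())


class TestTabulatedEntropyEnthalpy:
    def test_empty_structure(self, turner):
        seq = NucleotideSequence("GGGAAAACCC")
        s = SecondaryStructure(n=10)
        assert turner_entropy_of_structure(seq, s, turner) == 0.0
        assert turner_enthalpy_of_structure(seq, s, turner) == 0.0

    def test_entropy_negative_for_folded_structures(self, turner, pyrng):
        # the 0.01 kcal/mol grid can flatten S_t of sparse structures to ~0;
        # stabilizing (MFE) structures show a strict entropic loss
        from entrofold.ensemble import mfe_structure
        found = 0
        while found < 10:
            seq = NucleotideSequence(random_rna_str(pyrng, pyrng.randint(20, 40)))
            s, e = mfe_structure(seq, turner)
            if e > -1.0 or len(s.pairs) < 3:
                continue
            found += 1
            st = turner_entropy_of_structure(seq, s, turner)
            assert st < 0.0

    def test_linearity_e_equals_ht_minus_t_st(self, turner):
        seq = NucleotideSequence("GGGCUUCGGCCCAAAGGGAAACCC")
        s = SecondaryStructure.from_dot_bracket("((((....))))...((....)).")
        st = turner_entropy_of_structure(seq, s, turner)
        ht = turner_enthalpy_of_structure(seq, s, turner)
        # tables are integers on a 0.01 kcal/mol grid: S_t inherits up to
        # 0.02 of grid error which is amplified by |T - 310.15|, and each
        # loop term truncates independently, hence the tolerance
        for t in (T37 - 5, T37 - 2, T37, T37 + 1, T37 + 2, T37 + 5):
            e = structure_energy(seq, s, turner, T=t)
            assert e == pytest.approx(ht - t * st, abs=0.25)
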