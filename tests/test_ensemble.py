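import numpy as np
import pytest
from scipy import stats

from entrofold.ensemble import (
    EnumerationCapError,
    boltzmann_sample,
    brute_force_summary,
    entropy_estimate_band,
    entropy_estimate_sampling,
    enumerate_structures,
    mfe,
    mfe_structure,
    wuchty_suboptimals,
)
from entrofold.entropy_dp import entropy_dp
from entrofold.partition import inside
from entrofold.sequence import NucleotideSequence

from conftest import random_rna_str


class TestEnumeration:
    @pytest.mark.parametrize("seq,count", [("AAAAA", 1), ("ACGU", 1)])
    def test_trivial_counts(self, seq, count):
        assert len(enumerate_structures(NucleotideSequence(seq))) == count

    def test_count_matches_zero_energy_partition_function(self, zero_params,
                                                          pyrng):
        for _ in range(10):
            seq = NucleotideSequence(random_rna_str(pyrng, pyrng.randint(8, 25)))
            count = len(enumerate_structures(seq))
            z = inside(seq, zero_params).partition_function
            assert count == round(z)

    def test_no_duplicates_and_valid(self, pyrng):
        seq = NucleotideSequence(random_rna_str(pyrng, 20))
        structs = enumerate_structures(seq)
        assert len({s.pairs for s in structs}) == len(structs)

    def test_cap_refusal(self):
        with pytest.raises(EnumerationCapError):
            enumerate_structures(NucleotideSequence("GC" * 20))


class TestBruteForce:
    def test_no_pair_sequence(self, turner):
        bf = brute_force_summary(NucleotideSequence("AAAAAA"), turner)
        assert (bf.z, bf.entropy, bf.expected_energy) == (1.0, 0.0, 0.0)

    def test_internal_identity(self, turner, pyrng):
        seq = NucleotideSequence(random_rna_str(pyrng, 18))
        bf = brute_force_summary(seq, turner)
        rt = 1.98717e-3 * 310.15
        assert bf.entropy == pytest.approx(
            bf.expected_energy / rt + np.log(bf.z), abs=1e-10)

    def test_two_structure_closed_form(self, nussinov):
        # GCAAAAGC under the toy model: empty structure or one of three
        # single pairs; verify against the closed-form Boltzmann entropy
        seq = NucleotideSequence("GGAAAACC")
        bf = brute_force_summary(seq, nussinov)
        w = np.exp(-bf.energies / (1.98717e-3 * 310.15))
        p = w / w.sum()
        h_direct = float(-(p * np.log(p)).sum())
        assert bf.entropy == pytest.approx(h_direct, abs=1e-12)


class TestMFE:
    def test_no_pair_sequence_mfe_zero(self, turner):
        assert mfe(NucleotideSequence("AAAAAA"), turner) == 0.0

    @pytest.mark.parametrize("paramset", ["turner", "classic", "nussinov"])
    def test_mfe_matches_enumeration_minimum(self, paramset, request, pyrng):
        params = request.getfixturevalue(paramset)
        for _ in range(6):
            seq = NucleotideSequence(random_rna_str(pyrng, pyrng.randint(10, 22)))
            bf = brute_force_summary(seq, params)
            assert mfe(seq, params) == pytest.approx(bf.energies.min(),
                                                     abs=1e-9)

    def test_mfe_structure_achieves_mfe(self, turner, pyrng):
        seq = NucleotideSequence(random_rna_str(pyrng, 30))
        s, e = mfe_structure(seq, turner)
        assert e == pytest.approx(mfe(seq, turner), abs=1e-9)


class TestWuchty:
    def test_band_zero_returns_only_optima(self, turner):
        seq = NucleotideSequence("GGGAAAACCC")
        bf = brute_force_summary(seq, turner)
        opt = wuchty_suboptimals(seq, turner, band=0.0)
        emin = bf.energies.min()
        expect = {s.pairs for s, e in zip(bf.structures, bf.energies)
                  if e <= emin + 1e-9}
        assert {s.pairs for s, _ in opt} == expect

    def test_wide_band_equals_enumeration(self, turner, pyrng):
        for _ in range(4):
            seq = NucleotideSequence(random_rna_str(pyrng, pyrng.randint(10, 18)))
            bf = brute_force_summary(seq, turner)
            band = float(bf.energies.max() - bf.energies.min()) + 1.0
            sub = wuchty_suboptimals(seq, turner, band=band)
            assert {s.pairs for s, _ in sub} == {s.pairs for s in bf.structures}
            by_pairs = {s.pairs: e for s, e in sub}
            for s, e in zip(bf.structures, bf.energies):
                assert by_pairs[s.pairs] == pytest.approx(e, abs=1e-9)

    def test_band_filter_is_exact(self, turner):
        seq = NucleotideSequence("GGGAAAACCC")
        bf = brute_force_summary(seq, turner)
        band = 2.0
        expect = {s.pairs for s, e in zip(bf.structures, bf.energies)
                  if e <= bf.energies.min() + band + 1e-9}
        got = {s.pairs for s, _ in wuchty_suboptimals(seq, turner, band=band)}
        assert got == expect

    def test_negative_band_rejected(self, turner):
        with pytest.raises(ValueError):
            wuchty_suboptimals(NucleotideSequence("GGGAAAACCC"), turner,
                               band=-1.0)


class TestSampling:
    def test_no_pair_sequence_all_empty(self, turner):
        out = boltzmann_sample(NucleotideSequence("AAAAAA"), turner,
                               n_samples=20, seed=1)
        assert all(len(s.pairs) == 0 for s in out)

    def test_same_seed_reproducible(self, turner):
        seq = NucleotideSequence("GGGGAAAACCCCAAGG")
        a = boltzmann_sample(seq, turner, n_samples=25, seed=7)
        b = boltzmann_sample(seq, turner, n_samples=25, seed=7)
        assert [s.pairs for s in a] == [s.pairs for s in b]

    def test_frequencies_within_standard_errors(self, turner, pyrng):
        # per-structure empirical frequency within 4 SE of exact probability
        seq = NucleotideSequence("GCGCAAAAGCGC")
        bf = brute_force_summary(seq, turner)
        n = 4000
        sample = boltzmann_sample(seq, turner, n_samples=n, seed=3)
        counts = {s.pairs: 0 for s in bf.structures}
        for s in sample:
            counts[s.pairs] += 1
        for s, p in zip(bf.structures, bf.probabilities):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[s.pairs] / n - p) <= 4 * se + 1e-9


class TestEntropyEstimates:
    def test_single_structure_sampling_estimate_zero(self, turner):
        h = entropy_estimate_sampling(NucleotideSequence("AAAAAA"), turner,
                                      n_samples=10, seed=0)
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_band_estimate_is_exact(self, turner):
        seq = NucleotideSequence("GGGAAAACCC")
        h_dp = entropy_dp(seq, turner).entropy
        h_band = entropy_estimate_band(seq, turner, band=100.0)
        assert h_band == pytest.approx(h_dp, abs=1e-9)

    def test_band_estimate_monotone_toward_dp(self, turner):
        seq = NucleotideSequence("GGCGCAAAAGCGCAAGG")
        h_dp = entropy_dp(seq, turner).entropy
        hs = [entropy_estimate_band(seq, turner, band=b)
              for b in (0.5, 2.0, 5.0, 50.0)]
        errs = [abs(h - h_dp) for h in hs]
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errs, errs[1:]))
        assert hs[-1] == pytest.approx(h_dp, abs=1e-9)

    def test_sampling_estimate_converges(self, turner):
        seq = NucleotideSequence("GGGAAAACCCAAGGG")
        h_dp = entropy_dp(seq, turner).entropy
        h_hat = entropy_estimate_sampling(seq, turner, n_samples=20000, seed=5)
        # sampling error envelope: SE of mean energy / RT, generous factor
        assert abs(h_hat - h_dp) < 0.05
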