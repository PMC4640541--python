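import numpy as np
import pytest

from entrofold.ensemble import brute_force_summary, mfe_structure
from entrofold.measures import (
    ensemble_defect,
    ensemble_measures,
    expected_bp_distance,
    heat_capacity,
    morgan_higgs_diversity,
    native_contacts,
    positional_entropy,
    temperature_scan,
    vienna_diversity,
)
from entrofold.params import GAS_CONSTANT, K0
from entrofold.partition import basepair_probabilities
from entrofold.sequence import (
    NucleotideSequence,
    SecondaryStructure,
    basepair_distance,
)

from conftest import random_rna_str


def _pstar_direct(bf, n):
    """p* assembled directly from enumerated pair frequencies."""
    ps = bf.pair_freq.copy()
    np.fill_diagonal(ps, 1.0 - bf.pair_freq.sum(axis=1))
    return ps


class TestPositionalEntropy:
    def test_zero_for_unpairable_sequence(self, turner):
        pm = basepair_probabilities(NucleotideSequence("AAAAAA"), turner)
        h2, mean = positional_entropy(pm)
        assert np.allclose(h2, 0.0) and mean == 0.0

    def test_matches_direct_formula_on_enumerated_pstar(self, turner, pyrng):
        seq = NucleotideSequence(random_rna_str(pyrng, 16))
        bf = brute_force_summary(seq, turner)
        pm = basepair_probabilities(seq, turner)
        ps = _pstar_direct(bf, len(seq))
        direct = np.array([
            -sum(p * np.log(p) for p in row if p > 0) for row in ps
        ])
        h2, mean = positional_entropy(pm)
        assert np.allclose(h2, direct, atol=1e-9)
        assert 0.0 <= mean <= np.log(len(seq))


class TestReferenceMeasures:
    """All reference-structure measures vs direct Boltzmann averages."""

    @pytest.fixture
    def small_case(self, turner, pyrng):
        seq = NucleotideSequence("GGGAAAACCC")
        bf = brute_force_summary(seq, turner)
        pm = basepair_probabilities(seq, turner)
        s0 = mfe_structure(seq, turner)[0]
        return seq, bf, pm, s0

    def test_ensemble_defect_matches_enumeration(self, small_case):
        seq, bf, pm, s0 = small_case
        n = len(seq)
        partner0 = s0.partner()
        direct = 0.0
        for s, p in zip(bf.structures, bf.probabilities):
            partner = s.partner()
            direct += p * sum(partner[i] != partner0[i] for i in range(n))
        assert ensemble_defect(pm, s0) == pytest.approx(direct / n, abs=1e-9)

    def test_expected_bp_distance_matches_enumeration(self, small_case):
        seq, bf, pm, s0 = small_case
        direct = sum(p * basepair_distance(s, s0)
                     for s, p in zip(bf.structures, bf.probabilities))
        assert expected_bp_distance(pm, s0) == pytest.approx(
            direct / len(seq), abs=1e-9)

    def test_native_contacts_matches_enumeration(self, small_case):
        seq, bf, pm, s0 = small_case
        direct = sum(p * len(s.pairs & s0.pairs) / len(s0.pairs)
                     for s, p in zip(bf.structures, bf.probabilities))
        assert native_contacts(pm, s0) == pytest.approx(direct, abs=1e-9)

    def test_native_contacts_empty_reference_rejected(self, small_case):
        seq, bf, pm, s0 = small_case
        with pytest.raises(ValueError):
            native_contacts(pm, SecondaryStructure(n=len(seq)))

    def test_defect_zero_for_unique_structure_ensemble(self, turner):
        seq = NucleotideSequence("AAAAAA")
        pm = basepair_probabilities(seq, turner)
        s0 = SecondaryStructure(n=6)
        assert ensemble_defect(pm, s0) == pytest.approx(0.0, abs=1e-12)
        assert expected_bp_distance(pm, s0) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_rejected(self, small_case):
        seq, bf, pm, s0 = small_case
        with pytest.raises(ValueError):
            ensemble_defect(pm, SecondaryStructure(n=7))


class TestDiversities:
    def test_single_structure_ensemble_zero(self, turner):
        pm = basepair_probabilities(NucleotideSequence("AAAAAA"), turner)
        assert vienna_diversity(pm) == 0.0
        assert morgan_higgs_diversity(pm) == pytest.approx(0.0, abs=1e-12)

    def test_match_pairwise_averages_by_enumeration(self, turner, pyrng):
        seq = NucleotideSequence(random_rna_str(pyrng, 14))
        bf = brute_force_summary(seq, turner)
        pm = basepair_probabilities(seq, turner)
        n = len(seq)
        probs = bf.probabilities
        bpd = 0.0
        ham = 0.0
        partners = [s.partner() for s in bf.structures]
        for a, pa in enumerate(probs):
            for b, pb in enumerate(probs):
                bpd += pa * pb * basepair_distance(bf.structures[a],
                                                   bf.structures[b])
                ham += pa * pb * int((partners[a] != partners[b]).sum())
        assert vienna_diversity(pm) == pytest.approx(bpd, abs=1e-9)
        assert morgan_higgs_diversity(pm) == pytest.approx(ham, abs=1e-9)

    def test_measure_bundle(self, turner):
        seq = NucleotideSequence("GGGAAAACCC")
        s0 = mfe_structure(seq, turner)[0]
        m = ensemble_measures(seq, turner, s0=s0)
        assert m.native_contacts is not None
        assert m.ensemble_defect >= 0 and m.expected_bp_distance >= 0


class TestTemperature:
    def test_homopolymer_heat_capacity_zero(self, turner):
        assert heat_capacity(NucleotideSequence("AAAAAAAA"), turner, 37.0) == 0.0

    def test_two_state_hairpin_has_positive_melting_peak(self, turner):
        seq = NucleotideSequence("GCAUCAAAAGAUGC")
        prof = temperature_scan(seq, turner, 0.0, 100.0, 2.0)
        k = int(np.argmax(prof.heat_capacity))
        assert prof.heat_capacity[k] > 0.5
        assert 0 < k < len(prof.temperatures_c) - 1

    def test_heat_capacity_integrates_ensemble_enthalpy(self, turner):
        # integral of C = -T G'' recovers the change of the Boltzmann-average
        # enthalpy <H_t>; the endpoint averages are computed independently by
        # exhaustive enumeration (interior of the grid, away from the
        # derivative-filter edges)
        import dataclasses
        from entrofold.ensemble import brute_force_summary
        from entrofold.energy import turner_enthalpy_of_structure
        from entrofold.partition import TemperaturePair

        seq = NucleotideSequence("GGGGGAAAACCCCC")
        smooth = dataclasses.replace(turner, quantize=False)
        prof = temperature_scan(seq, turner, 10.0, 95.0, 0.5)
        grid = prof.temperatures_c
        mask = (grid >= 20.0) & (grid <= 85.0)
        integral = np.trapezoid(prof.heat_capacity[mask], grid[mask])

        def mean_enthalpy(tc):
            t = tc + K0
            bf = brute_force_summary(seq, smooth, TemperaturePair(t, t))
            hts = np.array([turner_enthalpy_of_structure(seq, s, smooth)
                            for s in bf.structures])
            return float((bf.probabilities * hts).sum())

        dh = mean_enthalpy(85.0) - mean_enthalpy(20.0)
        assert integral == pytest.approx(dh, rel=0.01)

    def test_profile_matches_independent_dp_runs(self, turner):
        import dataclasses
        from entrofold.entropy_dp import entropy_dp
        from entrofold.partition import TemperaturePair
        seq = NucleotideSequence("GGCGCAAAAGCGCAAGG")
        smooth = dataclasses.replace(turner, quantize=False)
        prof = temperature_scan(seq, turner, 30.0, 50.0, 10.0)
        for tc, h in zip(prof.temperatures_c, prof.entropy):
            t = tc + K0
            s = entropy_dp(seq, smooth, TemperaturePair(t, t))
            assert h == pytest.approx(s.entropy, abs=1e-12)

    def test_no_pair_sequence_flat_profile(self, turner):
        prof = temperature_scan(NucleotideSequence("AAAAAAAA"), turner,
                                20.0, 60.0, 10.0)
        assert np.allclose(prof.entropy, 0.0)

    def test_entropy_slope_peaks_with_heat_capacity(self, turner):
        # dH/dT = C/(RT) - (1/R) d<S_t>/dT: the entropy of the ensemble
        # changes fastest in the melting region, so its slope peaks within a
        # few Kelvin of the heat-capacity maximum.  Past the midpoint the
        # second term wins and the slope turns negative, which is why a plain
        # Pearson correlation over the whole range is not the right check.
        seq = NucleotideSequence("GCAUCAAAAGAUGC")
        prof = temperature_scan(seq, turner, 0.0, 100.0, 1.0)
        dh = np.gradient(prof.entropy, prof.temperatures_c)
        t_c = prof.temperatures_c[np.argmax(prof.heat_capacity)]
        t_h = prof.temperatures_c[np.argmax(dh)]
        assert dh.max() > 0
        assert abs(t_c - t_h) <= 15.0

    def test_hairpin_entropy_rises_with_temperature(self, turner):
        seq = NucleotideSequence("GGGGGAAAACCCCC")
        prof = temperature_scan(seq, turner, 10.0, 100.0, 10.0)
        assert prof.entropy[-1] > prof.entropy[0]
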