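"""Ensemble-derived structural measures and temperature profiles.

All measures are closed-form functions of the exact base-pair probability
matrix ``p`` (and its positional extension ``p*``), so they are Boltzmann
averages over the full ensemble without any sampling:

* positional entropy  H2(i) = -sum_j p*[i,j] ln p*[i,j]
* ensemble defect     expected number of wrongly paired/unpaired positions
  relative to a reference structure s0, length-normalized
* expected base-pair distance to s0, length-normalized
* native contacts     sum of p[i,j] over pairs of s0, divided by |s0|
* structural diversity, both the base-pair-distance form (the "ensemble
  diversity" of the Vienna tradition) and the Morgan-Higgs Hamming form

Temperature profiles rescale the tables *and* the formal temperature
together (full temperature), in contrast to the formal-only derivative used
by the finite-difference entropy method; the heat capacity is the calorimetric
C(T) = -T d2G/dT2, i.e. the temperature derivative of the Boltzmann-average
enthalpy, estimated on that full-temperature grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.signal import savgol_filter

from .entropy_dp import EnsembleSummary, entropy_dp
from .params import EnergyParameters, K0, ModelConventions
from .partition import BasePairMatrix, TemperaturePair, basepair_probabilities
from .sequence import NucleotideSequence, SecondaryStructure


def _xlogx(v: np.ndarray) -> np.ndarray:
    out = np.zeros_like(v)
    mask = v > 0
    out[mask] = v[mask] * np.log(v[mask])
    return out


def positional_entropy(pmat: BasePairMatrix) -> tuple[np.ndarray, float]:
    """Per-position Shannon entropies H2(i) and their average, in nats.

    H2(i) is the entropy of the distribution "position i pairs with j, or
    stays unpaired" (0 ln 0 := 0).  Low values mean the ensemble agrees on
    the pairing status of position i.
    """
    h2 = -_xlogx(pmat.pstar).sum(axis=1)
    return h2, float(h2.mean())


def _check_ref(pmat: BasePairMatrix, s0: SecondaryStructure) -> None:
    if s0.n != pmat.n:
        raise ValueError(
            f"reference structure length {s0.n} != matrix size {pmat.n}")


def ensemble_defect(pmat: BasePairMatrix, s0: SecondaryStructure) -> float:
    """Length-normalized expected number of positions whose pairing status
    disagrees with ``s0``: n - sum_pairs p* - sum_unpaired p*_ii, over n."""
    _check_ref(pmat, s0)
    n = pmat.n
    agree = 0.0
    partner = s0.partner()
    for i in range(n):
        j = partner[i]
        agree += pmat.pstar[i, j] if j >= 0 else pmat.pstar[i, i]
    return (n - agree) / n


def expected_bp_distance(pmat: BasePairMatrix, s0: SecondaryStructure) -> float:
    """Length-normalized Boltzmann-average base-pair distance to ``s0``.

    Closed form: sum over i<j of p[i,j] for pairs not in s0 plus (1 - p[i,j])
    for pairs in s0.
    """
    _check_ref(pmat, s0)
    n = pmat.n
    iu = np.triu_indices(n, 1)
    total = float(pmat.p[iu].sum())
    for (i, j) in s0.pairs:
        total += 1.0 - 2.0 * pmat.p[i, j]
    return total / n


def native_contacts(pmat: BasePairMatrix, s0: SecondaryStructure) -> float:
    """Boltzmann-expected fraction of the reference pairs present in the
    ensemble: sum_{(i,j) in s0} p[i,j] / |s0|."""
    _check_ref(pmat, s0)
    if len(s0.pairs) == 0:
        raise ValueError("native_contacts is undefined for an empty reference")
    return float(sum(pmat.p[i, j] for (i, j) in s0.pairs)) / len(s0.pairs)


def vienna_diversity(pmat: BasePairMatrix) -> float:
    """Mean base-pair distance between two independent ensemble draws:
    2 * sum_{i<j} p[i,j] (1 - p[i,j])."""
    n = pmat.n
    iu = np.triu_indices(n, 1)
    p = pmat.p[iu]
    return float((2.0 * p * (1.0 - p)).sum())


def morgan_higgs_diversity(pmat: BasePairMatrix) -> float:
    """Mean Hamming distance between the partner arrays of two independent
    draws: n - sum_{i,j} p*[i,j]^2."""
    return float(pmat.n - (pmat.pstar ** 2).sum())


@dataclass
class MeasureSet:
    """All closed-form ensemble measures for one sequence."""

    positional: np.ndarray
    positional_mean: float
    ensemble_defect: float | None
    expected_bp_distance: float | None
    native_contacts: float | None
    vienna_diversity: float
    morgan_higgs_diversity: float


def ensemble_measures(seq: NucleotideSequence, params: EnergyParameters,
                      temps: TemperaturePair | None = None, *,
                      s0: SecondaryStructure | None = None,
                      theta: int = 3,
                      conv: ModelConventions | None = None) -> MeasureSet:
    """Compute every measure from one exact probability matrix."""
    pmat = basepair_probabilities(seq, params, temps, theta=theta, conv=conv)
    h2, h2m = positional_entropy(pmat)
    return MeasureSet(
        positional=h2,
        positional_mean=h2m,
        ensemble_defect=(ensemble_defect(pmat, s0) if s0 is not None else None),
        expected_bp_distance=(expected_bp_distance(pmat, s0)
                              if s0 is not None else None),
        native_contacts=(native_contacts(pmat, s0)
                         if s0 is not None and len(s0.pairs) else None),
        vienna_diversity=vienna_diversity(pmat),
        morgan_higgs_diversity=morgan_higgs_diversity(pmat),
    )


# ---------------------------------------------------------------------------
# Temperature dependence (full temperature: tables and RT move together)


def _summary_full_t(seq: NucleotideSequence, params: EnergyParameters,
                    t_kelvin: float, theta: int,
                    conv: ModelConventions | None) -> EnsembleSummary:
    temps = TemperaturePair(t_table=t_kelvin, t_formal=t_kelvin)
    # real-valued rescaling: quantizing back onto the 0.01 grid makes G(T)
    # jagged and turns temperature derivatives into noise
    params = _dc_replace(params, quantize=False)
    return entropy_dp(seq, params, temps, theta=theta, conv=conv)


def heat_capacity(seq: NucleotideSequence, params: EnergyParameters,
                  t_celsius: float, dt: float = 1.0, *, theta: int = 3,
                  conv: ModelConventions | None = None) -> float:
    """Heat capacity C(T) = -T d2G/dT2 by a centered second difference.

    Both the tables and the formal temperature move with T (full
    temperature), in contrast to the formal-only derivative of the entropy
    machinery.  By Gibbs-Helmholtz the result equals the derivative of the
    ensemble-average enthalpy, the calorimetric melting response, in
    kcal/(mol*K).
    """
    t = t_celsius + K0
    g_hi = _summary_full_t(seq, params, t + dt, theta, conv).free_energy
    g_mid = _summary_full_t(seq, params, t, theta, conv).free_energy
    g_lo = _summary_full_t(seq, params, t - dt, theta, conv).free_energy
    return -t * (g_hi - 2.0 * g_mid + g_lo) / (dt * dt)


@dataclass
class TemperatureProfile:
    """Aligned per-temperature ensemble quantities on a Celsius grid."""

    temperatures_c: np.ndarray
    entropy: np.ndarray           # H(T), nats
    free_energy: np.ndarray       # G(T), kcal/mol
    expected_energy: np.ndarray   # <E>(T), kcal/mol
    heat_capacity: np.ndarray     # C(T), kcal/(mol*K)


def temperature_scan(seq: NucleotideSequence, params: EnergyParameters,
                     t_min_c: float = 0.0, t_max_c: float = 100.0,
                     step: float = 1.0, *, theta: int = 3,
                     conv: ModelConventions | None = None
                     ) -> TemperatureProfile:
    """H, G, <E> and C on a temperature grid (full-temperature rescaling)."""
    if not t_max_c > t_min_c or step <= 0:
        raise ValueError("require t_min < t_max and positive step")
    grid = np.arange(t_min_c, t_max_c + step / 2, step)
    hs, gs, es = [], [], []
    for tc in grid:
        s = _summary_full_t(seq, params, tc + K0, theta, conv)
        hs.append(s.entropy)
        gs.append(s.free_energy)
        es.append(s.expected_energy)
    gs_arr = np.asarray(gs)
    t_kelvin = grid + K0
    # The integer 0.01 kcal/mol tables make G(T) piecewise linear with small
    # kinks; a local-parabola (Savitzky-Golay) second derivative suppresses
    # that quantization noise, in the spirit of melting-curve software.
    if len(gs_arr) >= 7:
        win = min(11, len(gs_arr) - (1 - len(gs_arr) % 2))
        d2g = savgol_filter(gs_arr, window_length=win, polyorder=2, deriv=2,
                            delta=float(step))
    else:
        d2g = np.gradient(np.gradient(gs_arr, t_kelvin), t_kelvin)
    cs = -t_kelvin * d2g
    return TemperatureProfile(temperatures_c=grid, entropy=np.asarray(hs),
                              free_energy=gs_arr,
                              expected_energy=np.asarray(es),
                              heat_capacity=cs)
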