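"""Exact structural entropy by dynamic programming.

Alongside the partition function ``Z = sum_s exp(-E(s)/RT)`` the recursions
accumulate ``Q = sum_s E(s) * exp(-E(s)/RT)``, so the Boltzmann-expected
energy is the exact ratio ``<E> = Q/Z`` and the Shannon entropy of the
ensemble follows from the identity

    H = -sum_s p(s) ln p(s) = <E>/RT + ln Z = (<E> - G) / RT.

With every structure energy equal to zero (or formal temperature going to
infinity) H reduces to the logarithm of the number of structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import GAS_CONSTANT, EnergyParameters
from .partition import InsideMatrices, TemperaturePair, inside
from .energy import ModelConventions
from .sequence import NucleotideSequence


@dataclass(frozen=True)
class EnsembleSummary:
    """Thermodynamic summary of the Boltzmann ensemble of one sequence."""

    log_z: float              #: ln Z
    free_energy: float        #: G = -RT ln Z, kcal/mol
    expected_energy: float    #: <E>, kcal/mol
    entropy: float            #: H, nats (dimensionless Shannon entropy)
    temps: TemperaturePair
    method: str = "dp"

    @property
    def conformational_entropy(self) -> float:
        """S = k_B * H in molar units, kcal/(mol*K).

        The Boltzmann constant times Avogadro's number is the gas constant,
        so per mole of molecules S is simply R * H.
        """
        return GAS_CONSTANT * self.entropy


def q_matrices(seq: NucleotideSequence, params: EnergyParameters,
               temps: TemperaturePair | None = None, *, theta: int = 3,
               conv: ModelConventions | None = None,
               matrices: InsideMatrices | None = None) -> InsideMatrices:
    """Inside matrices including the energy-weighted Q/QB/QM/QM1 set."""
    if matrices is not None:
        if matrices.Q is None:
            raise ValueError("inside matrices were filled without the Q set")
        return matrices
    return inside(seq, params, temps, theta=theta, want_q=True, conv=conv)


def expected_energy_dp(seq: NucleotideSequence, params: EnergyParameters,
                       temps: TemperaturePair | None = None, *,
                       theta: int = 3,
                       conv: ModelConventions | None = None,
                       matrices: InsideMatrices | None = None) -> float:
    """Exact Boltzmann-expected energy <E> = Q(1,n) / Z(1,n), kcal/mol."""
    m = q_matrices(seq, params, temps, theta=theta, conv=conv,
                   matrices=matrices)
    n = m.n
    return float(m.Q[0, n - 1] / m.Z[0, n - 1])


def entropy_dp(seq: NucleotideSequence, params: EnergyParameters,
               temps: TemperaturePair | None = None, *, theta: int = 3,
               conv: ModelConventions | None = None,
               matrices: InsideMatrices | None = None) -> EnsembleSummary:
    """Exact structural entropy H = <E>/RT + ln Z of the ensemble."""
    m = q_matrices(seq, params, temps, theta=theta, conv=conv,
                   matrices=matrices)
    n = m.n
    z = float(m.Z[0, n - 1])
    log_z = math.log(z)
    e = float(m.Q[0, n - 1] / z)
    rt = m.temps.rt
    h = e / rt + log_z
    return EnsembleSummary(log_z=log_z, free_energy=-rt * log_z,
                           expected_energy=e, entropy=h, temps=m.temps,
                           method="dp")
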