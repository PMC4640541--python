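"""McCaskill-style inside/outside recursions with uncoupled temperatures.

Two distinct temperatures appear in the partition function

    Z = sum_s exp(-E(s) / (R * T_formal))

The *table temperature* determines the energies E(s) through the
temperature-rescaled parameter tables; the *formal temperature* is the one
occurring in every RT.  Keeping them independent is what makes a clean
finite-difference derivative of ln Z possible (the tables are integer-valued
in 0.01 kcal/mol and jump discontinuously with table temperature, while
ln Z is smooth in the formal temperature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .energy import ModelConventions, can_pair_types, hairpin_energy_int
from .params import EnergyParameters, GAS_CONSTANT, T37, rescale_to_temperature
from .sequence import NucleotideSequence

#: Largest sequence length for which the unscaled partition function is safe
#: in double precision (homopolymer-stack heuristic, ~0.5 nats per base).
MAX_UNSCALED_N = 1300


class NumericRangeError(OverflowError):
    """Partition function exceeds double-precision range for this length."""


@dataclass(frozen=True)
class TemperaturePair:
    """Table temperature and formal temperature, both in Kelvin."""

    t_table: float = T37
    t_formal: float = T37

    def __post_init__(self) -> None:
        if self.t_table <= 0 or self.t_formal <= 0:
            raise ValueError("temperatures must be positive (Kelvin)")

    @property
    def beta(self) -> float:
        """Scaling factor T_formal / T_table (the betaScale constant)."""
        return self.t_formal / self.t_table

    @property
    def rt(self) -> float:
        """R * T_formal in kcal/mol."""
        return GAS_CONSTANT * self.t_formal

    def shifted(self, delta: float) -> "TemperaturePair":
        """Same tables, formal temperature shifted by ``delta`` Kelvin."""
        return TemperaturePair(self.t_table, self.t_formal + delta)


def _table_args(seq_enc: np.ndarray, params: EnergyParameters, theta: int,
                conv: ModelConventions):
    """Kernel-ready dense view of the energy model at params.T_table."""
    n = len(seq_enc)
    ptype = can_pair_types(seq_enc, theta)
    hp = np.full((n, n), _kernels.BIG)
    pb = params.pair_bonus / 100.0
    for i in range(n):
        for j in range(i + theta + 1, n):
            if ptype[i, j] != 0:
                hp[i, j] = hairpin_energy_int(seq_enc, i, j, params, conv) / 100.0 + pb
    au = params.terminal_au_penalty / 100.0
    au_mask = (ptype > 2).astype(np.float64) * np.tri(n, n, -1).T
    au_ext = au_mask * (au if conv.au_exterior else 0.0)
    au_ml = au_mask * (au if conv.au_multiloop else 0.0)
    t = params.table
    return dict(
        seq=seq_enc.astype(np.int64),
        ptype=ptype,
        hp=hp,
        au_ext=au_ext,
        au_ml=au_ml,
        stack=t("stack") / 100.0,
        bulge=t("bulge") / 100.0,
        internal=t("internal") / 100.0,
        mm_int=t("mismatch_internal") / 100.0,
        mm_1n=t("mismatch_internal_1n") / 100.0,
        mm_23=t("mismatch_internal_23") / 100.0,
        i11=t("int11") / 100.0,
        i21=t("int21") / 100.0,
        i22=t("int22") / 100.0,
        ninio_m=params.ninio_m / 100.0,
        ninio_max=params.ninio_max / 100.0,
        lxc=params.lxc,
        au_bulge=(au if conv.au_bulge else 0.0),
        pair_bonus=pb,
        a=params.a / 100.0 + pb,
        b=params.b / 100.0,
        c=params.c / 100.0,
        max_loop=min(params.max_loop, n),
    )


@dataclass
class InsideMatrices:
    """Inside partition-function matrices and their energy-weighted twins."""

    seq: NucleotideSequence
    params: EnergyParameters
    temps: TemperaturePair
    theta: int
    conv: ModelConventions
    Z: np.ndarray
    ZB: np.ndarray
    ZM: np.ndarray
    ZM1: np.ndarray
    Q: np.ndarray | None = None
    QB: np.ndarray | None = None
    QM: np.ndarray | None = None
    QM1: np.ndarray | None = None
    _targs: dict | None = None

    @property
    def n(self) -> int:
        return len(self.seq)

    @property
    def partition_function(self) -> float:
        return float(self.Z[0, self.n - 1])

    @property
    def log_partition_function(self) -> float:
        return math.log(self.partition_function)


def inside(seq: NucleotideSequence, params: EnergyParameters,
           temps: TemperaturePair | None = None, *, theta: int = 3,
           want_q: bool = False,
           conv: ModelConventions | None = None) -> InsideMatrices:
    """Fill the inside matrices; ``want_q`` adds the Q (energy-sum) set."""
    if temps is None:
        temps = TemperaturePair()
    if conv is None:
        conv = params.conventions
    if params.T_table != temps.t_table:
        params = rescale_to_temperature(params, temps.t_table)
    n = len(seq)
    if n > MAX_UNSCALED_N:
        raise NumericRangeError(
            f"n = {n} exceeds the double-precision safe length "
            f"{MAX_UNSCALED_N} of the unscaled recursions"
        )
    targs = _table_args(seq.encode(), params, theta, conv)
    Z, ZB, ZM, ZM1, Q, QB, QM, QM1 = _kernels.fill_inside(
        n, theta, temps.rt, targs["seq"], targs["ptype"], targs["hp"],
        targs["au_ext"], targs["au_ml"], targs["stack"], targs["bulge"],
        targs["internal"], targs["mm_int"], targs["mm_1n"], targs["mm_23"],
        targs["i11"], targs["i21"], targs["i22"], targs["ninio_m"],
        targs["ninio_max"], targs["lxc"], targs["au_bulge"],
        targs["pair_bonus"], targs["a"], targs["b"], targs["c"],
        targs["max_loop"], want_q)
    if not np.isfinite(Z[0, n - 1]):
        raise NumericRangeError(f"partition function overflow at n = {n}")
    return InsideMatrices(seq=seq, params=params, temps=temps, theta=theta,
                          conv=conv, Z=Z, ZB=ZB, ZM=ZM, ZM1=ZM1,
                          Q=(Q if want_q else None),
                          QB=(QB if want_q else None),
                          QM=(QM if want_q else None),
                          QM1=(QM1 if want_q else None),
                          _targs=targs)


def ensemble_free_energy(matrices: InsideMatrices,
                         temps: TemperaturePair | None = None) -> float:
    """G = -R T_formal ln Z, kcal/mol."""
    temps = temps or matrices.temps
    return -temps.rt * matrices.log_partition_function


@dataclass
class BasePairMatrix:
    """Exact pairing probabilities p[i, j] and the positional distribution
    p*[i, j] whose diagonal holds the probability of being unpaired."""

    p: np.ndarray
    pstar: np.ndarray

    @property
    def n(self) -> int:
        return self.p.shape[0]


def basepair_probabilities(seq: NucleotideSequence, params: EnergyParameters,
                           temps: TemperaturePair | None = None, *,
                           theta: int = 3,
                           conv: ModelConventions | None = None,
                           matrices: InsideMatrices | None = None) -> BasePairMatrix:
    """Boltzmann probability of every base pair, via outside recursions."""
    m = matrices or inside(seq, params, temps, theta=theta, conv=conv)
    targs = m._targs
    n = m.n
    O = _kernels.fill_outside(
        n, m.theta, m.temps.rt, targs["seq"], targs["ptype"], m.Z, m.ZB,
        m.ZM, m.ZM1, targs["au_ext"], targs["au_ml"], targs["stack"],
        targs["bulge"], targs["internal"], targs["mm_int"], targs["mm_1n"],
        targs["mm_23"], targs["i11"], targs["i21"], targs["i22"],
        targs["ninio_m"], targs["ninio_max"], targs["lxc"],
        targs["au_bulge"], targs["pair_bonus"], targs["a"], targs["b"],
        targs["c"], targs["max_loop"])
    p = O * m.ZB / m.partition_function
    p = p + p.T
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ArithmeticError(
            f"pair probability outside [0,1]: min={p.min()}, max={p.max()}"
        )
    pstar = p.copy()
    np.fill_diagonal(pstar, np.clip(1.0 - p.sum(axis=1), 0.0, 1.0))
    return BasePairMatrix(p=p, pstar=pstar)
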