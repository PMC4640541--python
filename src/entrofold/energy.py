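"""Loop-decomposition free energies of secondary structures.

Every secondary structure decomposes uniquely into loops: hairpins, internal
loops (stacked pairs and bulges are the degenerate cases), multiloops and the
exterior loop.  ``structure_energy`` sums the loop terms exactly as an
RNAeval-style evaluator would with dangles and coaxial stacking disabled:

* hairpins: length term, terminal mismatch (loops of 4+), special
  tri/tetra/hexaloop motifs, terminal-AU penalty for triloops;
* internal loops: stack table, bulge tables (plus stacking across bulges of
  one base), 1x1/2x1/2x2 special tables, generic length + Ninio asymmetry +
  terminal mismatches;
* multiloops: affine ``a + b*N_b + c*N_u`` with ``N_b`` counting the closing
  pair, plus a terminal-AU penalty per AU/GU stem facing the loop;
* exterior loop: terminal-AU penalty per AU/GU top-level stem.

All arithmetic is integer (0.01 kcal/mol units); kcal/mol floats only at the
API boundary.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    CLASSIC,
    STANDARD,
    EnergyParameters,
    ModelConventions,
    T37,
    rescale_to_temperature,
)
from .sequence import PAIR_TYPE, NucleotideSequence, SecondaryStructure, StructureError


def can_pair_types(seq_enc: np.ndarray, theta: int) -> np.ndarray:
    """Pair-type matrix: ``pt[i, j]`` in 0..6, zeroed where ``0 <= j - i <= theta``.

    The lower triangle keeps the raw reversed pair types (``pt[j, i]`` is the
    type of the inner pair seen from inside a loop).
    """
    pt = PAIR_TYPE[seq_enc[:, None], seq_enc[None, :]].astype(np.int64)
    n = len(seq_enc)
    ii, jj = np.indices((n, n))
    pt[(jj >= ii) & (jj - ii <= theta)] = 0
    return pt


def _lxc_term(lxc: float, size: int, quantize: bool = True):
    v = lxc * math.log(size / 30.0)
    return int(v) if quantize else v


def hairpin_energy_int(seq_enc: np.ndarray, i: int, j: int,
                       params: EnergyParameters,
                       conv: ModelConventions | None = None) -> int:
    """Hairpin loop closed by (i, j), integer 0.01 kcal/mol (no pair bonus)."""
    if conv is None:
        conv = params.conventions
    s = seq_enc
    pt = PAIR_TYPE[s[i], s[j]]
    if pt == 0:
        raise StructureError(f"bases {i + 1} and {j + 1} cannot pair")
    size = j - i - 1
    hp = params.table("hairpin")
    e = (hp[size].item() if size <= 30
         else hp[30].item() + _lxc_term(params.lxc, size, params.quantize))
    if conv.special_hairpins and size in (3, 4, 6):
        motif = "".join("NACGU"[b] for b in s[i:j + 1])
        es = params.special_hairpin_energy(motif)
        if es is not None:
            return es
    if size == 3:
        if pt > 2 and conv.au_hairpin3:
            e += params.terminal_au_penalty
        return e
    mm = params.table("mismatch_hairpin")
    return e + mm[pt, s[i + 1], s[j - 1]].item()


def internal_energy_int(seq_enc: np.ndarray, i: int, j: int, l: int, r: int,
                        params: EnergyParameters,
                        conv: ModelConventions | None = None) -> int:
    """Internal loop / bulge / stack between pairs (i, j) and (l, r)."""
    if conv is None:
        conv = params.conventions
    s = seq_enc
    if not (i < l < r < j):
        raise StructureError("internal loop requires i < l < r < j")
    pt = PAIR_TYPE[s[i], s[j]]
    pt2 = PAIR_TYPE[s[r], s[l]]  # inner pair seen from the inside
    if pt == 0 or pt2 == 0:
        raise StructureError("both closing pairs must be pairable")
    n1 = l - i - 1
    n2 = j - r - 1
    if n1 + n2 > params.max_loop:
        raise StructureError(
            f"internal loop of {n1}+{n2} unpaired exceeds cap {params.max_loop}"
        )
    nl, ns = (n1, n2) if n1 >= n2 else (n2, n1)
    au = params.terminal_au_penalty
    if nl == 0:
        return params.table("stack")[pt, pt2].item()
    if ns == 0:  # bulge
        bt = params.table("bulge")
        e = (bt[nl].item() if nl <= 30
             else bt[30].item() + _lxc_term(params.lxc, nl, params.quantize))
        if nl == 1:
            e += params.table("stack")[pt, pt2].item()
        else:
            if conv.au_bulge:
                if pt > 2:
                    e += au
                if pt2 > 2:
                    e += au
        return e
    si1, sj1 = s[i + 1], s[j - 1]
    sp1, sq1 = s[l - 1], s[r + 1]
    if ns == 1:
        if nl == 1:
            return params.table("int11")[pt, pt2, si1, sj1].item()
        if nl == 2:
            if n1 == 1:
                return params.table("int21")[pt, pt2, si1, sq1, sj1].item()
            return params.table("int21")[pt2, pt, sq1, si1, sp1].item()
        # 1 x n loops
        it = params.table("internal")
        u = nl + 1
        e = (it[u].item() if u <= 30
             else it[30].item() + _lxc_term(params.lxc, u, params.quantize))
        e += min(params.ninio_max, (nl - ns) * params.ninio_m)
        mm = params.table("mismatch_internal_1n")
        return e + mm[pt, si1, sj1].item() + mm[pt2, sq1, sp1].item()
    if ns == 2:
        if nl == 2:
            return params.table("int22")[pt, pt2, si1, sp1, sq1, sj1].item()
        if nl == 3:
            mm = params.table("mismatch_internal_23")
            return (params.table("internal")[5].item() + params.ninio_m
                    + mm[pt, si1, sj1].item() + mm[pt2, sq1, sp1].item())
    it = params.table("internal")
    u = nl + ns
    e = (it[u].item() if u <= 30
         else it[30].item() + _lxc_term(params.lxc, u, params.quantize))
    e += min(params.ninio_max, (nl - ns) * params.ninio_m)
    mm = params.table("mismatch_internal")
    return e + mm[pt, si1, sj1].item() + mm[pt2, sq1, sp1].item()


# ---------------------------------------------------------------------------
# Whole-structure evaluation


def hairpin_energy(seq: NucleotideSequence, i: int, j: int,
                   params: EnergyParameters,
                   conv: ModelConventions | None = None) -> float:
    """Hairpin loop energy in kcal/mol (0-based indices)."""
    return hairpin_energy_int(seq.encode(), i, j, params, conv) / 100.0


def internal_loop_energy(seq: NucleotideSequence, i: int, j: int, l: int,
                         r: int, params: EnergyParameters,
                         conv: ModelConventions | None = None) -> float:
    """Stack / bulge / internal-loop energy in kcal/mol."""
    return internal_energy_int(seq.encode(), i, j, l, r, params, conv) / 100.0


def multiloop_energy(n_branches: int, n_unpaired: int,
                     params: EnergyParameters) -> float:
    """``a + b*N_b + c*N_u`` in kcal/mol with N_b counting all stems incl.
    the closing pair."""
    if n_branches < 0 or n_unpaired < 0:
        raise ValueError("branch and unpaired counts must be non-negative")
    return (params.a + params.b * n_branches + params.c * n_unpaired) / 100.0


def structure_energy_int(seq_enc: np.ndarray, structure: SecondaryStructure,
                         params: EnergyParameters,
                         conv: ModelConventions | None = None) -> int:
    """Total loop-decomposition energy, integer 0.01 kcal/mol."""
    if conv is None:
        conv = params.conventions
    n = len(seq_enc)
    if structure.n != n:
        raise StructureError("structure length does not match sequence")
    partner = structure.partner()
    au = params.terminal_au_penalty
    total = params.pair_bonus * len(structure.pairs)

    def au_of(i: int, j: int) -> int:
        return au if PAIR_TYPE[seq_enc[i], seq_enc[j]] > 2 else 0

    def children_of(i: int, j: int) -> tuple[list, int]:
        kids = []
        unpaired = 0
        k = i + 1
        while k < j:
            if partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            elif partner[k] == -1:
                unpaired += 1
                k += 1
            else:  # pragma: no cover - excluded by structure validity
                raise StructureError("inconsistent pairing")
        return kids, unpaired

    for (i, j) in structure.pairs:
        kids, unpaired = children_of(i, j)
        if not kids:
            total += hairpin_energy_int(seq_enc, i, j, params, conv)
        elif len(kids) == 1:
            (l, r) = kids[0]
            total += internal_energy_int(seq_enc, i, j, l, r, params, conv)
        else:
            total += params.a + params.b * (len(kids) + 1) + params.c * unpaired
            if conv.au_multiloop:
                total += au_of(i, j)
                for (l, r) in kids:
                    total += au_of(l, r)
    # exterior loop
    if conv.au_exterior:
        k = 0
        while k < n:
            if partner[k] > k:
                total += au_of(k, partner[k])
                k = partner[k] + 1
            else:
                k += 1
    return total


def structure_energy(seq: NucleotideSequence, structure: SecondaryStructure,
                     params: EnergyParameters, T: float | None = None,
                     conv: ModelConventions | None = None) -> float:
    """Free energy E(s) of a structure in kcal/mol at table temperature T."""
    if T is not None and T != params.T_table:
        params = rescale_to_temperature(params, T)
    return structure_energy_int(seq.encode(), structure, params, conv) / 100.0


def turner_entropy_of_structure(seq: NucleotideSequence,
                                structure: SecondaryStructure,
                                params: EnergyParameters,
                                conv: ModelConventions | None = None) -> float:
    """Tabulated entropy change S_t(s) = E(s, 37C) - E(s, 38C), kcal/(mol*K).

    Always non-positive for non-empty structures in the Turner model (the
    entropic cost of ordering the chain into a structure).
    """
    e37 = structure_energy(seq, structure, params, T37, conv)
    e38 = structure_energy(seq, structure, params, T37 + 1.0, conv)
    return e37 - e38


def turner_enthalpy_of_structure(seq: NucleotideSequence,
                                 structure: SecondaryStructure,
                                 params: EnergyParameters,
                                 conv: ModelConventions | None = None) -> float:
    """Tabulated enthalpy H_t(s) with E(s, T) = H_t(s) - T * S_t(s)."""
    st = turner_entropy_of_structure(seq, structure, params, conv)
    return structure_energy(seq, structure, params, T37, conv) + T37 * st
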