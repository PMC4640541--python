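"""Ensemble verification and approximation machinery.

Exhaustive enumeration is the ground truth everything else is checked
against: Z, expected energy, entropy and pair frequencies by direct
summation over all structures.  The minimum free energy, the Wuchty-style
band enumeration (all structures within a fixed energy of the MFE) and
Ding-Lawrence stochastic traceback reuse the same loop-energy model and the
same recursion decomposition as the partition function, so every method sums
over exactly the same ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .energy import ModelConventions, structure_energy_int
from .params import EnergyParameters, rescale_to_temperature
from .partition import InsideMatrices, TemperaturePair, _table_args, inside
from .sequence import NucleotideSequence, SecondaryStructure

DEFAULT_ENUM_CAP_N = 30
DEFAULT_ENUM_CAP_COUNT = 5_000_000
_EPS = 1e-6


class EnumerationCapError(RuntimeError):
    """Structure space too large to enumerate; use the DP methods instead."""


def enumerate_structures(seq: NucleotideSequence, theta: int = 3, *,
                         cap_n: int = DEFAULT_ENUM_CAP_N,
                         cap_count: int = DEFAULT_ENUM_CAP_COUNT
                         ) -> list[SecondaryStructure]:
    """All secondary structures of ``seq``, in lexicographic pair order."""
    n = len(seq)
    if n > cap_n:
        raise EnumerationCapError(
            f"refusing to enumerate n = {n} > {cap_n}; the count grows "
            "exponentially -- use the partition-function methods"
        )
    from .sequence import PAIR_TYPE
    enc = seq.encode()
    memo: dict[tuple[int, int], tuple] = {}

    def rec(i: int, j: int) -> tuple:
        if j - i <= theta:
            return ((),)
        key = (i, j)
        hit = memo.get(key)
        if hit is not None:
            return hit
        out = list(rec(i, j - 1))
        for k in range(i, j - theta):
            if PAIR_TYPE[enc[k], enc[j]] == 0:
                continue
            left = rec(i, k - 1) if k > i else ((),)
            right = rec(k + 1, j - 1)
            for s1 in left:
                for s2 in right:
                    out.append(s1 + ((k, j),) + s2)
        memo[key] = tuple(out)
        return memo[key]

    raw = rec(0, n - 1)
    if len(raw) > cap_count:
        raise EnumerationCapError(
            f"{len(raw)} structures exceed the cap {cap_count}")
    structs = [SecondaryStructure(n=n, pairs=frozenset(p), theta=theta)
               for p in raw]
    structs.sort(key=lambda s: sorted(s.pairs))
    return structs


@dataclass
class EnsembleEnumeration:
    """Direct Boltzmann sums over the exhaustively enumerated ensemble."""

    structures: list[SecondaryStructure]
    energies: np.ndarray          # kcal/mol
    probabilities: np.ndarray
    z: float
    expected_energy: float
    entropy: float
    pair_freq: np.ndarray         # exact p[i, j] by summation

    def __len__(self) -> int:
        return len(self.structures)


def brute_force_summary(seq: NucleotideSequence, params: EnergyParameters,
                        temps: TemperaturePair | None = None, *,
                        theta: int = 3,
                        conv: ModelConventions | None = None
                        ) -> EnsembleEnumeration:
    """Ground-truth Z, <E>, H and pair frequencies by full enumeration."""
    temps = temps or TemperaturePair()
    if params.T_table != temps.t_table:
        params = rescale_to_temperature(params, temps.t_table)
    structs = enumerate_structures(seq, theta)
    enc = seq.encode()
    energies = np.array(
        [structure_energy_int(enc, s, params, conv) / 100.0 for s in structs])
    w = np.exp(-energies / temps.rt)
    z = float(w.sum())
    p = w / z
    e_mean = float((p * energies).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        h = float(-(p * np.log(p)).sum())
    n = len(seq)
    pair_freq = np.zeros((n, n))
    for s, pk in zip(structs, p):
        for (x, y) in s.pairs:
            pair_freq[x, y] += pk
    pair_freq = pair_freq + pair_freq.T
    return EnsembleEnumeration(structures=structs, energies=energies,
                               probabilities=p, z=z, expected_energy=e_mean,
                               entropy=h, pair_freq=pair_freq)


# ---------------------------------------------------------------------------
# Minimum free energy and band enumeration


def _mfe_matrices(seq: NucleotideSequence, params: EnergyParameters,
                  temps: TemperaturePair, theta: int,
                  conv: ModelConventions | None):
    if conv is None:
        conv = params.conventions
    if params.T_table != temps.t_table:
        params = rescale_to_temperature(params, temps.t_table)
    targs = _table_args(seq.encode(), params, theta, conv)
    n = len(seq)
    W, V, VM, VM1 = _kernels.fill_mfe(
        n, theta, targs["seq"], targs["ptype"], targs["hp"],
        targs["au_ext"], targs["au_ml"], targs["stack"], targs["bulge"],
        targs["internal"], targs["mm_int"], targs["mm_1n"], targs["mm_23"],
        targs["i11"], targs["i21"], targs["i22"], targs["ninio_m"],
        targs["ninio_max"], targs["lxc"], targs["au_bulge"],
        targs["pair_bonus"], targs["a"], targs["b"], targs["c"],
        targs["max_loop"])
    return W, V, VM, VM1, targs


def _interior_py(targs, k, l, i, j):
    return float(_kernels._interior(
        k, l, i, j, targs["seq"], targs["ptype"], targs["stack"],
        targs["bulge"], targs["internal"], targs["mm_int"], targs["mm_1n"],
        targs["mm_23"], targs["i11"], targs["i21"], targs["i22"],
        targs["ninio_m"], targs["ninio_max"], targs["lxc"],
        targs["au_bulge"], targs["max_loop"]))


def mfe(seq: NucleotideSequence, params: EnergyParameters,
        temps: TemperaturePair | None = None, *, theta: int = 3,
        conv: ModelConventions | None = None) -> float:
    """Minimum free energy over all structures, kcal/mol (0 for no pairs)."""
    temps = temps or TemperaturePair()
    W, *_ = _mfe_matrices(seq, params, temps, theta, conv)
    n = len(seq)
    return float(W[0, n - 1])


def mfe_structure(seq: NucleotideSequence, params: EnergyParameters,
                  temps: TemperaturePair | None = None, *, theta: int = 3,
                  conv: ModelConventions | None = None
                  ) -> tuple[SecondaryStructure, float]:
    """An MFE structure (ties broken deterministically) and its energy."""
    temps = temps or TemperaturePair()
    structs = wuchty_suboptimals(seq, params, temps, band=0.0, theta=theta,
                                 conv=conv)
    return structs[0]


def wuchty_suboptimals(seq: NucleotideSequence, params: EnergyParameters,
                       temps: TemperaturePair | None = None, *,
                       band: float = 0.0, theta: int = 3,
                       conv: ModelConventions | None = None,
                       cap_count: int = DEFAULT_ENUM_CAP_COUNT
                       ) -> list[tuple[SecondaryStructure, float]]:
    """All structures with E(s) <= MFE + band, complete and duplicate-free.

    Backtracks through the min-plus matrices keeping partial structures
    whose optimistic completion stays inside the band, which is exactly the
    suboptimal-enumeration strategy of the RNAsubopt lineage.
    """
    if band < 0:
        raise ValueError("band must be non-negative")
    temps = temps or TemperaturePair()
    W, V, VM, VM1, targs = _mfe_matrices(seq, params, temps, theta, conv)
    n = len(seq)
    limit = float(W[0, n - 1]) + band + _EPS
    ptype = targs["ptype"]
    hp = targs["hp"]
    au_ext = targs["au_ext"]
    au_ml = targs["au_ml"]
    a, b, c = targs["a"], targs["b"], targs["c"]
    pair_bonus = targs["pair_bonus"]
    max_loop = targs["max_loop"]

    def bound(ctx: int, i: int, j: int) -> float:
        if j < i:
            return 0.0
        if ctx == 0:
            return float(W[i, j]) if j - i > theta else 0.0
        if j - i <= theta:
            return _kernels.BIG
        return float((V, VM, VM1)[ctx - 1][i, j])

    results: list[tuple[tuple, float]] = []
    # state: (acc energy, items tuple of (ctx,i,j), pairs tuple)
    stack = [(0.0, ((0, 0, n - 1),), ())]
    while stack:
        acc, items, pairs = stack.pop()
        if not items:
            results.append((pairs, acc))
            if len(results) > cap_count:
                raise EnumerationCapError(
                    f"more than {cap_count} structures within the band")
            continue
        (ctx, i, j), rest = items[0], items[1:]
        rest_bound = sum(bound(*it) for it in rest)

        def push(extra: float, children: tuple, new_pairs: tuple = ()):
            tot = acc + extra + rest_bound + sum(bound(*ch) for ch in children)
            if tot <= limit:
                stack.append((acc + extra, children + rest, pairs + new_pairs))

        if ctx == 0:  # exterior-like W context
            if j - i <= theta:
                push(0.0, ())
                continue
            push(0.0, ((0, i, j - 1),))
            for k in range(i, j - theta):
                if ptype[k, j] == 0:
                    continue
                ch = ((1, k, j),) if k == i else ((0, i, k - 1), (1, k, j))
                push(float(au_ext[k, j]), ch, ((k, j),))
        elif ctx == 1:  # V: structures closed by pair (i, j)
            e = float(hp[i, j])
            if e < 1e8:
                push(e, ())
            lmax = min(i + max_loop + 1, j - theta - 2)
            for l in range(i + 1, lmax + 1):
                n1 = l - i - 1
                rmin = max(l + theta + 1, j - 1 - (max_loop - n1))
                for r in range(rmin, j):
                    if ptype[l, r] == 0:
                        continue
                    e = _interior_py(targs, i, j, l, r) + pair_bonus
                    if e < 1e8:
                        push(e, ((1, l, r),), ((l, r),))
            e0 = a + b + float(au_ml[i, j])
            for r in range(i + theta + 3, j - theta - 1):
                push(e0, ((2, i + 1, r - 1), (3, r, j - 1)))
        elif ctx == 2:  # VM: one or more multiloop components
            for r in range(i, j - theta):
                push(c * (r - i), ((3, r, j),))
            for r in range(i + theta + 2, j - theta):
                push(0.0, ((2, i, r - 1), (3, r, j)))
        else:  # VM1: exactly one component starting at i
            for k in range(i + theta + 1, j + 1):
                if ptype[i, k] == 0:
                    continue
                e1 = b + float(au_ml[i, k]) + c * (j - k)
                push(e1, ((1, i, k),), ((i, k),))

    seen = {}
    for pairs, e in results:
        seen[frozenset(pairs)] = e
    out = [(SecondaryStructure(n=n, pairs=fs, theta=theta), e)
           for fs, e in seen.items()]
    out.sort(key=lambda t: (t[1], sorted(t[0].pairs)))
    return out


# ---------------------------------------------------------------------------
# Stochastic traceback (Ding-Lawrence sampling)


def boltzmann_sample(seq: NucleotideSequence, params: EnergyParameters,
                     temps: TemperaturePair | None = None, *, n_samples: int,
                     seed: int, theta: int = 3,
                     conv: ModelConventions | None = None,
                     matrices: InsideMatrices | None = None
                     ) -> list[SecondaryStructure]:
    """``n_samples`` i.i.d. draws from the Boltzmann distribution.

    Stochastic traceback of the inside matrices: at every decomposition
    point the branch is chosen with probability proportional to its
    contribution to the corresponding inside sum.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    m = matrices or inside(seq, params, temps, theta=theta, conv=conv)
    rng = np.random.default_rng(seed)
    n = m.n
    targs = m._targs
    rt = m.temps.rt
    ptype = targs["ptype"]
    hp = targs["hp"]
    au_ext = targs["au_ext"]
    au_ml = targs["au_ml"]
    a, b, c = targs["a"], targs["b"], targs["c"]
    pair_bonus = targs["pair_bonus"]
    max_loop = targs["max_loop"]
    Z, ZB, ZM, ZM1 = m.Z, m.ZB, m.ZM, m.ZM1
    th = theta

    def choose(weights: list[float], total: float) -> int:
        u = rng.random() * total
        acc = 0.0
        for idx, w in enumerate(weights):
            acc += w
            if u <= acc:
                return idx
        return len(weights) - 1

    def sample_one() -> frozenset:
        pairs: list[tuple[int, int]] = []
        agenda: list[tuple[int, int, int]] = [(0, 0, n - 1)]
        while agenda:
            ctx, i, j = agenda.pop()
            if j - i <= th:
                continue
            if ctx == 0:  # Z context
                cases = [(Z[i, j - 1], None)]
                for k in range(i, j - th):
                    if ptype[k, j] == 0 or ZB[k, j] == 0.0:
                        continue
                    zl = Z[i, k - 1] if k > i else 1.0
                    w = math.exp(-au_ext[k, j] / rt) * zl * ZB[k, j]
                    cases.append((w, k))
                idx = choose([w for w, _ in cases], Z[i, j])
                k = cases[idx][1]
                if k is None:
                    agenda.append((0, i, j - 1))
                else:
                    pairs.append((k, j))
                    agenda.append((1, k, j))
                    if k > i:
                        agenda.append((0, i, k - 1))
            elif ctx == 1:  # ZB context: pair (i, j) fixed
                cases = []
                e = hp[i, j]
                cases.append((math.exp(-e / rt) if e < 1e8 else 0.0,
                              ("hp",)))
                lmax = min(i + max_loop + 1, j - th - 2)
                for l in range(i + 1, lmax + 1):
                    n1 = l - i - 1
                    rmin = max(l + th + 1, j - 1 - (max_loop - n1))
                    for r in range(rmin, j):
                        if ptype[l, r] == 0 or ZB[l, r] == 0.0:
                            continue
                        e = _interior_py(targs, i, j, l, r) + pair_bonus
                        if e >= 1e8:
                            continue
                        cases.append((math.exp(-e / rt) * ZB[l, r],
                                      ("il", l, r)))
                w0 = math.exp(-(a + b + au_ml[i, j]) / rt)
                for r in range(i + th + 3, j - th - 1):
                    zl = ZM[i + 1, r - 1]
                    zr = ZM1[r, j - 1]
                    if zl == 0.0 or zr == 0.0:
                        continue
                    cases.append((w0 * zl * zr, ("ml", r)))
                idx = choose([w for w, _ in cases], ZB[i, j])
                tag = cases[idx][1]
                if tag[0] == "il":
                    _, l, r = tag
                    pairs.append((l, r))
                    agenda.append((1, l, r))
                elif tag[0] == "ml":
                    r = tag[1]
                    agenda.append((2, i + 1, r - 1))
                    agenda.append((3, r, j - 1))
            elif ctx == 2:  # ZM context
                cases = []
                for r in range(i, j - th):
                    if ZM1[r, j] == 0.0:
                        continue
                    cases.append((math.exp(-c * (r - i) / rt) * ZM1[r, j],
                                  ("one", r)))
                for r in range(i + th + 2, j - th):
                    if ZM[i, r - 1] == 0.0 or ZM1[r, j] == 0.0:
                        continue
                    cases.append((ZM[i, r - 1] * ZM1[r, j], ("more", r)))
                idx = choose([w for w, _ in cases], ZM[i, j])
                kind, r = cases[idx][1]
                agenda.append((3, r, j))
                if kind == "more":
                    agenda.append((2, i, r - 1))
            else:  # ZM1 context
                cases = []
                for k in range(i + th + 1, j + 1):
                    if ptype[i, k] == 0 or ZB[i, k] == 0.0:
                        continue
                    e1 = b + au_ml[i, k] + c * (j - k)
                    cases.append((math.exp(-e1 / rt) * ZB[i, k], k))
                idx = choose([w for w, _ in cases], ZM1[i, j])
                k = cases[idx][1]
                pairs.append((i, k))
                agenda.append((1, i, k))
        return frozenset(pairs)

    return [SecondaryStructure(n=n, pairs=sample_one(), theta=theta)
            for _ in range(n_samples)]


# ---------------------------------------------------------------------------
# Sampling-based entropy approximations


def entropy_estimate_sampling(seq: NucleotideSequence,
                              params: EnergyParameters,
                              temps: TemperaturePair | None = None, *,
                              n_samples: int, seed: int, theta: int = 3,
                              conv: ModelConventions | None = None) -> float:
    """H estimate with <E> replaced by the mean energy of sampled structures.

    ln Z is exact (from the inside matrices); only the expected energy is
    approximated, by the arithmetic mean over ``n_samples`` Boltzmann draws.
    """
    temps = temps or TemperaturePair()
    m = inside(seq, params, temps, theta=theta, conv=conv)
    sample = boltzmann_sample(seq, params, temps, n_samples=n_samples,
                              seed=seed, theta=theta, conv=conv, matrices=m)
    p = m.params
    enc = seq.encode()
    energies = [structure_energy_int(enc, s, p, conv) / 100.0 for s in sample]
    e_mean = float(np.mean(energies))
    return e_mean / m.temps.rt + m.log_partition_function


def entropy_estimate_band(seq: NucleotideSequence, params: EnergyParameters,
                          temps: TemperaturePair | None = None, *,
                          band: float, theta: int = 3,
                          conv: ModelConventions | None = None,
                          use_truncated_z: bool = False) -> float:
    """H estimate over the structures within ``band`` kcal/mol of the MFE.

    Structure probabilities are normalized by the truncated partition
    function Z0 of the generated set; by default the final assembly uses the
    exact ln Z, with ``use_truncated_z`` switching to ln Z0.
    """
    temps = temps or TemperaturePair()
    subopt = wuchty_suboptimals(seq, params, temps, band=band, theta=theta,
                                conv=conv)
    energies = np.array([e for _, e in subopt])
    w = np.exp(-energies / temps.rt)
    z0 = float(w.sum())
    p = w / z0
    e_mean = float((p * energies).sum())
    if use_truncated_z:
        lnz = math.log(z0)
    else:
        lnz = inside(seq, params, temps, theta=theta,
                     conv=conv).log_partition_function
    return e_mean / temps.rt + lnz
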