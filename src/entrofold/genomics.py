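"""Genome-scale applications: window scans, dinucleotide-shuffle null
distributions, and linker-concatenation hybridization entropy.

The window scan computes structural entropy for overlapping fixed-size
windows, smooths the profile with a centered moving average and reports
Z-scores against the mean and standard deviation of all windows of the same
scan.  Shuffle Z-scores instead compare one sequence against a null
distribution of dinucleotide-preserving shuffles (Altschul-Erikson), which
keeps both composition and nearest-neighbor stacking statistics fixed.

Hybridization entropy approximates a two-strand complex by folding the
concatenation strand1 + linker + strand2 (an unstructured oligo-A linker),
so the net entropy change of complex formation is

    dH = -H(complex) + H(strand1) + H(strand2)
    dS = k_B dH          -T dS = -RT dH  (kcal/mol at the formal T)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .entropy_dp import entropy_dp
from .measures import positional_entropy
from .params import EnergyParameters, GAS_CONSTANT, ModelConventions
from .partition import TemperaturePair, basepair_probabilities
from .sequence import NucleotideSequence


class DegenerateNullWarning(UserWarning):
    """The null distribution has zero spread; Z-scores reported as 0."""


@dataclass
class WindowProfile:
    """Sliding-window entropy profile with smoothing and Z-scores."""

    starts: np.ndarray        # 1-based window start positions
    window: int
    step: int
    smooth_k: int
    entropy: np.ndarray       # raw H per window
    smoothed: np.ndarray      # centered moving average over smooth_k windows
    zscores: np.ndarray       # (smoothed - mean) / sd over all windows


def window_scan(genome: NucleotideSequence, params: EnergyParameters,
                temps: TemperaturePair | None = None, *, window: int = 100,
                step: int = 10, smooth_k: int = 5, theta: int = 3,
                conv: ModelConventions | None = None) -> WindowProfile:
    """Entropy of every ``window``-sized portion advanced by ``step``."""
    n = len(genome)
    if window > n:
        raise ValueError(f"window {window} exceeds genome length {n}")
    if smooth_k < 1 or smooth_k % 2 == 0:
        raise ValueError("smooth_k must be a positive odd number")
    starts = np.arange(0, n - window + 1, step)
    hs = np.array([
        entropy_dp(NucleotideSequence(genome[s:s + window]), params, temps,
                   theta=theta, conv=conv).entropy
        for s in starts
    ])
    kernel = np.ones(smooth_k) / smooth_k
    if len(hs) >= smooth_k:
        sm = np.convolve(hs, kernel, mode="same")
        # fix edge windows where fewer than smooth_k values were averaged
        counts = np.convolve(np.ones_like(hs), kernel, mode="same")
        sm = sm / counts
    else:
        sm = np.full_like(hs, hs.mean())
    mu = sm.mean()
    sigma = sm.std(ddof=0)
    if sigma == 0.0:
        warnings.warn("all windows have identical entropy; Z-scores set to 0",
                      DegenerateNullWarning, stacklevel=2)
        z = np.zeros_like(sm)
    else:
        z = (sm - mu) / sigma
    return WindowProfile(starts=starts + 1, window=window, step=step,
                         smooth_k=smooth_k, entropy=hs, smoothed=sm,
                         zscores=z)


# ---------------------------------------------------------------------------
# Altschul-Erikson dinucleotide shuffle


def dinucleotide_shuffle(seq: NucleotideSequence,
                         rng: np.random.Generator | int) -> NucleotideSequence:
    """A uniform draw among sequences with the same dinucleotide counts.

    Implements the Eulerian-path strategy: the sequence is a walk on the
    letter multigraph; a random "last edge" per vertex is accepted when the
    last edges form a tree into the final letter, remaining edges are
    shuffled, and the walk is replayed.  First and last letters are fixed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    s = str(seq)
    if len(s) < 2:
        return seq
    letters = sorted(set(s))
    if len(letters) == 1:
        return seq
    idx = {ch: k for k, ch in enumerate(letters)}
    edges: list[list[int]] = [[] for _ in letters]
    for a, b in zip(s, s[1:]):
        edges[idx[a]].append(idx[b])
    first, last = idx[s[0]], idx[s[-1]]
    nv = len(letters)
    while True:
        last_edge = [-1] * nv
        ok = True
        for v in range(nv):
            if v == last:
                continue
            if edges[v]:
                last_edge[v] = edges[v][rng.integers(len(edges[v]))]
            elif v != last:
                last_edge[v] = -2  # isolated vertex (cannot occur mid-walk)
        # check the chosen last edges lead every active vertex to `last`
        for v in range(nv):
            if last_edge[v] < 0:
                continue
            seen = set()
            u = v
            while u != last and u not in seen and last_edge[u] >= 0:
                seen.add(u)
                u = last_edge[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    order: list[list[int]] = []
    for v in range(nv):
        rest = list(edges[v])
        if last_edge[v] >= 0:
            rest.remove(last_edge[v])
        rest = [rest[k] for k in rng.permutation(len(rest))]
        if last_edge[v] >= 0:
            rest.append(last_edge[v])
        order.append(rest)
    pos = [0] * nv
    out = [s[0]]
    u = first
    for _ in range(len(s) - 1):
        v = order[u][pos[u]]
        pos[u] += 1
        out.append(letters[v])
        u = v
    return NucleotideSequence("".join(out))


@dataclass
class ShuffleZScore:
    """Observed statistic against a dinucleotide-shuffle null."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_shuffles: int
    seed: int
    statistic: str


_STATISTICS = ("H", "H_per_n", "positional")


def _statistic(name: str, seq: NucleotideSequence, params: EnergyParameters,
               temps: TemperaturePair | None, theta: int,
               conv: ModelConventions | None) -> float:
    if name == "H":
        return entropy_dp(seq, params, temps, theta=theta, conv=conv).entropy
    if name == "H_per_n":
        return entropy_dp(seq, params, temps, theta=theta,
                          conv=conv).entropy / len(seq)
    if name == "positional":
        pmat = basepair_probabilities(seq, params, temps, theta=theta,
                                      conv=conv)
        return positional_entropy(pmat)[1]
    raise ValueError(f"unknown statistic {name!r}; choose from {_STATISTICS}")


def shuffle_zscore(seq: NucleotideSequence, params: EnergyParameters,
                   temps: TemperaturePair | None = None, *,
                   statistic: str = "H", n_shuffles: int = 1000,
                   seed: int = 0, theta: int = 3,
                   conv: ModelConventions | None = None) -> ShuffleZScore:
    """Z = (x - mu) / sigma of a statistic against its shuffle null."""
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles for a standard deviation")
    rng = np.random.default_rng(seed)
    x = _statistic(statistic, seq, params, temps, theta, conv)
    null = np.array([
        _statistic(statistic, dinucleotide_shuffle(seq, rng), params, temps,
                   theta, conv)
        for _ in range(n_shuffles)
    ])
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        warnings.warn("shuffle null has zero spread; Z reported as 0",
                      DegenerateNullWarning, stacklevel=2)
        z = 0.0
    else:
        z = (x - mu) / sd
    return ShuffleZScore(observed=x, null_mean=mu, null_sd=sd, z=z,
                         n_shuffles=n_shuffles, seed=seed,
                         statistic=statistic)


# ---------------------------------------------------------------------------
# Linker-concatenation hybridization entropy


DEFAULT_LINKER = "AAAAA"


@dataclass
class HybridizationEntropy:
    """Net structural-entropy change of complex formation via a linker."""

    h_strand1: float
    h_strand2: float
    h_complex: float
    linker: str
    t_formal: float

    @property
    def delta_h(self) -> float:
        """Net entropy change dH = -H(complex) + H(s1) + H(s2), nats."""
        return -self.h_complex + self.h_strand1 + self.h_strand2

    @property
    def delta_s(self) -> float:
        """dS = k_B dH in molar units, kcal/(mol*K)."""
        return GAS_CONSTANT * self.delta_h

    @property
    def minus_t_delta_s(self) -> float:
        """-T dS = -RT dH, kcal/mol: the entropic free-energy contribution."""
        return -self.t_formal * self.delta_s


def linker_hybridization_entropy(strand1: NucleotideSequence,
                                 strand2: NucleotideSequence,
                                 params: EnergyParameters,
                                 temps: TemperaturePair | None = None, *,
                                 linker: str = DEFAULT_LINKER, theta: int = 3,
                                 conv: ModelConventions | None = None
                                 ) -> HybridizationEntropy:
    """Entropies of both strands and of the linker-concatenated complex.

    The single-strand terms are computed on the bare strands (without the
    linker); the complex is strand1 + linker + strand2.
    """
    temps = temps or TemperaturePair()
    h1 = entropy_dp(strand1, params, temps, theta=theta, conv=conv).entropy
    h2 = entropy_dp(strand2, params, temps, theta=theta, conv=conv).entropy
    chimera = NucleotideSequence(str(strand1) + linker + str(strand2))
    hc = entropy_dp(chimera, params, temps, theta=theta, conv=conv).entropy
    return HybridizationEntropy(h_strand1=h1, h_strand2=h2, h_complex=hc,
                                linker=linker, t_formal=temps.t_formal)
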