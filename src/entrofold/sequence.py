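"""RNA sequences and secondary structures.

A secondary structure is a set of base pairs ``(i, j)`` (0-based, ``i < j``)
that is triple-free and nested (no pseudoknots), with every hairpin loop
containing at least ``theta`` unpaired bases (``j - i > theta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

#: Base encoding shared by the whole package: N=0, A=1, C=2, G=3, U=4.
BASES = "NACGU"
BASE_CODE = {b: k for k, b in enumerate(BASES)}

#: Pair-type encoding: 0 = not pairable, then CG, GC, GU, UG, AU, UA.
PAIR_NAMES = ("", "CG", "GC", "GU", "UG", "AU", "UA")
PAIR_TYPE = np.zeros((5, 5), dtype=np.int8)
for _t, _p in enumerate(PAIR_NAMES):
    if _p:
        PAIR_TYPE[BASE_CODE[_p[0]], BASE_CODE[_p[1]]] = _t

#: Default minimum number of unpaired bases in a hairpin loop.
THETA = 3


class SequenceError(ValueError):
    """Raised for sequences containing characters outside {A,C,G,U,T}."""


class StructureError(ValueError):
    """Raised for base-pair sets that are not valid secondary structures."""


def can_pair(x: str, y: str) -> bool:
    """True exactly for the six Watson-Crick / wobble pairs (incl. GU)."""
    try:
        return bool(PAIR_TYPE[BASE_CODE[x.upper()], BASE_CODE[y.upper()]] != 0)
    except KeyError as exc:  # pragma: no cover - defensive
        raise SequenceError(f"not a nucleotide: {exc}") from None


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated RNA string over {A, C, G, U}.

    DNA input is accepted (T is normalized to U); case is folded. Any other
    character, including IUPAC ambiguity codes, is a hard error.
    """

    residues: str

    def __post_init__(self) -> None:
        raw = self.residues.upper().replace("T", "U")
        if not raw:
            raise SequenceError("empty sequence")
        for pos, ch in enumerate(raw):
            if ch not in "ACGU":
                raise SequenceError(
                    f"invalid character {ch!r} at position {pos + 1}"
                )
        object.__setattr__(self, "residues", raw)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, item):
        return self.residues[item]

    def encode(self) -> np.ndarray:
        """Integer encoding (A=1, C=2, G=3, U=4) as an int8 array."""
        return np.frombuffer(
            self.residues.encode().translate(_ENCODE_TABLE), dtype=np.int8
        ).copy()

    def __add__(self, other: "NucleotideSequence | str") -> "NucleotideSequence":
        return NucleotideSequence(self.residues + str(other))


_ENCODE_TABLE = bytes.maketrans(b"ACGU", bytes([1, 2, 3, 4]))


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested, triple-free set of base pairs on ``n`` positions (0-based)."""

    n: int
    pairs: frozenset = field(default_factory=frozenset)
    theta: int = THETA

    def __post_init__(self) -> None:
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        seen: set[int] = set()
        for i, j in pairs:
            if not (0 <= i < j < self.n):
                raise StructureError(f"pair ({i + 1}, {j + 1}) out of range")
            if j - i <= self.theta:
                raise StructureError(
                    f"hairpin of pair ({i + 1}, {j + 1}) below theta={self.theta}"
                )
            if i in seen or j in seen:
                raise StructureError(f"base triple at pair ({i + 1}, {j + 1})")
            seen.update((i, j))
        ordered = sorted(pairs)
        for a, (i, j) in enumerate(ordered):
            for k, l in ordered[a + 1 :]:
                if k >= j:
                    break
                if i < k < j < l:
                    raise StructureError(
                        f"pseudoknot between ({i + 1}, {j + 1}) and ({k + 1}, {l + 1})"
                    )

    @classmethod
    def from_dot_bracket(cls, db: str, theta: int = THETA) -> "SecondaryStructure":
        stack: list[int] = []
        pairs = set()
        for pos, ch in enumerate(db):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at position {pos + 1}")
                pairs.add((stack.pop(), pos))
            elif ch != ".":
                raise StructureError(f"invalid dot-bracket character {ch!r}")
        if stack:
            raise StructureError(f"unbalanced '(' at position {stack[-1] + 1}")
        return cls(n=len(db), pairs=frozenset(pairs), theta=theta)

    def dot_bracket(self) -> str:
        out = ["."] * self.n
        for i, j in self.pairs:
            out[i], out[j] = "(", ")"
        return "".join(out)

    def partner(self) -> np.ndarray:
        """Array ``p`` with ``p[i] = j`` if (i,j) or (j,i) paired, else -1."""
        p = np.full(self.n, -1, dtype=np.int64)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p

    def restriction(self, i: int, j: int) -> "SecondaryStructure":
        """Pairs fully contained in the closed interval [i, j] (0-based)."""
        sub = frozenset((x - i, y - i) for x, y in self.pairs if i <= x and y <= j)
        return SecondaryStructure(n=j - i + 1, pairs=sub, theta=self.theta)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.pairs))


def basepair_distance(s1: SecondaryStructure, s2: SecondaryStructure) -> int:
    """Number of pairs in the symmetric difference of two structures."""
    return len(s1.pairs ^ s2.pairs)
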