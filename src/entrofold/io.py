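"""Readers, writers and the random-sequence generator."""

from __future__ import annotations

import io as _io
import os
from typing import Iterable, TextIO

import numpy as np
from Bio import SeqIO

from .sequence import NucleotideSequence, SequenceError


class FastaError(ValueError):
    """Malformed FASTA input."""


def read_fasta(source: str | os.PathLike | TextIO
               ) -> list[tuple[str, NucleotideSequence]]:
    """Parse FASTA records into validated RNA sequences.

    Identifiers are kept verbatim; sequences are normalized (T -> U, case
    folded).  Records that are empty or contain characters outside
    {A,C,G,U,T} are hard errors naming the record.
    """
    if isinstance(source, (str, os.PathLike)):
        handle: TextIO = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        out = []
        for k, rec in enumerate(SeqIO.parse(handle, "fasta"), 1):
            raw = str(rec.seq)
            if not raw:
                raise FastaError(f"record {k} ({rec.id!r}) is empty")
            try:
                out.append((rec.id, NucleotideSequence(raw)))
            except SequenceError as exc:
                raise FastaError(f"record {k} ({rec.id!r}): {exc}") from None
        if not out:
            raise FastaError("no FASTA records found")
        return out
    finally:
        if close:
            handle.close()


def read_sequences(text_or_path: str) -> list[tuple[str, NucleotideSequence]]:
    """FASTA file path, or a raw sequence string as a single record."""
    if os.path.exists(text_or_path):
        return read_fasta(text_or_path)
    if text_or_path.lstrip().startswith(">"):
        return read_fasta(_io.StringIO(text_or_path))
    return [("seq1", NucleotideSequence(text_or_path.strip()))]


def random_rna(length: int, composition: Iterable[float] = (0.25,) * 4,
               rng: np.random.Generator | int | None = None
               ) -> NucleotideSequence:
    """I.i.d. random RNA with per-letter frequencies (A, C, G, U)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    comp = np.asarray(list(composition), dtype=float)
    if comp.shape != (4,) or comp.min() < 0 or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be 4 non-negative values summing to 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    letters = rng.choice(np.array(list("ACGU")), size=length, p=comp)
    return NucleotideSequence("".join(letters))


def write_tsv(handle: TextIO, header: list[str],
              rows: Iterable[Iterable]) -> None:
    """Plain TSV writer with fixed float formatting (6 decimals)."""
    handle.write("\t".join(header) + "\n")
    for row in rows:
        cells = []
        for v in row:
            if isinstance(v, float):
                cells.append(f"{v:.6f}")
            else:
                cells.append(str(v))
        handle.write("\t".join(cells) + "\n")
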