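"""Nearest-neighbor energy parameters and the Vienna parameter-file format.

The Turner model assigns free energies to *loops* (stacks, hairpins, bulges,
internal loops, multiloops), not to base pairs.  Parameter sets are read from
the standard Vienna ``.par`` layout (format v2.0), whose sections hold paired
free-energy (37 °C) and enthalpy tables in integer units of 0.01 kcal/mol.
All tables are kept internally in those integer units; kcal/mol floats appear
only at API boundaries.

Temperature dependence follows the two-parameter form used throughout the
nearest-neighbor literature: for a feature with free energy ``dG37`` at
310.15 K and enthalpy ``dH`` (assumed temperature-independent),

    dG(T) = dH - T * (dH - dG37) / 310.15

A toy Nussinov set (every pair contributes -1, all loop terms zero) is
constructed programmatically and shares the same interfaces.
"""

from __future__ import annotations

import logging
import math
import os
import sys
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path
from typing import Mapping

import numpy as np

log = logging.getLogger(__name__)

#: Gas constant in kcal/(mol*K); the value used by the Vienna package family.
GAS_CONSTANT = 1.98717e-3
#: Boltzmann constant in kcal/(mol*K) (per molecule: R / N_A).
BOLTZMANN_KCAL = GAS_CONSTANT / 6.02214076e23
#: 37 Celsius in Kelvin; the reference temperature of all printed tables.
T37 = 310.15
#: Zero Celsius in Kelvin.
K0 = 273.15
#: Sentinel for forbidden motifs, integer decacal convention.
INF = 10_000_000
#: Default cap on total unpaired bases in an internal loop.
MAX_LOOP = 30
#: Universal multiplier for length extrapolation of loops beyond 30 nt.
LXC37 = 107.856

_NB = 8  # pair-type axis size (0 unused, 1..6 pairs, 7 = NN row of the file)
_NBASE = 5  # N,A,C,G,U


class ParameterError(ValueError):
    """Malformed or unsupported parameter file."""


@dataclass(frozen=True)
class ModelConventions:
    """Evaluation conventions of the loop-energy function.

    ``au_*`` toggles control the loop contexts in which the terminal-AU
    penalty is charged.  ``STANDARD`` reproduces dangle-free (d0) RNAeval
    behavior of the Vienna 2.x lineage; ``CLASSIC`` reproduces the older
    evaluator style used by several entropy/partition-function codes, which
    charges the penalty on exterior stems and bulges but not on multiloop
    stems or triloop closing pairs.  Tabulated tetra/hexaloop motifs replace
    the generic hairpin energy entirely when enabled.
    """

    special_hairpins: bool = True
    au_hairpin3: bool = True
    au_bulge: bool = True
    au_multiloop: bool = True
    au_exterior: bool = True


STANDARD = ModelConventions()
CLASSIC = ModelConventions(au_hairpin3=False, au_multiloop=False)


@dataclass(frozen=True)
class _Pairs:
    """A (dG37, dH) pair of integer tables of identical shape."""

    g: np.ndarray
    h: np.ndarray

    def at(self, T: float, quantize: bool = True) -> np.ndarray:
        """Tables rescaled to temperature ``T`` (Kelvin).

        With ``quantize`` the result is truncated back onto the integer
        0.01 kcal/mol grid (the convention of the established folding
        engines, whose energies jump at particular temperatures); without
        it the exact linear rescaling is kept, which temperature profiles
        use to avoid quantization noise in derivatives.
        """
        if T == T37:
            return self.g
        g = self.g.astype(np.float64)
        h = self.h.astype(np.float64)
        out = h - (h - g) * (T / T37)
        if quantize:
            out = np.trunc(out).astype(np.int64)
        out[self.g >= INF] = INF
        return out


def _scalar(g: int, h: int, T: float, quantize: bool = True):
    if T == T37:
        return int(g)
    val = h - (h - g) * (T / T37)
    return int(math.trunc(val)) if quantize else val


@dataclass(frozen=True)
class EnergyParameters:
    """A complete nearest-neighbor parameter set.

    The raw 37 °C / enthalpy tables are immutable; `rescale_to_temperature`
    produces a sibling whose effective tables are evaluated at the requested
    *table temperature* ``T_table``.  Axes follow the package conventions:
    pair types 1..6 (CG, GC, GU, UG, AU, UA) and bases N,A,C,G,U = 0..4.
    """

    kind: str
    T_table: float
    # paired dG37/dH tables, integer decacal
    stack: _Pairs
    hairpin: _Pairs            # [31] by loop size
    bulge: _Pairs              # [31]
    internal: _Pairs           # [31]
    mismatch_hairpin: _Pairs   # [8,5,5]
    mismatch_internal: _Pairs
    mismatch_internal_1n: _Pairs
    mismatch_internal_23: _Pairs
    int11: _Pairs              # [8,8,5,5]
    int21: _Pairs              # [8,8,5,5,5]
    int22: _Pairs              # [8,8,5,5,5,5]
    ml_base: tuple             # (g, h): c, per unpaired base
    ml_closing: tuple          # a
    ml_intern: tuple           # b, per branch
    ninio: tuple               # (m_g, m_h, max)
    terminal_au: tuple
    duplex_init: tuple
    special_hairpins: Mapping[str, tuple] = field(default_factory=dict)
    pair_bonus: int = 0        # decacal per base pair (Nussinov: -100)
    max_loop: int = MAX_LOOP
    lxc37: float = LXC37
    conventions: ModelConventions = STANDARD
    quantize: bool = True      # keep rescaled tables on the 0.01 grid

    # -- derived, effective at T_table ------------------------------------
    def table(self, name: str) -> np.ndarray:
        """Effective table ``name`` at ``T_table`` (integer decacal when
        ``quantize`` is set, the default)."""
        return getattr(self, name).at(self.T_table, self.quantize)

    @property
    def a(self):
        """Multiloop closing offset (decacal) at T_table."""
        return _scalar(*self.ml_closing, self.T_table, self.quantize)

    @property
    def b(self):
        """Multiloop per-branch cost (decacal) at T_table."""
        return _scalar(*self.ml_intern, self.T_table, self.quantize)

    @property
    def c(self):
        """Multiloop per-unpaired-base cost (decacal) at T_table."""
        return _scalar(*self.ml_base, self.T_table, self.quantize)

    @property
    def terminal_au_penalty(self):
        return _scalar(*self.terminal_au, self.T_table, self.quantize)

    @property
    def ninio_m(self):
        return _scalar(self.ninio[0], self.ninio[1], self.T_table,
                       self.quantize)

    @property
    def ninio_max(self) -> int:
        return int(self.ninio[2])

    @property
    def lxc(self) -> float:
        return self.lxc37 * (self.T_table / T37)

    def special_hairpin_energy(self, motif: str):
        """Special tri/tetra/hexaloop energy at T_table, or None."""
        gh = self.special_hairpins.get(motif)
        if gh is None:
            return None
        return _scalar(gh[0], gh[1], self.T_table, self.quantize)


def rescale_to_temperature(params: EnergyParameters, T: float) -> EnergyParameters:
    """Parameter set whose tables are evaluated at table temperature ``T`` (K)."""
    if not T > 0:
        raise ValueError(f"temperature must be positive (Kelvin), got {T}")
    return _dc_replace(params, T_table=float(T))


# ---------------------------------------------------------------------------
# Vienna .par reader


def _tokens_of_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    in_comment = False
    for lineno, line in enumerate(text.splitlines(), 1):
        if in_comment:
            if "*/" in line:
                line = line.split("*/", 1)[1]
                in_comment = False
            else:
                continue
        while "/*" in line:
            head, rest = line.split("/*", 1)
            if "*/" in rest:
                line = head + rest.split("*/", 1)[1]
            else:
                line = head
                in_comment = True
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            continue
        if line.startswith("#"):
            name = line[1:].strip()
            current = sections.setdefault(name, [])
            continue
        if current is None:
            raise ParameterError(f"data before any section header at line {lineno}")
        current.extend(line.split())
    return sections


def _ints(tokens: list[str], section: str) -> np.ndarray:
    out = np.empty(len(tokens), dtype=np.int64)
    for k, t in enumerate(tokens):
        if t in ("INF", "inf"):
            out[k] = INF
        elif t in ("DEF", "@"):
            out[k] = -50
        else:
            try:
                out[k] = int(t)
            except ValueError:
                try:
                    out[k] = int(round(float(t)))
                except ValueError:
                    raise ParameterError(
                        f"non-numeric value {t!r} in section {section!r}"
                    ) from None
    return out


def _embed(flat: np.ndarray, file_shape: tuple, full_shape: tuple,
           pair_axes: int, section: str) -> np.ndarray:
    """Reshape file data and embed into the package's [8,...,5,...] layout.

    ``file_shape`` dims for pair axes are 6 or 7 (CG..UA[,NN]); base axes are
    4 (A..U) or 5 (N..U).  ``full_shape`` is the padded layout with pair axes
    of 8 and base axes of 5; missing entries stay at 0 except where noted.
    """
    if flat.size != int(np.prod(file_shape)):
        raise ParameterError(
            f"section {section!r}: expected {int(np.prod(file_shape))} values, "
            f"got {flat.size}"
        )
    src = flat.reshape(file_shape)
    out = np.zeros(full_shape, dtype=np.int64)
    index = []
    for k, (fs, os_) in enumerate(zip(file_shape, full_shape)):
        if k < pair_axes:
            index.append(slice(1, 1 + fs))
        else:
            index.append(slice(os_ - fs, os_))
    out[tuple(index)] = src
    return out


_SECTION_ALIASES = {
    "mismatch_interior": "mismatch_internal",
    "mismatch_interior_1n": "mismatch_internal_1n",
    "mismatch_interior_23": "mismatch_internal_23",
    "interior": "internal",
}


def load_parameter_file(path: str | os.PathLike) -> dict:
    """Parse a Vienna v2.0 parameter file into raw integer tables."""
    text = Path(path).read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    if not text.strip():
        raise ParameterError(f"{path}: empty parameter file")
    if "RNAfold parameter file v2.0" not in first:
        raise ParameterError(
            f"{path}: unsupported parameter dialect (expected v2.0 header)"
        )
    sections = _tokens_of_sections(text)
    sections = {_SECTION_ALIASES.get(k.replace(" ", "_"), k.replace(" ", "_")): v
                for k, v in sections.items()}

    def grab(name: str, file_shape: tuple, full_shape: tuple, pair_axes: int,
             required: bool = True) -> np.ndarray:
        tok = sections.get(name)
        if tok is None:
            if required:
                raise ParameterError(f"{path}: missing section {name!r}")
            log.warning("parameter file %s: missing optional section %r; "
                        "defaulting to zero penalty", path, name)
            return np.zeros(full_shape, dtype=np.int64)
        return _embed(_ints(tok, name), file_shape, full_shape, pair_axes, name)

    raw: dict = {}
    for sec, fshape, fullshape, paxes in [
        ("stack", (7, 7), (_NB, _NB), 2),
        ("mismatch_hairpin", (7, 5, 5), (_NB, _NBASE, _NBASE), 1),
        ("mismatch_internal", (7, 5, 5), (_NB, _NBASE, _NBASE), 1),
        ("mismatch_internal_1n", (7, 5, 5), (_NB, _NBASE, _NBASE), 1),
        ("mismatch_internal_23", (7, 5, 5), (_NB, _NBASE, _NBASE), 1),
        ("int11", (7, 7, 5, 5), (_NB, _NB, _NBASE, _NBASE), 2),
        ("int21", (7, 7, 5, 5, 5), (_NB, _NB, _NBASE, _NBASE, _NBASE), 2),
    ]:
        raw[sec] = grab(sec, fshape, fullshape, paxes)
        raw[sec + "_dH"] = grab(sec + "_enthalpies", fshape, fullshape, paxes,
                                required=False)

    # int22 is listed for the 6 true pairs and 4 true bases only
    n22 = len(sections.get("int22", []))
    f22 = (7, 7, 5, 5, 5, 5) if n22 == 7**2 * 5**4 else (6, 6, 4, 4, 4, 4)
    full22 = (_NB, _NB, _NBASE, _NBASE, _NBASE, _NBASE)
    raw["int22"] = grab("int22", f22, full22, 2)
    raw["int22_dH"] = grab("int22_enthalpies", f22, full22, 2, required=False)

    for sec in ("hairpin", "bulge", "internal"):
        tok = sections.get(sec)
        if tok is None:
            raise ParameterError(f"{path}: missing section {sec!r}")
        vals = _ints(tok, sec)
        if vals.size != MAX_LOOP + 1:
            raise ParameterError(f"{path}: section {sec!r} must have 31 entries")
        raw[sec] = vals
        dh = sections.get(sec + "_enthalpies")
        raw[sec + "_dH"] = (_ints(dh, sec) if dh is not None
                            else np.zeros(MAX_LOOP + 1, dtype=np.int64))

    ml = _ints(sections.get("ML_params", []), "ML_params")
    if ml.size != 6:
        raise ParameterError(f"{path}: ML_params must have 6 entries")
    raw["ml_base"] = (int(ml[0]), int(ml[1]))
    raw["ml_closing"] = (int(ml[2]), int(ml[3]))
    raw["ml_intern"] = (int(ml[4]), int(ml[5]))

    ninio = _ints(sections.get("NINIO", []), "NINIO")
    if ninio.size != 3:
        raise ParameterError(f"{path}: NINIO must have 3 entries")
    raw["ninio"] = (int(ninio[0]), int(ninio[1]), int(ninio[2]))

    misc = sections.get("Misc", [])
    mv = _ints(misc, "Misc")
    if mv.size < 4:
        raise ParameterError(f"{path}: Misc must have at least 4 entries")
    raw["duplex_init"] = (int(mv[0]), int(mv[1]))
    raw["terminal_au"] = (int(mv[2]), int(mv[3]))
    raw["lxc37"] = float(misc[4]) if mv.size >= 6 else LXC37

    special: dict[str, tuple] = {}
    for sec in ("Triloops", "Tetraloops", "Hexaloops"):
        tok = sections.get(sec, [])
        if len(tok) % 3 != 0:
            raise ParameterError(f"{path}: section {sec!r} rows must be "
                                 "'motif dG dH'")
        for k in range(0, len(tok), 3):
            motif = tok[k].upper().replace("T", "U")
            special[motif] = (int(tok[k + 1]), int(tok[k + 2]))
    raw["special_hairpins"] = special
    return raw


def _params_from_raw(raw: dict, kind: str) -> EnergyParameters:
    def pair(name: str) -> _Pairs:
        return _Pairs(raw[name], raw[name + "_dH"])

    return EnergyParameters(
        kind=kind,
        T_table=T37,
        stack=pair("stack"),
        hairpin=pair("hairpin"),
        bulge=pair("bulge"),
        internal=pair("internal"),
        mismatch_hairpin=pair("mismatch_hairpin"),
        mismatch_internal=pair("mismatch_internal"),
        mismatch_internal_1n=pair("mismatch_internal_1n"),
        mismatch_internal_23=pair("mismatch_internal_23"),
        int11=pair("int11"),
        int21=pair("int21"),
        int22=pair("int22"),
        ml_base=raw["ml_base"],
        ml_closing=raw["ml_closing"],
        ml_intern=raw["ml_intern"],
        ninio=raw["ninio"],
        terminal_au=raw["terminal_au"],
        duplex_init=raw["duplex_init"],
        special_hairpins=raw["special_hairpins"],
        lxc37=raw.get("lxc37", LXC37),
    )


# ---------------------------------------------------------------------------
# Bundled sets

_PARAM_FILES = {
    "turner2004": "rna_turner2004.par",
    "turner1999": "rna_turner1999.par",
}


def _candidate_dirs() -> list[Path]:
    dirs = []
    env = os.environ.get("ENTROFOLD_PARAM_DIR")
    if env:
        dirs.append(Path(env))
    dirs.append(Path(sys.prefix) / "share" / "ViennaRNA")
    dirs.append(Path("/usr/local/share/ViennaRNA"))
    dirs.append(Path("/usr/share/ViennaRNA"))
    return dirs


def locate_parameter_file(name: str) -> Path:
    """Find a named parameter file among the known installation directories."""
    fname = _PARAM_FILES.get(name)
    if fname is None:
        raise ParameterError(f"unknown bundled parameter set {name!r}")
    for d in _candidate_dirs():
        p = d / fname
        if p.is_file():
            return p
    raise ParameterError(
        f"cannot locate parameter file {fname!r}; set ENTROFOLD_PARAM_DIR "
        "to a directory containing Vienna .par files"
    )


def _nussinov() -> EnergyParameters:
    zero31 = np.zeros(MAX_LOOP + 1, dtype=np.int64)
    z = _Pairs(zero31, zero31)
    zmm = _Pairs(np.zeros((_NB, _NBASE, _NBASE), dtype=np.int64),
                 np.zeros((_NB, _NBASE, _NBASE), dtype=np.int64))
    zpp = _Pairs(np.zeros((_NB, _NB), dtype=np.int64),
                 np.zeros((_NB, _NB), dtype=np.int64))
    return EnergyParameters(
        kind="nussinov",
        T_table=T37,
        stack=zpp,
        hairpin=z, bulge=z, internal=z,
        mismatch_hairpin=zmm, mismatch_internal=zmm,
        mismatch_internal_1n=zmm, mismatch_internal_23=zmm,
        int11=_Pairs(np.zeros((_NB, _NB, _NBASE, _NBASE), dtype=np.int64),
                     np.zeros((_NB, _NB, _NBASE, _NBASE), dtype=np.int64)),
        int21=_Pairs(np.zeros((_NB, _NB, _NBASE, _NBASE, _NBASE), dtype=np.int64),
                     np.zeros((_NB, _NB, _NBASE, _NBASE, _NBASE), dtype=np.int64)),
        int22=_Pairs(
            np.zeros((_NB, _NB, _NBASE, _NBASE, _NBASE, _NBASE), dtype=np.int64),
            np.zeros((_NB, _NB, _NBASE, _NBASE, _NBASE, _NBASE), dtype=np.int64)),
        ml_base=(0, 0), ml_closing=(0, 0), ml_intern=(0, 0),
        ninio=(0, 0, 0),
        terminal_au=(0, 0), duplex_init=(0, 0),
        special_hairpins={},
        pair_bonus=-100,
        max_loop=10**9,
        lxc37=0.0,
    )


def zero_energy_like(params: EnergyParameters) -> EnergyParameters:
    """A parameter set in which every structure has energy exactly zero."""
    p = _nussinov()
    return _dc_replace(p, kind="zero", pair_bonus=0)


_CACHE: dict[str, EnergyParameters] = {}

#: Name of the parameter profile used by default throughout the package: the
#: Turner 2004 tables evaluated with the classic conventions under which the
#: published reference entropies were produced.
DEFAULT_SET = "turner2004-classic"


def load_parameters(source: str | os.PathLike = DEFAULT_SET) -> EnergyParameters:
    """Load a parameter set by bundled name or explicit .par path.

    Bundled names: ``turner2004``, ``turner1999`` (plain Vienna-d0 style),
    ``turner2004-classic`` (default), ``turner1999-classic`` (classic
    evaluator conventions, with the classic multiloop coefficients
    a = 3.4, b = 0.4, c = 0 kcal/mol), and ``nussinov``.
    """
    key = str(source)
    if key in _CACHE:
        return _CACHE[key]
    if key == "nussinov":
        params = _nussinov()
    elif key.endswith("-classic") and key[:-8] in _PARAM_FILES:
        plain = load_parameters(key[:-8])
        params = _dc_replace(plain, kind=key, conventions=CLASSIC,
                             ml_closing=(340, 0), ml_intern=(40, 0),
                             ml_base=(0, 0))
    elif key in _PARAM_FILES:
        params = _params_from_raw(load_parameter_file(locate_parameter_file(key)),
                                  kind=key)
    else:
        params = _params_from_raw(load_parameter_file(source), kind=str(source))
    _CACHE[key] = params
    return params
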