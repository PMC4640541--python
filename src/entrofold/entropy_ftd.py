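"""Structural entropy by the formal-temperature-derivative (FTD) method.

From statistical physics, ``<E> = R T^2 d(ln Z)/dT`` when structure energies
are treated as temperature-independent constants.  For the nearest-neighbor
model this holds only if the derivative is taken with respect to the *formal*
temperature (the T inside every RT) while the energy tables stay fixed at the
table temperature.  The derivative is approximated by finite differences

    uncentered:  <E> ~ RT^2 (ln Z(T+dT) - ln Z(T)) / dT
    centered:    <E> ~ RT^2 (ln Z(T+dT) - ln Z(T-dT)) / (2 dT)

``ln Z`` is strictly decreasing and concave-down in the formal temperature,
so the uncentered difference over-estimates |d ln Z / dT| and the resulting
entropy is a lower bound on the exact DP value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .energy import ModelConventions
from .entropy_dp import EnsembleSummary
from .params import EnergyParameters
from .partition import TemperaturePair, inside
from .sequence import NucleotideSequence

#: Default formal-temperature increments (Kelvin).
DEFAULT_DELTA_UNCENTERED = 1e-7
DEFAULT_DELTA_CENTERED = 1e-2


class PrecisionWarning(UserWarning):
    """The finite difference of ln Z is at the floating-point noise floor."""


@dataclass(frozen=True)
class FtdConfig:
    """Finite-difference configuration for the FTD entropy estimate."""

    delta: float | None = None
    scheme: str = "uncentered"
    temperatures: TemperaturePair = field(default_factory=TemperaturePair)
    strict: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in ("uncentered", "centered"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.delta is not None and not (0.0 < self.delta <= 0.1):
            raise ValueError("delta must lie in (0, 0.1] Kelvin")

    @property
    def effective_delta(self) -> float:
        if self.delta is not None:
            return self.delta
        return (DEFAULT_DELTA_UNCENTERED if self.scheme == "uncentered"
                else DEFAULT_DELTA_CENTERED)


def _log_z(seq, params, temps, theta, conv):
    return inside(seq, params, temps, theta=theta,
                  conv=conv).log_partition_function


def expected_energy_ftd(seq: NucleotideSequence, params: EnergyParameters,
                        config: FtdConfig | None = None, *, theta: int = 3,
                        conv: ModelConventions | None = None,
                        _return_lnz: bool = False):
    """Finite-difference estimate of <E> in kcal/mol.

    The energy tables are evaluated once at the table temperature; only the
    formal temperature inside RT is shifted.
    """
    config = config or FtdConfig()
    temps = config.temperatures
    dt = config.effective_delta
    lnz = _log_z(seq, params, temps, theta, conv)
    if config.scheme == "uncentered":
        lnz_hi = _log_z(seq, params, temps.shifted(dt), theta, conv)
        slope = (lnz_hi - lnz) / dt
        diff = lnz_hi - lnz
    else:
        lnz_hi = _log_z(seq, params, temps.shifted(dt), theta, conv)
        lnz_lo = _log_z(seq, params, temps.shifted(-dt), theta, conv)
        slope = (lnz_hi - lnz_lo) / (2.0 * dt)
        diff = lnz_hi - lnz_lo
    noise_floor = 64.0 * math.ulp(1.0) * max(abs(lnz), 1.0)
    if abs(diff) < noise_floor and lnz != 0.0:
        msg = (f"|delta ln Z| = {abs(diff):.3g} is below the precision floor "
               f"{noise_floor:.3g}; increase delta")
        if config.strict:
            raise ArithmeticError(msg)
        warnings.warn(msg, PrecisionWarning, stacklevel=2)
    e = config.temperatures.rt * config.temperatures.t_formal * slope
    if _return_lnz:
        return e, lnz
    return e


def entropy_ftd(seq: NucleotideSequence, params: EnergyParameters,
                config: FtdConfig | None = None, *, theta: int = 3,
                conv: ModelConventions | None = None) -> EnsembleSummary:
    """Structural entropy H = (<E> - G)/RT with <E> from finite differences."""
    config = config or FtdConfig()
    e, lnz = expected_energy_ftd(seq, params, config, theta=theta, conv=conv,
                                 _return_lnz=True)
    rt = config.temperatures.rt
    h = e / rt + lnz
    return EnsembleSummary(log_z=lnz, free_energy=-rt * lnz,
                           expected_energy=e, entropy=h,
                           temps=config.temperatures,
                           method=f"ftd-{config.scheme}")
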