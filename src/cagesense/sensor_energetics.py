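"""Adsorption energetics and gas-sensor response metrics.

Covers cohesive energy, counterpoise-corrected adsorption energy,
Arrhenius-type recovery time, Richardson-type electrical conductivity and
the dipole magnitude, plus the before/after deltas used to quantify a
sensor's electronic response to analyte binding.

Unit ledger
-----------
Total electronic energies enter in hartree and leave as kJ/mol
(1 hartree = 2625.4996394799 kJ/mol). The conductivity exponent supports
two conventions:

* ``physical``  — exponent = HLG / (2 k_B T) with k_B in eV/K. This is the
  dimensionally consistent Richardson-type form and the default.
* ``published`` — exponent = HLG (numeric value in eV) / (2 R T with R T
  expressed in kJ/mol, ~4.955 at 298 K). Dimensionally this mixes scales,
  but it is the convention that reproduces the conductivity tables of the
  doped-C60 acetone-sensor literature this package re-derives, so the
  reproduction pipeline selects it explicitly.

The recovery time tau = v0^-1 exp(|Eads| / R T) is implemented physically;
see docs/methods.md for why some published tau tables cannot be recovered
from it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .conceptual_dft import DescriptorSet
from .constants import (
    DEFAULT_ATTEMPT_FREQUENCY_HZ,
    DEFAULT_RICHARDSON_A,
    DEFAULT_TEMPERATURE_K,
    BOLTZMANN_EV_PER_K,
    GAS_CONSTANT_J_MOL_K,
    HARTREE_TO_KJ_MOL,
)
from .qc_io import SpeciesRecord

__all__ = [
    "AdsorptionSystem",
    "SensorConventions",
    "OverflowWarning",
    "cohesive_energy",
    "adsorption_energy",
    "recovery_time",
    "conductivity",
    "dipole_magnitude",
    "delta_metrics",
]

_MAX_EXPONENT = 700.0  # exp() overflow guard (float64 limit ~709)


class OverflowWarning(UserWarning):
    """Exponent too large; an infinite sentinel was returned."""


@dataclass(frozen=True)
class AdsorptionSystem:
    """Host + guest + complex with a counterpoise (BSSE) correction in kJ/mol."""

    host: SpeciesRecord
    guest: SpeciesRecord
    complex: SpeciesRecord
    bsse: float = 0.0

    def __post_init__(self) -> None:
        if self.bsse < 0:
            raise ValueError("BSSE correction must be >= 0 (it raises Eads)")


@dataclass(frozen=True)
class SensorConventions:
    """Conventions and constants for the sensor-response formulas."""

    sigma_mode: str = "physical"                    # or "published"
    temperature: float = DEFAULT_TEMPERATURE_K      # K
    richardson_a: float = DEFAULT_RICHARDSON_A      # A m^-2
    attempt_frequency: float = DEFAULT_ATTEMPT_FREQUENCY_HZ  # s^-1
    boltzmann_ev: float = BOLTZMANN_EV_PER_K        # eV/K
    gas_constant: float = GAS_CONSTANT_J_MOL_K      # J/(mol K)

    def __post_init__(self) -> None:
        if self.sigma_mode not in ("physical", "published"):
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.attempt_frequency <= 0:
            raise ValueError("attempt frequency must be positive")


DEFAULT_CONVENTIONS = SensorConventions()


def cohesive_energy(e_complex: float, e_individuals: list[float], n: int,
                    sign_mode: str = "published") -> float:
    """Cohesive energy per atom in kJ/mol.

    The literal finite-difference expression -(E_complex - sum E_i)/n gives
    a *positive* number for a bound system; stability plots in the sensing
    literature instead report the more-negative-is-more-stable convention.
    ``sign_mode="published"`` (default) returns -|literal|; ``"physical"``
    returns the literal value. Energies enter in hartree.
    """
    if n < 1:
        raise ValueError("atom count must be >= 1")
    if not e_individuals:
        raise ValueError("need at least one individual-fragment energy")
    if sign_mode not in ("published", "physical"):
        raise ValueError(f"unknown sign_mode {sign_mode!r}")
    literal = -(e_complex - sum(e_individuals)) / n * HARTREE_TO_KJ_MOL
    return -abs(literal) if sign_mode == "published" else literal


def adsorption_energy(system: AdsorptionSystem) -> float:
    """BSSE-corrected adsorption energy in kJ/mol.

    Eads = E_complex - (E_host + E_guest) + E_BSSE, with total energies in
    hartree and the counterpoise correction already in kJ/mol. Negative
    values denote favourable adsorption.
    """
    raw = (system.complex.total_energy
           - system.host.total_energy
           - system.guest.total_energy) * HARTREE_TO_KJ_MOL
    return raw + system.bsse


def recovery_time(e_ads: float, conventions: SensorConventions = DEFAULT_CONVENTIONS,
                  ) -> float:
    """Arrhenius desorption (recovery) time in seconds.

    tau = v0^-1 exp(-Eads / (R T)) with Eads in kJ/mol; for a favourably
    bound system (Eads < 0) the exponent is positive and tau grows with the
    binding strength. tau(0) = 1/v0 exactly. Exponents beyond the float64
    range return ``inf`` with an :class:`OverflowWarning`.
    """
    exponent = -e_ads * 1000.0 / (conventions.gas_constant * conventions.temperature)
    if exponent > _MAX_EXPONENT:
        warnings.warn("recovery-time exponent overflow; returning inf",
                      OverflowWarning, stacklevel=2)
        return math.inf
    return math.exp(exponent) / conventions.attempt_frequency


def conductivity(hlg: float, conventions: SensorConventions = DEFAULT_CONVENTIONS,
                 ) -> float:
    """Richardson-type electrical conductivity sigma = A T^{3/2} exp(-x).

    The exponent x follows ``conventions.sigma_mode`` (see module unit
    ledger). Result in A m^-2; strictly decreasing in the gap at fixed T.
    """
    if hlg < 0:
        raise ValueError("HOMO-LUMO gap must be >= 0")
    T = conventions.temperature
    prefactor = conventions.richardson_a * T ** 1.5
    if conventions.sigma_mode == "physical":
        x = hlg / (2.0 * conventions.boltzmann_ev * T)
    else:  # published
        rt_kj_mol = conventions.gas_constant * T / 1000.0
        x = hlg / (2.0 * rt_kj_mol)
    if x > _MAX_EXPONENT:
        return 0.0
    return prefactor * math.exp(-x)


def dipole_magnitude(mu_x: float, mu_y: float, mu_z: float) -> float:
    """Euclidean norm of the dipole vector, in Debye."""
    for c in (mu_x, mu_y, mu_z):
        if not math.isfinite(c):
            raise ValueError("dipole components must be finite")
    return math.hypot(mu_x, mu_y, mu_z)


def delta_metrics(before: tuple[DescriptorSet, float],
                  after: tuple[DescriptorSet, float]) -> tuple[float, float]:
    """Sensor response upon analyte binding: (delta HLG in eV, delta mu in D).

    Each argument is a ``(DescriptorSet, dipole magnitude)`` pair; the
    deltas are after - before.
    """
    (d_before, mu_before), (d_after, mu_after) = before, after
    return d_after.hlg - d_before.hlg, mu_after - mu_before
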