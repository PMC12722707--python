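"""Frontier-orbital reactivity descriptors and density-of-states curves.

The global conceptual-DFT descriptors are computed from the frontier
orbital energies alone (Koopmans-style finite-difference approximation):

    HLG    = |E_HOMO - E_LUMO|          HOMO-LUMO gap, eV
    eta    = (E_LUMO - E_HOMO) / 2      chemical hardness, eV
    mu     = (E_HOMO + E_LUMO) / 2      chemical potential, eV
    S      = 1 / (2 eta)                chemical softness, eV^-1
    dNmax  = -mu / eta                  maximum fractional charge transfer

Softness is implemented as the reciprocal 1/(2 eta) — the convention every
tabulated softness value in the doped-C60 literature this package
reproduces actually follows, even where the accompanying formula is
typeset as eta/2 (see docs/methods.md).

The charge-transfer descriptor ECT is the difference of two dNmax values;
its sign gives the net electron-flow direction between the two species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .qc_io import OrbitalLevel, SpeciesRecord

__all__ = [
    "DescriptorSet",
    "FrontierUndefinedError",
    "DegenerateFrontierWarning",
    "frontier",
    "descriptor_set",
    "ect",
    "dos_curve",
]


class FrontierUndefinedError(ValueError):
    """Spectrum has no occupied or no virtual level."""


class DegenerateFrontierWarning(UserWarning):
    """HOMO energy is not strictly below LUMO energy."""


@dataclass(frozen=True)
class DescriptorSet:
    """Global reactivity descriptors for one species (eV-based units)."""

    e_homo: float     # eV
    e_lumo: float     # eV
    hlg: float        # eV
    eta: float        # eV
    mu_chem: float    # eV
    s: float          # eV^-1
    dn_max: float     # dimensionless


def frontier(record: SpeciesRecord) -> tuple[float, float]:
    """Frontier orbital energies (E_HOMO, E_LUMO) in eV.

    Identification is by occupancy, not level index: the HOMO is the
    highest-energy level with occupancy > 0 and the LUMO the lowest-energy
    level with occupancy 0. A non-positive gap triggers a
    :class:`DegenerateFrontierWarning` instead of an error (degenerate or
    inverted frontiers occur in transcribed literature tables).
    """
    occ = record.occupied
    vir = record.virtual
    if not occ or not vir:
        raise FrontierUndefinedError(
            f"species {record.label!r} needs at least one occupied and one "
            "virtual level for frontier analysis")
    e_homo = max(l.energy for l in occ)
    e_lumo = min(l.energy for l in vir)
    if e_homo >= e_lumo:
        warnings.warn(f"degenerate/inverted frontier for {record.label!r}: "
                      f"E_HOMO={e_homo} >= E_LUMO={e_lumo}",
                      DegenerateFrontierWarning, stacklevel=2)
    return e_homo, e_lumo


def descriptor_set(e_homo: float, e_lumo: float) -> DescriptorSet:
    """Compute the full descriptor suite from the frontier energies (eV)."""
    if not (math.isfinite(e_homo) and math.isfinite(e_lumo)):
        raise ValueError("frontier energies must be finite")
    hlg = abs(e_homo - e_lumo)
    eta = (e_lumo - e_homo) / 2.0
    mu_chem = (e_homo + e_lumo) / 2.0
    if eta == 0.0:
        raise ValueError("zero hardness: softness and dNmax are undefined")
    s = 1.0 / (2.0 * eta)
    dn_max = -mu_chem / eta
    return DescriptorSet(e_homo=e_homo, e_lumo=e_lumo, hlg=hlg, eta=eta,
                         mu_chem=mu_chem, s=s, dn_max=dn_max)


def ect(dn_max_alpha: float, dn_max_beta: float) -> float:
    """Electrophilicity-based charge transfer: dNmax(alpha) - dNmax(beta).

    Antisymmetric under argument swap. ECT > 0 means species alpha is the
    stronger electron acceptor (net electron flow beta -> alpha).
    """
    if not (math.isfinite(dn_max_alpha) and math.isfinite(dn_max_beta)):
        raise ValueError("dNmax inputs must be finite")
    return dn_max_alpha - dn_max_beta


def dos_curve(levels: Sequence[OrbitalLevel], broadening: float = 0.25,
              e_min: float | None = None, e_max: float | None = None,
              step: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-broadened density of states sampled on a regular energy grid.

    Each level contributes a unit-area Gaussian of width ``broadening``
    (eV), so the numerical integral of the curve equals the number of
    levels. The default grid spans all levels plus five broadenings of
    margin on each side.

    Returns ``(energies, dos)`` arrays.
    """
    if not levels:
        raise ValueError("DOS requires at least one orbital level")
    if broadening <= 0:
        raise ValueError("broadening must be positive")
    energies = np.array([l.energy for l in levels], dtype=float)
    lo = (min(energies) - 5 * broadening) if e_min is None else e_min
    hi = (max(energies) + 5 * broadening) if e_max is None else e_max
    if hi <= lo:
        raise ValueError("empty energy grid")
    grid = np.arange(lo, hi + step / 2, step)
    norm = broadening * math.sqrt(2 * math.pi)
    dos = np.exp(-((grid[:, None] - energies[None, :]) ** 2)
                 / (2 * broadening ** 2)).sum(axis=1) / norm
    return grid, dos
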