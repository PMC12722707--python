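"""QTAIM bond-critical-point analysis and NBO perturbation energies.

At a bond critical point the total electron energy density is
Hb = G(r) + V(r). Its sign, together with the sign of the density
Laplacian, classifies the interaction (Rozas scheme):

    lap < 0, Hb < 0   strong       (quasi-covalent, shared electrons)
    lap < 0, Hb > 0   moderate     (predominantly electrostatic)
    lap > 0, Hb > 0   weak         (dispersive / closed-shell)
    lap > 0, Hb < 0   unclassified (outside the scheme; flagged)

The NBO stabilization from a donor orbital i into an acceptor j is the
standard second-order perturbative term E(2) = q F(i,j)^2 / (E_j - E_i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .constants import HARTREE_TO_KCAL_MOL, HARTREE_TO_KJ_MOL
from .qc_io import BCPRecord

__all__ = [
    "BondClass",
    "SIGN_TOLERANCE",
    "total_energy_density",
    "rozas_classify",
    "classify_record",
    "rank_by_rho",
    "e2_energy",
]

# |lap| or |Hb| below this (a.u.) is treated as a sign boundary
SIGN_TOLERANCE = 1e-10

_E2_UNITS = {"hartree": 1.0,
             "kcal/mol": HARTREE_TO_KCAL_MOL,
             "kj/mol": HARTREE_TO_KJ_MOL}


@dataclass(frozen=True)
class BondClass:
    """Rozas-style classification of one bond-critical-point interaction."""

    label: str           # strong | moderate | weak | unclassified
    hb: float            # a.u.
    lap: float           # a.u.
    boundary: bool = False


def total_energy_density(record: BCPRecord) -> float:
    """Total electron energy density Hb = G + V at the BCP, in a.u."""
    return record.g + record.v


def rozas_classify(lap: float, hb: float) -> BondClass:
    """Classify an interaction from the Laplacian and Hb signs.

    Values within ``SIGN_TOLERANCE`` of zero sit on a class boundary; the
    near-zero quantity is resolved so that the other, well-determined sign
    decides the class (near-zero lap counts as negative, near-zero Hb as
    positive), and the result is flagged ``boundary=True``. This keeps
    boundary cases out of the unclassified quadrant.
    """
    if not (math.isfinite(lap) and math.isfinite(hb)):
        raise ValueError("lap and Hb must be finite")
    boundary = abs(lap) < SIGN_TOLERANCE or abs(hb) < SIGN_TOLERANCE
    lap_neg = lap < 0 or abs(lap) < SIGN_TOLERANCE
    hb_neg = hb < 0 and not abs(hb) < SIGN_TOLERANCE
    if lap_neg and hb_neg:
        label = "strong"
    elif lap_neg:
        label = "moderate"
    elif not hb_neg:
        label = "weak"
    else:
        label = "unclassified"
    return BondClass(label=label, hb=hb, lap=lap, boundary=boundary)


def classify_record(record: BCPRecord) -> BondClass:
    """Hb and Rozas class for one parsed BCP row."""
    return rozas_classify(record.lap, total_energy_density(record))


def rank_by_rho(records: Sequence[BCPRecord]) -> list[BCPRecord]:
    """Records ordered by descending BCP density; stable for ties.

    Higher rho at the bond critical point marks the stronger, more
    localized contact.
    """
    if not records:
        raise ValueError("cannot rank an empty BCP list")
    return sorted(records, key=lambda r: -r.rho)


def e2_energy(q: float, f: float, delta_e: float,
              out_unit: str = "kcal/mol") -> float:
    """Second-order NBO stabilization E(2) = q F^2 / dE.

    q is the donor occupancy, F the Fock matrix element and dE the orbital
    energy difference, all in atomic units; the result is converted to
    ``out_unit`` ('hartree', 'kcal/mol' or 'kJ/mol'). Linear in q,
    quadratic in F, inverse in dE.
    """
    if not delta_e > 0:
        raise ValueError(f"orbital energy difference must be > 0, got {delta_e}")
    if not (0 < q <= 2):
        raise ValueError(f"donor occupancy must lie in (0, 2], got {q}")
    if f < 0:
        raise ValueError("Fock element must be >= 0")
    key = out_unit.lower()
    if key not in _E2_UNITS:
        raise ValueError(f"unknown output unit {out_unit!r}")
    return q * f * f / delta_e * _E2_UNITS[key]
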