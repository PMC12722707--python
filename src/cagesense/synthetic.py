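"""Synthetic inputs for every pipeline stage.

Real electronic-structure runs for these systems take hours and their raw
outputs are not redistributable; this module generates structurally
faithful stand-ins — species logs, adsorption systems, BCP tables and toy
geometries — with *controllable* target values, so the whole pipeline can
be exercised and its arithmetic verified by parameter recovery.

Design: quantities with downstream targets (frontier energies, adsorption
energy) are back-solved exactly rather than sampled-and-measured, so
recovery tests are exact to rounding; everything else is drawn from one
seeded generator per spec — no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import HARTREE_TO_KJ_MOL
from .qc_io import (
    BCPRecord,
    OrbitalLevel,
    SpeciesRecord,
    render_bcp_table,
    render_species_log,
)
from .sensor_energetics import AdsorptionSystem

__all__ = ["GeneratorSpec", "make_species", "make_adsorption_system",
           "make_bcp_table", "make_two_atom_geometry"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Controllable targets for one synthetic species / adsorption system."""

    seed: int = 0
    label: str = "synthetic"
    n_filler_levels: int = 10          # non-frontier orbitals on each side
    target_homo: float = -5.38         # eV
    target_lumo: float = -3.70         # eV
    target_eads: float = -35.81        # kJ/mol
    target_bsse: float = 0.0           # kJ/mol
    dipole_target: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise: float = 0.0                 # jitter scale for filler levels, eV

    def __post_init__(self) -> None:
        if not self.target_homo < self.target_lumo:
            raise ValueError("target HOMO must lie below target LUMO")
        if self.target_bsse < 0:
            raise ValueError("target BSSE must be >= 0")
        if self.n_filler_levels < 0:
            raise ValueError("filler level count must be >= 0")
        if self.noise < 0:
            raise ValueError("noise scale must be >= 0")


def _rng(spec: GeneratorSpec, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((spec.seed, salt))


def make_species(spec: GeneratorSpec) -> tuple[SpeciesRecord, str]:
    """A species whose frontier equals (target_homo, target_lumo) exactly.

    Filler levels are placed strictly outside the frontier window —
    occupied fillers below the HOMO, virtual fillers above the LUMO — at
    0.5 eV minimum offsets plus seeded jitter, so they can never usurp the
    frontier. Returns the record and its rendered log text; identical
    specs give byte-identical text.
    """
    rng = _rng(spec, salt=1)
    levels = [OrbitalLevel(spec.target_homo, 2), OrbitalLevel(spec.target_lumo, 0)]
    n = spec.n_filler_levels
    if n:
        below = spec.target_homo - 0.5 - np.sort(rng.uniform(0.0, 4.0, size=n))[::-1]
        above = spec.target_lumo + 0.5 + np.sort(rng.uniform(0.0, 4.0, size=n))
        if spec.noise:
            below = below - np.abs(rng.normal(0.0, spec.noise, size=n))
            above = above + np.abs(rng.normal(0.0, spec.noise, size=n))
        levels += [OrbitalLevel(float(e), 2) for e in below]
        levels += [OrbitalLevel(float(e), 0) for e in above]
    record = SpeciesRecord(
        label=spec.label,
        total_energy=float(np.round(rng.uniform(-2500.0, -100.0), 9)),
        levels=tuple(levels),
        dipole_vector=spec.dipole_target,
        bsse=spec.target_bsse if spec.target_bsse > 0 else None,
    )
    return record, render_species_log(record)


def make_adsorption_system(spec: GeneratorSpec) -> AdsorptionSystem:
    """An adsorption system whose Eads equals ``target_eads`` exactly.

    Host and guest are generated independently (salted sub-streams of the
    spec seed); the complex total energy is back-solved from
    Eads = (E_complex - E_host - E_guest) * 2625.4996... + BSSE, which the
    energetics stage then recovers to float precision.
    """
    host_spec = GeneratorSpec(seed=spec.seed, label=f"{spec.label}-host",
                              n_filler_levels=spec.n_filler_levels,
                              target_homo=spec.target_homo,
                              target_lumo=spec.target_lumo, noise=spec.noise)
    guest_spec = GeneratorSpec(seed=spec.seed + 1, label=f"{spec.label}-guest",
                               n_filler_levels=spec.n_filler_levels,
                               target_homo=spec.target_homo - 0.1,
                               target_lumo=spec.target_lumo + 0.1,
                               noise=spec.noise)
    host, _ = make_species(host_spec)
    guest, _ = make_species(guest_spec)
    e_complex = (host.total_energy + guest.total_energy
                 + (spec.target_eads - spec.target_bsse) / HARTREE_TO_KJ_MOL)
    complex_spec = GeneratorSpec(seed=spec.seed + 2, label=f"{spec.label}-complex",
                                 n_filler_levels=spec.n_filler_levels,
                                 target_homo=spec.target_homo + 0.2,
                                 target_lumo=spec.target_lumo - 0.05,
                                 dipole_target=spec.dipole_target,
                                 noise=spec.noise)
    complex_rec, _ = make_species(complex_spec)
    complex_rec = SpeciesRecord(
        label=complex_rec.label, total_energy=e_complex,
        levels=complex_rec.levels, dipole_vector=complex_rec.dipole_vector)
    return AdsorptionSystem(host=host, guest=guest, complex=complex_rec,
                            bsse=spec.target_bsse)


_CLASS_TEMPLATES = {
    # label -> (lap sign, hb sign)
    "strong": (-1.0, -1.0),
    "moderate": (-1.0, +1.0),
    "weak": (+1.0, +1.0),
    "unclassified": (+1.0, -1.0),
}


def make_bcp_table(classes: list[str], seed: int = 0) -> str:
    """CSV text of BCP rows, one per requested Rozas class.

    Each row is constructed so that (sign(lap), sign(Hb)) matches its
    requested class: rho and G are drawn positive, V is solved from the
    requested Hb, and the Laplacian magnitude is drawn with the requested
    sign. The unclassified quadrant may be requested and is labelled.
    """
    rng = np.random.default_rng((seed, 99))
    records = []
    for i, cls in enumerate(classes):
        if cls not in _CLASS_TEMPLATES:
            raise ValueError(f"unknown Rozas class {cls!r}")
        lap_sign, hb_sign = _CLASS_TEMPLATES[cls]
        rho = float(np.round(rng.uniform(0.005, 0.12), 6))
        g = float(np.round(rng.uniform(0.002, 0.2), 6))
        hb = hb_sign * float(np.round(rng.uniform(0.001, 0.25), 6))
        v = hb - g
        lap = lap_sign * float(np.round(rng.uniform(0.001, 0.15), 6))
        records.append(BCPRecord(pair_label=f"{cls}-{i}", rho=rho, g=g,
                                 v=round(v, 6), lap=lap))
    return render_bcp_table(records)


def make_two_atom_geometry(element: str = "H", separation: float = 3.0):
    """A symmetric homonuclear pair on the z axis, for NCI toy systems."""
    from .geometry import Geometry
    half = separation / 2.0
    return Geometry.from_arrays([element, element],
                                [(0.0, 0.0, -half), (0.0, 0.0, half)],
                                comment=f"{element}2 at {separation} Angstrom")
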