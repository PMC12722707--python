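"""Readers and writers for every external representation the pipeline touches.

The species "log" is a deliberately constrained, documented dialect (see
``docs/formats.md``) rather than a full quantum-chemistry output format:
named blocks, one value per line. Adapters for production logs can be
layered on top without touching the rest of the pipeline.

Canonical units after parsing: orbital energies eV, total energy hartree,
dipole Debye, BSSE kJ/mol, QTAIM and NBO quantities atomic units.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .constants import HARTREE_TO_EV, HARTREE_TO_KJ_MOL
from .geometry import Geometry

__all__ = [
    "OrbitalLevel",
    "SpeciesRecord",
    "BCPRecord",
    "NBOInteraction",
    "LogParseError",
    "QcIoWarning",
    "parse_species_log",
    "render_species_log",
    "parse_bcp_table",
    "render_bcp_table",
    "parse_nbo_table",
    "render_nbo_table",
]


class LogParseError(ValueError):
    """Structured parse failure; ``block`` names the offending section."""

    def __init__(self, message: str, block: str | None = None):
        super().__init__(message)
        self.block = block


class QcIoWarning(UserWarning):
    """Non-fatal anomaly in parsed data (rejected rows, odd occupancies)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class OrbitalLevel:
    """One molecular-orbital level: energy in eV and its electron occupancy."""

    energy: float
    occupancy: int

    def __post_init__(self) -> None:
        if self.occupancy not in (0, 1, 2):
            raise ValueError(f"occupancy must be 0, 1 or 2, got {self.occupancy}")
        if not math.isfinite(self.energy):
            raise ValueError("orbital energy must be finite")


@dataclass(frozen=True)
class SpeciesRecord:
    """A single chemical species as produced by one electronic-structure run.

    ``levels`` is kept sorted ascending in energy. ``bsse`` holds an optional
    counterpoise correction (kJ/mol) when the log carries one.
    """

    label: str
    total_energy: float                      # hartree
    levels: tuple[OrbitalLevel, ...]
    dipole_vector: tuple[float, float, float] = (0.0, 0.0, 0.0)
    geometry: Geometry | None = None
    bsse: float | None = None                # kJ/mol
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.total_energy):
            raise ValueError("total energy must be finite")
        object.__setattr__(self, "levels",
                           tuple(sorted(self.levels, key=lambda l: l.energy)))
        object.__setattr__(self, "dipole_vector",
                           tuple(float(c) for c in self.dipole_vector))

    @property
    def occupied(self) -> tuple[OrbitalLevel, ...]:
        return tuple(l for l in self.levels if l.occupancy > 0)

    @property
    def virtual(self) -> tuple[OrbitalLevel, ...]:
        return tuple(l for l in self.levels if l.occupancy == 0)

    def with_warning(self, tag: str) -> "SpeciesRecord":
        return replace(self, warnings=self.warnings + (tag,))


@dataclass(frozen=True)
class BCPRecord:
    """Bond-critical-point properties in atomic units.

    rho: electron density; g: (positive) kinetic energy density;
    v: potential energy density; lap: Laplacian of the density.
    """

    pair_label: str
    rho: float
    g: float
    v: float
    lap: float

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"BCP density must be positive, got {self.rho}")
        if self.g < 0:
            raise ValueError(f"kinetic energy density must be >= 0, got {self.g}")


_DONOR_TYPES = {"σ": "σ", "sigma": "σ", "π": "π", "pi": "π",
                "LP": "LP", "lp": "LP", "LP(1)": "LP", "LP(2)": "LP"}
_ACCEPTOR_TYPES = {"σ*": "σ*", "sigma*": "σ*", "π*": "π*", "pi*": "π*"}


@dataclass(frozen=True)
class NBOInteraction:
    """One donor->acceptor row of a second-order perturbation table.

    ``e2`` keeps the magnitude as printed, with the unit tag found in the
    source header carried verbatim in ``e2_unit`` (tables in the literature
    are not always labelled with the unit actually used).
    """

    donor: str
    donor_type: str          # σ, π or LP
    acceptor: str
    acceptor_type: str       # σ* or π*
    e2: float
    delta_e: float           # E(j) - E(i), a.u.
    f: float                 # Fock matrix element F(i,j), a.u.
    q: float = 2.0           # donor occupancy
    e2_unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.donor_type not in ("σ", "π", "LP"):
            raise ValueError(f"unknown donor orbital type {self.donor_type!r}")
        if self.acceptor_type not in ("σ*", "π*"):
            raise ValueError(f"unknown acceptor orbital type {self.acceptor_type!r}")
        if not self.delta_e > 0:
            raise ValueError(f"orbital energy difference must be > 0, got {self.delta_e}")
        if self.f < 0:
            raise ValueError("Fock element must be >= 0")
        if not (0 < self.q <= 2):
            raise ValueError(f"donor occupancy must lie in (0, 2], got {self.q}")


# ---------------------------------------------------------------------------
# species log dialect
# ---------------------------------------------------------------------------

_ENERGY_TO_EV = {"ev": 1.0, "hartree": HARTREE_TO_EV,
                 "kj/mol": HARTREE_TO_EV / HARTREE_TO_KJ_MOL}
_ENERGY_TO_HARTREE = {"hartree": 1.0, "ev": 1.0 / HARTREE_TO_EV,
                      "kj/mol": 1.0 / HARTREE_TO_KJ_MOL}


def _normalize(text: str) -> str:
    # Unicode minus (U+2212) and non-breaking spaces appear in transcribed tables
    return text.replace("−", "-").replace(" ", " ")


def _split_blocks(text: str) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    current: str | None = None
    for raw in _normalize(text).splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip().lower()
            if current in blocks:
                raise LogParseError(f"duplicate block [{current}]", block=current)
            blocks[current] = []
        elif current is None:
            raise LogParseError(f"content before first block: {line!r}")
        else:
            blocks[current].append(line)
    return blocks


def _block_unit(lines: list[str], default: str) -> tuple[str, list[str]]:
    unit = default
    body = []
    for line in lines:
        if line.lower().startswith("unit"):
            unit = line.split("=", 1)[1].strip().lower()
        else:
            body.append(line)
    return unit, body


def parse_species_log(text: str) -> SpeciesRecord:
    """Parse one species log into a :class:`SpeciesRecord`.

    Requires exactly one ``[species]``, ``[energy]``, ``[orbitals]`` and
    ``[dipole]`` block; ``[bsse]`` is optional. Orbital energies may be
    given in eV, hartree or kJ/mol and are converted to eV.
    """
    blocks = _split_blocks(text)
    for required in ("species", "energy", "orbitals", "dipole"):
        if required not in blocks:
            raise LogParseError(f"missing [{required}] block", block=required)

    label = ""
    for line in blocks["species"]:
        if line.lower().startswith("label"):
            label = line.split("=", 1)[1].strip()
    if not label:
        raise LogParseError("[species] block must set 'label'", block="species")

    unit, body = _block_unit(blocks["energy"], "hartree")
    if unit not in _ENERGY_TO_HARTREE or len(body) != 1:
        raise LogParseError("[energy] block needs a unit line and one value",
                            block="energy")
    total_energy = float(body[0]) * _ENERGY_TO_HARTREE[unit]

    unit, body = _block_unit(blocks["orbitals"], "ev")
    if unit not in _ENERGY_TO_EV:
        raise LogParseError(f"unknown orbital energy unit {unit!r}", block="orbitals")
    if not body:
        raise LogParseError("[orbitals] block is empty", block="orbitals")
    levels = []
    for line in body:
        parts = line.split()
        if len(parts) != 2:
            raise LogParseError(f"orbital line must be 'energy occupancy': {line!r}",
                                block="orbitals")
        levels.append(OrbitalLevel(float(parts[0]) * _ENERGY_TO_EV[unit],
                                   int(parts[1])))
    levels.sort(key=lambda l: l.energy)

    unit, body = _block_unit(blocks["dipole"], "debye")
    if unit != "debye" or len(body) != 1:
        raise LogParseError("[dipole] block needs one 'x y z' line in Debye",
                            block="dipole")
    comps = body[0].split()
    if len(comps) != 3:
        raise LogParseError("dipole line must have three components", block="dipole")
    dipole = tuple(float(c) for c in comps)

    bsse = None
    if "bsse" in blocks:
        unit, body = _block_unit(blocks["bsse"], "kj/mol")
        if unit != "kj/mol" or len(body) != 1:
            raise LogParseError("[bsse] block needs one value in kJ/mol", block="bsse")
        bsse = float(body[0])

    record = SpeciesRecord(label=label, total_energy=total_energy,
                           levels=tuple(levels), dipole_vector=dipole, bsse=bsse)
    occ = record.occupied
    vir = record.virtual
    if occ and vir and max(l.energy for l in occ) > min(l.energy for l in vir):
        record = record.with_warning("non-monotone-occupancy")
        warnings.warn("occupied level above a virtual level in "
                      f"{label!r}", QcIoWarning, stacklevel=2)
    return record


def render_species_log(record: SpeciesRecord) -> str:
    """Serialize a record to the log dialect; inverse of :func:`parse_species_log`."""
    out = io.StringIO()
    out.write(f"[species]\nlabel = {record.label}\n\n")
    out.write(f"[energy]\nunit = hartree\n{record.total_energy!r}\n\n")
    out.write("[orbitals]\nunit = eV\n")
    for level in record.levels:
        out.write(f"{level.energy!r} {level.occupancy}\n")
    dx, dy, dz = record.dipole_vector
    out.write(f"\n[dipole]\nunit = debye\n{dx!r} {dy!r} {dz!r}\n")
    if record.bsse is not None:
        out.write(f"\n[bsse]\nunit = kJ/mol\n{record.bsse!r}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# BCP tables (CSV)
# ---------------------------------------------------------------------------

_BCP_COLUMNS = ["pair_label", "rho", "g", "v", "lap"]


def parse_bcp_table(text: str) -> list[BCPRecord]:
    """Parse a five-column CSV of bond-critical-point properties (a.u.).

    Rows violating ``rho > 0`` are dropped with a :class:`QcIoWarning`
    diagnostic rather than aborting the whole table.
    """
    frame = pd.read_csv(io.StringIO(_normalize(text)), skipinitialspace=True,
                        float_precision="round_trip")
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in _BCP_COLUMNS if c not in frame.columns]
    if missing:
        raise LogParseError(f"BCP table missing column(s): {', '.join(missing)}",
                            block="bcp")
    records: list[BCPRecord] = []
    for _, row in frame.iterrows():
        try:
            records.append(BCPRecord(pair_label=str(row["pair_label"]),
                                     rho=float(row["rho"]), g=float(row["g"]),
                                     v=float(row["v"]), lap=float(row["lap"])))
        except ValueError as exc:
            warnings.warn(f"rejected BCP row {row['pair_label']!r}: {exc}",
                          QcIoWarning, stacklevel=2)
    return records


def render_bcp_table(records: Sequence[BCPRecord]) -> str:
    lines = [",".join(_BCP_COLUMNS)]
    for r in records:
        lines.append(f"{r.pair_label},{r.rho!r},{r.g!r},{r.v!r},{r.lap!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# NBO second-order perturbation tables (plain text)
# ---------------------------------------------------------------------------

def parse_nbo_table(text: str) -> list[NBOInteraction]:
    """Parse a whitespace-separated NBO perturbation table.

    Layout: a header line whose ``E2[...]`` token carries the energy unit
    tag verbatim, then one row per interaction:
    ``donor donor_type acceptor acceptor_type e2 delta_e f [q]``.
    Rows with a non-positive energy denominator are rejected with a warning
    (they would poison the downstream q*F^2/dE evaluation).
    """
    lines = [ln for ln in (_normalize(text)).splitlines()
             if ln.strip() and not ln.strip().startswith("#")]
    if not lines:
        return []
    header, *rows = lines
    unit = "kcal/mol"
    for token in header.split():
        if token.lower().startswith("e2[") and token.endswith("]"):
            unit = token[3:-1]
    records: list[NBOInteraction] = []
    for row in rows:
        parts = row.split()
        if len(parts) not in (7, 8):
            raise LogParseError(f"NBO row must have 7 or 8 fields: {row!r}",
                                block="nbo")
        donor, dtype_tok, acceptor, atype_tok = parts[:4]
        if dtype_tok not in _DONOR_TYPES:
            raise LogParseError(f"unknown orbital type token {dtype_tok!r}",
                                block="nbo")
        if atype_tok not in _ACCEPTOR_TYPES:
            raise LogParseError(f"unknown orbital type token {atype_tok!r}",
                                block="nbo")
        q = float(parts[7]) if len(parts) == 8 else 2.0
        try:
            records.append(NBOInteraction(
                donor=donor, donor_type=_DONOR_TYPES[dtype_tok],
                acceptor=acceptor, acceptor_type=_ACCEPTOR_TYPES[atype_tok],
                e2=float(parts[4]), delta_e=float(parts[5]), f=float(parts[6]),
                q=q, e2_unit=unit))
        except ValueError as exc:
            warnings.warn(f"rejected NBO row {donor}->{acceptor}: {exc}",
                          QcIoWarning, stacklevel=2)
    return records


def render_nbo_table(records: Sequence[NBOInteraction],
                     unit: str | None = None) -> str:
    unit = unit if unit is not None else (records[0].e2_unit if records else "kcal/mol")
    lines = [f"donor type acceptor type E2[{unit}] dE(a.u.) F(a.u.) q"]
    for r in records:
        lines.append(f"{r.donor} {r.donor_type} {r.acceptor} {r.acceptor_type} "
                     f"{r.e2!r} {r.delta_e!r} {r.f!r} {r.q!r}")
    return "\n".join(lines) + "\n"
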