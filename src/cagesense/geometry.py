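"""Cartesian molecular geometry: XYZ I/O, bond lengths and bond angles.

Molecular (non-periodic) systems only. Coordinates are in Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import KNOWN_ELEMENTS

__all__ = [
    "Atom",
    "Geometry",
    "DegenerateGeometryError",
    "bond_length",
    "bond_angle",
    "read_xyz",
    "write_xyz",
]


class DegenerateGeometryError(ValueError):
    """Raised when an angle is requested with a zero-length arm."""


@dataclass(frozen=True)
class Atom:
    element: str
    x: float
    y: float
    z: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Geometry:
    """An ordered list of atoms with Cartesian coordinates in Angstrom."""

    atoms: list[Atom] = field(default_factory=list)
    comment: str = ""

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinate on atom {a.element!r}")
            if a.element not in KNOWN_ELEMENTS:
                raise ValueError(f"unknown element symbol {a.element!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @classmethod
    def from_arrays(cls, elements: Sequence[str], positions: Iterable[Sequence[float]],
                    comment: str = "") -> "Geometry":
        atoms = [Atom(el, float(p[0]), float(p[1]), float(p[2]))
                 for el, p in zip(elements, positions, strict=True)]
        return cls(atoms=atoms, comment=comment)


def _vec(geom: Geometry, i: int, j: int) -> np.ndarray:
    atoms = geom.atoms
    return atoms[j].position - atoms[i].position


def bond_length(geom: Geometry, i: int, j: int) -> float:
    """Euclidean distance between atoms *i* and *j* in Angstrom.

    Symmetric in (i, j); raises ``IndexError`` for out-of-range indices and
    ``ValueError`` if i == j.
    """
    if i == j:
        raise ValueError("bond length requires two distinct atom indices")
    if not (0 <= i < len(geom)) or not (0 <= j < len(geom)):
        raise IndexError(f"atom index out of range for geometry of {len(geom)} atoms")
    return float(np.linalg.norm(_vec(geom, i, j)))


def bond_angle(geom: Geometry, i: int, j: int, k: int) -> float:
    """Angle i-j-k (vertex at *j*) in degrees, in [0, 180].

    Uses atan2(|u x v|, u.v), which is well conditioned near 0 and 180
    degrees where the acos formulation loses precision.
    """
    if len({i, j, k}) != 3:
        raise ValueError("bond angle requires three distinct atom indices")
    for idx in (i, j, k):
        if not (0 <= idx < len(geom)):
            raise IndexError(f"atom index {idx} out of range")
    u = _vec(geom, j, i)
    v = _vec(geom, j, k)
    if np.linalg.norm(u) == 0.0 or np.linalg.norm(v) == 0.0:
        raise DegenerateGeometryError("angle arm has zero length")
    cross = float(np.linalg.norm(np.cross(u, v)))
    dot = float(np.dot(u, v))
    return math.degrees(math.atan2(cross, dot))


def read_xyz(source: str | Path) -> Geometry:
    """Read a standard XYZ file (atom count, comment, ``El x y z`` rows)."""
    text = Path(source).read_text() if isinstance(source, Path) else source
    if isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    lines = text.splitlines()
    if len(lines) < 2:
        raise ValueError("XYZ input too short")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise ValueError("first XYZ line must be the atom count") from exc
    comment = lines[1].rstrip()
    atoms = []
    for line in lines[2:2 + n]:
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"malformed XYZ atom line: {line!r}")
        atoms.append(Atom(parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
    if len(atoms) != n:
        raise ValueError(f"XYZ declares {n} atoms but {len(atoms)} parsed")
    return Geometry(atoms=atoms, comment=comment)


def write_xyz(geom: Geometry) -> str:
    lines = [str(len(geom)), geom.comment]
    for a in geom.atoms:
        lines.append(f"{a.element:<2s} {a.x:18.10f} {a.y:18.10f} {a.z:18.10f}")
    return "\n".join(lines) + "\n"
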