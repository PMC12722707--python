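"""Promolecular non-covalent-interaction (NCI) engine.

Builds an approximate molecular electron density as a sum of spherically
averaged, exponentially decaying atomic densities (a "promolecular"
density — no SCF required), evaluates its gradient and Hessian
analytically, and derives the two NCI observables:

* the reduced density gradient RDG = |grad rho| / (2 (3 pi^2)^{1/3} rho^{4/3})
* sign(lambda_2) * rho, where lambda_2 is the middle eigenvalue of the
  density Hessian — negative in attractive contacts, positive in
  repulsive (ring/cage) regions.

Low-RDG, low-density points mark non-covalent interactions; scatter plots
of RDG against sign(lambda_2) rho are the standard visualization.

Atomic densities are three-term exponential fits
rho_el(d) = sum_k c_k exp(-d / zeta_k) (d in bohr, density in a.u.) of
spherically averaged free-atom densities, of the form commonly used by
promolecular NCI codes; the parameters are tabulated below for the
elements this package targets (H, B, C, N, O, Si).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM
from .geometry import Geometry

__all__ = [
    "ATOMIC_DENSITY_PARAMS",
    "GridField",
    "promolecular_density",
    "density_at",
    "rdg",
    "sign_lambda2_rho",
    "nci_scatter",
    "write_cube",
]

# (c_k, zeta_k) pairs per element; d in bohr, contributions in a.u.
ATOMIC_DENSITY_PARAMS: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((0.2815, 0.5288),),
    "B": ((67.82, 0.1059), (0.8527, 0.5300)),
    "C": ((120.2, 0.0884), (1.172, 0.4532)),
    "N": ((190.9, 0.0767), (2.247, 0.3974)),
    "O": ((289.5, 0.0669), (2.879, 0.3994)),
    "Si": ((2271.0, 0.0333), (9.119, 0.3025), (0.7188, 1.6502)),
}

_RDG_PREFACTOR = 2.0 * (3.0 * math.pi ** 2) ** (1.0 / 3.0)


@dataclass
class GridField:
    """Promolecular density and derived fields on a regular 3-D grid.

    ``origin`` (Angstrom), scalar ``spacing`` (Angstrom) and ``shape``
    define the grid; ``rho`` (a.u.), ``grad_norm`` (a.u.) and ``lambda2``
    (a.u.) are arrays of that shape. ``elements``/``positions`` keep the
    generating geometry for cube output.
    """

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    rho: np.ndarray
    grad_norm: np.ndarray
    lambda2: np.ndarray
    elements: list[str]
    positions: np.ndarray  # Angstrom

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    def points(self) -> np.ndarray:
        """(N, 3) Cartesian coordinates of all grid points, Angstrom."""
        axes = [self.origin[d] + self.spacing * np.arange(self.shape[d])
                for d in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def _atomic_terms(element: str) -> np.ndarray:
    try:
        return np.array(ATOMIC_DENSITY_PARAMS[element], dtype=float)
    except KeyError:
        raise ValueError(
            f"no atomic density model for element {element!r}; "
            f"available: {sorted(ATOMIC_DENSITY_PARAMS)}") from None


def density_at(geom: Geometry, points: np.ndarray,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Promolecular rho, gradient and Hessian at arbitrary points.

    ``points`` is (N, 3) in Angstrom; returns ``rho`` (N,), ``grad``
    (N, 3) and ``hess`` (N, 3, 3), all in atomic units (lengths internally
    in bohr). For a spherical atomic term f(d), the gradient is f'(d) u and
    the Hessian f''(d) u u^T + (f'(d)/d) (I - u u^T) with u the unit
    displacement vector; the promolecular fields are sums over atoms.
    """
    if len(geom) == 0:
        raise ValueError("geometry has no atoms")
    pts = np.asarray(points, dtype=float) * ANGSTROM_TO_BOHR
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array")
    n = pts.shape[0]
    rho = np.zeros(n)
    grad = np.zeros((n, 3))
    hess = np.zeros((n, 3, 3))
    eye = np.eye(3)
    for atom in geom.atoms:
        terms = _atomic_terms(atom.element)
        delta = pts - atom.position * ANGSTROM_TO_BOHR   # (n, 3), bohr
        d = np.linalg.norm(delta, axis=1)
        d = np.maximum(d, 1e-12)                          # guard on-nucleus points
        u = delta / d[:, None]
        f = np.zeros(n)
        fp = np.zeros(n)
        fpp = np.zeros(n)
        for c, zeta in terms:
            e = c * np.exp(-d / zeta)
            f += e
            fp += -e / zeta
            fpp += e / zeta ** 2
        rho += f
        grad += fp[:, None] * u
        uut = u[:, :, None] * u[:, None, :]
        hess += fpp[:, None, None] * uut \
            + (fp / d)[:, None, None] * (eye[None, :, :] - uut)
    return rho, grad, hess


def promolecular_density(geom: Geometry, spacing: float = 0.1,
                         padding: float = 2.0,
                         origin: Sequence[float] | None = None,
                         shape: Sequence[int] | None = None) -> GridField:
    """Evaluate the promolecular density and NCI fields on a regular grid.

    By default the grid is a bounding box around the atoms extended by
    ``padding`` (Angstrom, >= 2 recommended) on every side. An explicit
    ``origin``/``shape`` pair is validated to cover all atoms.
    """
    if len(geom) == 0:
        raise ValueError("geometry has no atoms")
    pos = geom.positions
    if origin is None or shape is None:
        lo = pos.min(axis=0) - padding
        hi = pos.max(axis=0) + padding
        origin_arr = lo
        shape_t = tuple(int(math.ceil((hi[d] - lo[d]) / spacing)) + 1
                        for d in range(3))
    else:
        origin_arr = np.asarray(origin, dtype=float)
        shape_t = tuple(int(s) for s in shape)
        upper = origin_arr + spacing * (np.array(shape_t) - 1)
        if (pos < origin_arr).any() or (pos > upper).any():
            raise ValueError("grid does not cover all atoms")

    field = GridField(origin=np.asarray(origin_arr, dtype=float),
                      spacing=float(spacing), shape=shape_t,
                      rho=np.empty(shape_t), grad_norm=np.empty(shape_t),
                      lambda2=np.empty(shape_t),
                      elements=geom.elements, positions=pos)
    pts = field.points()
    rho, grad, hess = density_at(geom, pts)
    lam = np.linalg.eigvalsh(hess)          # ascending eigenvalues
    field.rho = rho.reshape(shape_t)
    field.grad_norm = np.linalg.norm(grad, axis=1).reshape(shape_t)
    field.lambda2 = lam[:, 1].reshape(shape_t)
    return field


def rdg(rho: np.ndarray | float, grad_norm: np.ndarray | float,
        ) -> np.ndarray | float:
    """Reduced density gradient s = |grad rho| / (2 (3 pi^2)^{1/3} rho^{4/3})."""
    rho_arr = np.asarray(rho, dtype=float)
    if (rho_arr <= 0).any():
        raise ValueError("RDG requires strictly positive density")
    out = np.asarray(grad_norm, dtype=float) / (_RDG_PREFACTOR * rho_arr ** (4.0 / 3.0))
    return float(out) if np.isscalar(rho) or rho_arr.ndim == 0 else out


def sign_lambda2_rho(field: GridField) -> np.ndarray:
    """Per-sample sign(lambda_2) * rho; negative marks attractive regions."""
    return np.sign(field.lambda2) * field.rho


def nci_scatter(field: GridField, rho_cutoff: float = 0.05,
                rdg_cutoff: float = 2.0) -> np.ndarray:
    """(sign(lambda_2) rho, RDG) pairs for the low-density NCI region.

    Keeps samples with rho < rho_cutoff and RDG < rdg_cutoff; returns an
    (N, 2) array (possibly empty).
    """
    if rho_cutoff < 0 or rdg_cutoff < 0:
        raise ValueError("cutoffs must be non-negative")
    rho = field.rho.ravel()
    s = rdg(np.maximum(rho, 1e-300), field.grad_norm.ravel())
    signed = (np.sign(field.lambda2) * field.rho).ravel()
    mask = (rho < rho_cutoff) & (s < rdg_cutoff)
    return np.stack([signed[mask], np.asarray(s)[mask]], axis=1)


def write_cube(field: GridField, which: str = "rho") -> str:
    """Serialize one field array to Gaussian cube format (text).

    Lengths are written in bohr as the format requires; ``which`` selects
    'rho', 'grad_norm' or 'lambda2'.
    """
    data = getattr(field, which, None)
    if data is None or which not in ("rho", "grad_norm", "lambda2"):
        raise ValueError(f"unknown field {which!r}")
    _Z = {"H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "Si": 14}
    nx, ny, nz = field.shape
    sp = field.spacing * ANGSTROM_TO_BOHR
    o = field.origin * ANGSTROM_TO_BOHR
    lines = [f"cagesense promolecular {which}",
             "generated on a regular grid (a.u.)",
             f"{len(field.elements):5d} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}",
             f"{nx:5d} {sp:12.6f} {0.0:12.6f} {0.0:12.6f}",
             f"{ny:5d} {0.0:12.6f} {sp:12.6f} {0.0:12.6f}",
             f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {sp:12.6f}"]
    for el, p in zip(field.elements, field.positions):
        z = _Z.get(el, 0)
        pb = np.asarray(p) * ANGSTROM_TO_BOHR
        lines.append(f"{z:5d} {float(z):12.6f} {pb[0]:12.6f} {pb[1]:12.6f} {pb[2]:12.6f}")
    flat = data.ravel()
    for i in range(0, flat.size, 6):
        lines.append(" ".join(f"{v:13.5e}" for v in flat[i:i + 6]))
    return "\n".join(lines) + "\n"
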