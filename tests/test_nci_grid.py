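"""Promolecular density engine: analytic derivatives vs finite differences,
RDG identities and NCI scatter behaviour."""

import math

import numpy as np
import pytest

from cagesense.constants import ANGSTROM_TO_BOHR
from cagesense.geometry import Geometry
from cagesense.nci_grid import (
    ATOMIC_DENSITY_PARAMS,
    density_at,
    nci_scatter,
    promolecular_density,
    rdg,
    sign_lambda2_rho,
    write_cube,
)
from cagesense.synthetic import make_two_atom_geometry


def atomic_rho(element, d_bohr):
    """Independent closed-form evaluation of the tabulated atomic model."""
    return sum(c * math.exp(-d_bohr / zeta)
               for c, zeta in ATOMIC_DENSITY_PARAMS[element])


class TestPromolecularDensity:
    def test_single_atom_density_decays_along_a_ray(self):
        geom = Geometry.from_arrays(["C"], [(0.0, 0.0, 0.0)])
        radii = np.linspace(0.3, 4.0, 25)
        pts = np.stack([radii, radii, radii], axis=1) / math.sqrt(3)
        rho, _, _ = density_at(geom, pts)
        assert (np.diff(rho) < 0).all()

    def test_two_identical_atoms_symmetric_about_midplane(self):
        geom = make_two_atom_geometry("H", separation=3.0)
        pts = np.array([[0.2, -0.4, 0.9], [0.2, -0.4, -0.9]])
        rho, _, _ = density_at(geom, pts)
        assert rho[0] == pytest.approx(rho[1], rel=1e-12)

    def test_midpoint_of_h_pair_is_twice_single_atom_value(self):
        geom = make_two_atom_geometry("H", separation=3.0)
        rho, _, _ = density_at(geom, np.array([[0.0, 0.0, 0.0]]))
        expected = 2.0 * atomic_rho("H", 1.5 * ANGSTROM_TO_BOHR)
        assert rho[0] == pytest.approx(expected, rel=1e-12)

    def test_analytic_gradient_and_hessian_match_finite_differences(self, rng):
        """Central-difference oracle agreement to 1e-6 a.u. at random points."""
        geom = Geometry.from_arrays(["C", "O", "H"],
                                    [(0, 0, 0), (1.2, 0, 0.3), (-0.8, 0.9, 0)])
        pts = rng.uniform(-2.5, 2.5, size=(20, 3))
        # keep points off the nuclei where the model has a cusp
        for a in geom.positions:
            d = np.linalg.norm(pts - a, axis=1)
            pts = pts[d > 0.5]
        rho, grad, hess = density_at(geom, pts)
        h = 1e-4  # Angstrom
        for axis in range(3):
            step = np.zeros(3)
            step[axis] = h
            rp, gp, _ = density_at(geom, pts + step)
            rm, gm, _ = density_at(geom, pts - step)
            fd_grad = (rp - rm) / (2 * h * ANGSTROM_TO_BOHR)
            assert np.allclose(grad[:, axis], fd_grad, atol=1e-6)
            fd_hess_col = (gp - gm) / (2 * h * ANGSTROM_TO_BOHR)
            assert np.allclose(hess[:, :, axis], fd_hess_col, atol=1e-6)

    def test_explicit_grid_must_cover_atoms(self):
        geom = make_two_atom_geometry("H", separation=4.0)
        with pytest.raises(ValueError, match="cover"):
            promolecular_density(geom, spacing=0.5, origin=(-1, -1, -1),
                                 shape=(5, 5, 5))

    def test_unknown_element_has_no_model(self):
        geom = Geometry.from_arrays(["F"], [(0, 0, 0)])
        with pytest.raises(ValueError, match="'F'"):
            density_at(geom, np.zeros((1, 3)))


class TestRDG:
    def test_uniform_density_gives_zero(self):
        assert rdg(0.02, 0.0) == 0.0

    def test_closed_form_for_exponential_density_at_origin(self):
        # rho = exp(-2r): |grad| = 2 at r -> 0, rho = 1
        expected = 2.0 / (2.0 * (3.0 * math.pi ** 2) ** (1.0 / 3.0))
        assert rdg(1.0, 2.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.3232, abs=5e-4)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            rdg(0.0, 1.0)

    def test_consistent_with_field_arrays(self):
        geom = make_two_atom_geometry("H", separation=2.0)
        field = promolecular_density(geom, spacing=0.4)
        s = rdg(field.rho, field.grad_norm)
        assert s.shape == field.rho.shape
        assert (s >= 0).all()


class TestSignLambda2AndScatter:
    def test_signed_density_signs_follow_lambda2(self):
        geom = make_two_atom_geometry("H", separation=2.5)
        field = promolecular_density(geom, spacing=0.4)
        signed = sign_lambda2_rho(field)
        assert np.all(signed[field.lambda2 < 0] < 0)
        assert np.all(signed[field.lambda2 > 0] > 0)

    def test_hessian_eigenvalues_match_finite_difference_eigenvalues(self, rng):
        geom = Geometry.from_arrays(["N"], [(0.0, 0.0, 0.0)])
        pts = rng.uniform(0.6, 1.8, size=(5, 3))
        _, _, hess = density_at(geom, pts)
        h = 1e-4
        for k, p in enumerate(pts):
            fd = np.zeros((3, 3))
            for a in range(3):
                sa = np.zeros(3)
                sa[a] = h
                _, gp, _ = density_at(geom, (p + sa)[None, :])
                _, gm, _ = density_at(geom, (p - sa)[None, :])
                fd[:, a] = (gp[0] - gm[0]) / (2 * h * ANGSTROM_TO_BOHR)
            lam_a = np.linalg.eigvalsh(hess[k])
            lam_fd = np.linalg.eigvalsh(0.5 * (fd + fd.T))
            assert np.allclose(lam_a, lam_fd, atol=1e-6)

    def test_infinite_cutoffs_keep_every_grid_point(self):
        geom = make_two_atom_geometry("H", separation=2.0)
        field = promolecular_density(geom, spacing=0.5)
        pairs = nci_scatter(field, rho_cutoff=math.inf, rdg_cutoff=math.inf)
        assert len(pairs) == field.rho.size

    def test_zero_rho_cutoff_keeps_nothing(self):
        geom = make_two_atom_geometry("H", separation=2.0)
        field = promolecular_density(geom, spacing=0.5)
        assert len(nci_scatter(field, rho_cutoff=0.0)) == 0

    def test_bonding_contact_appears_only_at_short_separation(self):
        """A low-RDG attractive spike exists at bonding range, not at 10 A.

        The RDG cutoff is kept tight (0.3): every isolated atom is wrapped
        in its own negative-lambda2 envelope at moderate RDG, so only the
        near-zero-RDG internuclear spike distinguishes an actual contact.
        """
        def min_signed(separation):
            geom = make_two_atom_geometry("H", separation)
            field = promolecular_density(geom, spacing=0.25, padding=2.0)
            pairs = nci_scatter(field, rho_cutoff=0.05, rdg_cutoff=0.3)
            attractive = pairs[pairs[:, 0] < 0]
            return attractive[:, 0].min() if len(attractive) else 0.0

        near = min_signed(2.0)
        far = min_signed(10.0)
        assert near < -1e-3
        assert abs(far) < abs(near) / 10

    def test_attraction_strengthens_monotonically_on_approach(self):
        def peak(separation):
            geom = make_two_atom_geometry("H", separation)
            field = promolecular_density(geom, spacing=0.25, padding=2.0)
            pairs = nci_scatter(field, rho_cutoff=0.05, rdg_cutoff=0.3)
            return pairs[:, 0].min()

        peaks = [peak(s) for s in (4.0, 3.0, 2.0)]
        assert peaks[0] > peaks[1] > peaks[2]


def test_cube_output_is_well_formed():
    geom = make_two_atom_geometry("H", separation=2.0)
    field = promolecular_density(geom, spacing=0.5)
    text = write_cube(field, "rho")
    lines = text.splitlines()
    assert int(lines[2].split()[0]) == 2            # atom count
    nx = int(lines[3].split()[0])
    assert nx == field.shape[0]
    n_values = sum(len(l.split()) for l in lines[8:])
    assert n_values == field.rho.size
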