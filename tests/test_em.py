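"""Electrical solve: closed-form oracles, conservation, symmetry audits."""

import math

import numpy as np
import pytest

from airwayrf import em
from airwayrf.fem import tet_geometry
from airwayrf.geometry import (
    Boundary,
    DeviceGeometry,
    Subdomain,
    build_annulus_mesh,
    build_bipolar_audit_mesh,
    build_box_mesh,
    build_mirror_audit_mesh,
)
from airwayrf.materials import MaterialTable

from conftest import sigma_for


def _uniform(mesh, sigma):
    return np.full(mesh.num_elements, sigma)


@pytest.fixture(scope="module")
def slab():
    mesh = build_box_mesh(4e-3, 2e-3, 3e-3, 5, 4, 3)
    field = em.solve_potential(mesh, _uniform(mesh, 0.359), 2.0)
    return mesh, field


@pytest.fixture(scope="module")
def sector_current_value(sector_mesh):
    field = em.solve_potential(sector_mesh, sigma_for(sector_mesh), 10.0)
    return em.sector_current(sector_mesh, field)


class TestSlab:
    """Uniform slab between opposite Dirichlet faces: 1-D closed form."""

    lx, ly, lz, sigma = 4e-3, 2e-3, 3e-3, 0.359

    def test_linear_potential_is_exact(self, slab):
        mesh, field = slab
        exact = 2.0 * (1.0 - mesh.nodes[:, 0] / self.lx)
        assert np.allclose(field.V, exact, atol=1e-10)

    def test_resistance_matches_L_over_sigma_A(self, slab):
        mesh, field = slab
        I = em.sector_current(mesh, field)
        R = self.lx / (self.sigma * self.ly * self.lz)
        assert 2.0 / I == pytest.approx(R, rel=1e-10)

    def test_uniform_joule_density(self, slab):
        mesh, field = slab
        q = em.joule_power_density(mesh, field, _uniform(mesh, self.sigma))
        E = 2.0 / self.lx
        assert np.allclose(q, self.sigma * E * E, rtol=1e-9)

    def test_joule_density_linear_in_sigma(self, slab):
        mesh, field = slab
        q1 = em.joule_power_density(mesh, field, _uniform(mesh, self.sigma))
        q2 = em.joule_power_density(mesh, field, _uniform(mesh, 2 * self.sigma))
        assert np.allclose(q2, 2.0 * q1, rtol=1e-12)

    def test_zero_drive_gives_zero_field_and_current(self, slab):
        mesh, _ = slab
        field = em.solve_potential(mesh, _uniform(mesh, self.sigma), 0.0)
        assert np.all(field.V == 0.0)
        assert em.sector_current(mesh, field) == 0.0
        with pytest.raises(ValueError):
            em.electrode_current_and_impedance(mesh, field)


class TestAnnulus:
    """Concentric annulus sector: R = ln(b/a) / (angle sigma L)."""

    a, b, L, angle, sigma = 2e-3, 8e-3, 5e-3, math.pi / 6, 0.359

    def _resistance(self, n):
        mesh = build_annulus_mesh(self.a, self.b, self.L, self.angle,
                                  n, n, max(n // 2, 2))
        field = em.solve_potential(mesh, _uniform(mesh, self.sigma), 1.0)
        return 1.0 / em.sector_current(mesh, field)

    def test_convergence_to_closed_form(self):
        exact = math.log(self.b / self.a) / (self.angle * self.sigma * self.L)
        err = [abs(self._resistance(n) - exact) for n in (8, 16)]
        assert err[0] / exact < 0.02
        # discretization error falls at least ~linearly under refinement
        assert err[1] < err[0] / 1.8


class TestSectorSolve:
    def test_maximum_principle(self, sector_mesh):
        field = em.solve_potential(sector_mesh, sigma_for(sector_mesh), 10.0)
        assert field.V.min() >= -1e-6
        assert field.V.max() <= 10.0 + 1e-6

    def test_power_balance_green_identity(self, sector_mesh):
        sigma = sigma_for(sector_mesh)
        field = em.solve_potential(sector_mesh, sigma, 10.0)
        q = em.joule_power_density(sector_mesh, field, sigma)
        vols, _ = tet_geometry(sector_mesh.nodes, sector_mesh.elems)
        P_volume = float((q * vols).sum())
        P_terminal = 10.0 * em.sector_current(sector_mesh, field)
        assert P_volume == pytest.approx(P_terminal, rel=5e-3)

    def test_impedance_follows_conductivity_law(self):
        """Uniformly heating homogeneous tissue by +10 C divides Z by e^0.15."""
        mesh = build_box_mesh(4e-3, 2e-3, 3e-3, 4, 3, 3)
        table = MaterialTable()
        Z = {}
        for T in (37.0, 47.0):
            sigma = _uniform(mesh, table.conductivity("trachea", T))
            field = em.solve_potential(mesh, sigma, 1.0)
            _, Z[T] = em.electrode_current_and_impedance(mesh, field)
        assert Z[47.0] / Z[37.0] == pytest.approx(math.exp(-0.15), rel=1e-9)

    def test_nonpositive_sigma_rejected(self, sector_mesh):
        sigma = sigma_for(sector_mesh)
        sigma[0] = 0.0
        with pytest.raises(ValueError):
            em.solve_potential(sector_mesh, sigma, 1.0)


class TestSymmetryAudit:
    """Brute-force audits that freeze the sector -> device scaling.

    A double-width model with a whole electrode between two grounded
    midplanes must carry twice the sector current (circumferential
    mirror); a 60-degree model with half electrodes at +V and -V must
    reproduce the sector solution with a ~0 V midplane (bipolar drive:
    terminal voltage = 2 x sector drive).
    """

    V = 10.0

    def test_mirror_factor_of_two(self, sector_current_value):
        sector_current = sector_current_value
        g = DeviceGeometry()
        mesh = build_mirror_audit_mesh(g, "tiny")
        drive = mesh.nodes_in(Subdomain.ELECTRODE)
        ground = mesh.nodes_on(Boundary.GROUND_PLANE)
        field = em.solve_potential(
            mesh, sigma_for(mesh), self.V,
            dirichlet=[(drive, self.V), (ground, 0.0)])
        assert em.sector_current(mesh, field) == pytest.approx(
            2.0 * sector_current, rel=0.02)

    def test_bipolar_pair_reproduces_sector(self, sector_current_value):
        sector_current = sector_current_value
        g = DeviceGeometry()
        mesh = build_bipolar_audit_mesh(g, "tiny")
        el = mesh.nodes_in(Subdomain.ELECTRODE)
        theta = mesh.cyl[el, 1]
        plus = el[theta < g.sector_angle]
        minus = el[theta > g.sector_angle]
        field = em.solve_potential(
            mesh, sigma_for(mesh), self.V,
            dirichlet=[(plus, self.V), (minus, -self.V)])
        assert em.sector_current(mesh, field) == pytest.approx(
            sector_current, rel=0.02)
        mid = np.abs(mesh.cyl[:, 1] - g.sector_angle) < 1e-9
        assert np.abs(field.V[mid]).max() < 0.02 * self.V

    def test_equipotential_body_drive_matches_face_drive(self, sector_mesh,
                                                         sector_current_value):
        sector_current = sector_current_value
        drive = sector_mesh.nodes_in(Subdomain.ELECTRODE)
        ground = sector_mesh.nodes_on(Boundary.GROUND_PLANE)
        field = em.solve_potential(
            sector_mesh, sigma_for(sector_mesh), self.V,
            dirichlet=[(drive, self.V), (ground, 0.0)])
        assert em.sector_current(sector_mesh, field) == pytest.approx(
            sector_current, rel=1e-3)

    def test_device_scaling_factors(self):
        conv = em.SymmetryConvention(6)
        assert (conv.voltage, conv.current, conv.power) == (2, 12, 24)
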