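"""Transient bioheat step: lumped oracles, energy identity, stepper."""

import math

import numpy as np
import pytest

from airwayrf import em
from airwayrf.bioheat import (
    BioheatModel,
    TemperatureField,
    TimeStepper,
    advance_adaptive,
    apply_initial_conditions,
)
from airwayrf.fem import DirichletSolver
from airwayrf.geometry import (
    Boundary,
    Subdomain,
    build_annulus_mesh,
    build_box_mesh,
)
from airwayrf.materials import EvaporationParams, MaterialTable, PerfusionParams

from conftest import sigma_for


def _adiabatic_box(subdomain=Subdomain.AIRWAY_WALL, n=2):
    """Sealed 1 mm cube: no fixed-temperature boundary anywhere."""
    mesh = build_box_mesh(1e-3, 1e-3, 1e-3, n, n, n, subdomain=subdomain)
    mesh.facet_tag[:] = int(Boundary.SYMMETRY_AXIAL_PLANE)
    return mesh


class TestStepOracles:
    def test_uniform_source_heats_like_lumped_ode(self):
        """Adiabatic uniform body under uniform q: dT = q dt / (rho c)."""
        mesh = _adiabatic_box()
        table = MaterialTable()
        model = BioheatModel(mesh, table, PerfusionParams(0.0, 0.0),
                             EvaporationParams(Hr=1.0))
        m = table["trachea"]
        q, dt = 5e6, 1e-3
        state = TemperatureField(np.full(mesh.num_nodes, 37.0), 0.0)
        new, energies = model.step(state, np.full(mesh.num_elements, q), dt)
        dT = q * dt / (m.rho * m.c)
        assert np.allclose(new.T, 37.0 + dT, rtol=1e-12)
        assert energies.joule == pytest.approx(q * 1e-9 * dt, rel=1e-12)

    def test_perfusion_relaxation_matches_scalar_recurrence(self):
        """Uniform hot field with perfusion only: exponential return to Tbody.

        The lumped discrete system on a uniform field reduces exactly to
        the scalar backward-Euler recurrence, which itself tracks the
        closed-form exponential.
        """
        mesh = _adiabatic_box(Subdomain.PARENCHYMA)
        table = MaterialTable()
        perf = PerfusionParams(omega_parenchyma=0.02)
        model = BioheatModel(mesh, table, perf, EvaporationParams(Hr=1.0))
        p = table["parenchyma"]
        tau = p.rho * p.c / (perf.rho_blood * perf.c_blood *
                             perf.omega_parenchyma)
        dt, nsteps, T0 = 2e-3, 150, 57.0
        state = TemperatureField(np.full(mesh.num_nodes, T0), 0.0)
        q = np.zeros(mesh.num_elements)
        T_scalar = T0
        for _ in range(nsteps):
            state, _ = model.step(state, q, dt)
            T_scalar = (T_scalar + dt / tau * 37.0) / (1.0 + dt / tau)
        assert np.allclose(state.T, T_scalar, rtol=1e-9)
        exact = 37.0 + (T0 - 37.0) * math.exp(-nsteps * dt / tau)
        assert state.T.mean() == pytest.approx(exact, abs=0.05)

    def test_equilibrium_field_is_stationary(self, sector_mesh):
        """37 C everywhere with 37 C boundaries and no source: unchanged."""
        model = BioheatModel(sector_mesh, baseline_subtraction=True)
        state = TemperatureField(np.full(sector_mesh.num_nodes, 37.0), 0.0)
        new, energies = model.step(state, np.zeros(sector_mesh.num_elements),
                                   0.03)
        assert np.allclose(new.T, 37.0, atol=1e-10)
        assert abs(energies.stored) < 1e-12

    def test_steady_radial_conduction_profile(self):
        """Annulus held at 65/37 C: logarithmic steady profile."""
        a, b = 2e-3, 8e-3
        errs = []
        for nr, nt in ((14, 8), (28, 16)):
            mesh = build_annulus_mesh(a, b, 4e-3, math.pi / 6, nr, nt, 4)
            model = BioheatModel(mesh, perfusion=PerfusionParams(0.0, 0.0),
                                 evaporation=EvaporationParams(Hr=1.0))
            inner = mesh.nodes_on(Boundary.ELECTRODE_DRIVE_FACE)
            outer = mesh.nodes_on(Boundary.GROUND_PLANE)
            fixed = np.concatenate([inner, outer])
            vals = np.concatenate([np.full(len(inner), 65.0),
                                   np.full(len(outer), 37.0)])
            solver = DirichletSolver(model.K, fixed, mesh.num_nodes)
            T = solver.solve(np.zeros(mesh.num_nodes), vals)
            exact = 65.0 + (37.0 - 65.0) * np.log(mesh.cyl[:, 0] / a) / \
                math.log(b / a)
            errs.append(float(np.abs(T - exact).max()))
        assert errs[0] < 0.2
        assert errs[1] < errs[0] / 1.8  # error at least halves per refinement

    def test_adiabatic_conservation_limit(self, sector_mesh):
        """Hr=1, no perfusion, sealed domain: enthalpy gain = joule input."""
        import copy

        mesh = copy.deepcopy(sector_mesh)
        # Seal the outer boundary (retag as adiabatic symmetry).
        outer = mesh.facet_tag == int(Boundary.OUTER_SURFACE)
        mesh.facet_tag[outer] = int(Boundary.SYMMETRY_AXIAL_PLANE)
        model = BioheatModel(mesh, perfusion=PerfusionParams(0.0, 0.0),
                             evaporation=EvaporationParams(Hr=1.0))
        sigma = sigma_for(mesh)
        field = em.solve_potential(mesh, sigma, 15.0)
        q = em.joule_power_density(mesh, field, sigma)
        state = TemperatureField(np.full(mesh.num_nodes, 37.0), 0.0)
        stored = 0.0
        for _ in range(10):
            state, energies = model.step(state, q, 0.01)
            stored += energies.stored
            assert energies.evaporation_parenchyma == 0.0
            assert energies.evaporation_luminal == 0.0
        joule = float((q * model.vols).sum()) * 0.1
        assert stored == pytest.approx(joule, rel=1e-9)

    def test_discrete_energy_identity_per_step(self, sector_mesh):
        """stored = joule - perfusion - evaporation - boundary outflow."""
        model = BioheatModel(sector_mesh, baseline_subtraction=True)
        sigma = sigma_for(sector_mesh)
        field = em.solve_potential(sector_mesh, sigma, 20.0)
        q = em.joule_power_density(sector_mesh, field, sigma)
        state = apply_initial_conditions(sector_mesh, "pretreat_offset")
        for dt in (1e-6, 1e-3, 0.03):
            state, e = model.step(state, q, dt)
            balance = (e.joule - e.perfusion_parenchyma - e.perfusion_wall
                       - e.evaporation_parenchyma - e.evaporation_luminal
                       - e.boundary_outflow)
            assert e.stored == pytest.approx(balance, abs=1e-12 + 1e-9 * abs(e.joule))

    def test_invalid_step_arguments(self, sector_mesh):
        model = BioheatModel(sector_mesh)
        state = TemperatureField(np.full(sector_mesh.num_nodes, 37.0), 0.0)
        with pytest.raises(ValueError):
            model.step(state, np.zeros(sector_mesh.num_elements), -1e-3)
        with pytest.raises(ValueError):
            model.step(state, np.full(sector_mesh.num_elements, -1.0), 1e-3)


class TestInitialConditions:
    def test_nominal_electrode_and_air_two_degrees_cool(self, sector_mesh):
        state = apply_initial_conditions(sector_mesh, "nominal")
        g = sector_mesh.geometry.params
        back = np.array([g.electrode_back_radius, 0.0, 0.0])
        control = int(np.argmin(np.linalg.norm(sector_mesh.nodes - back, axis=1)))
        assert state.T[control] == pytest.approx(35.0)
        tissue_interior = np.setdiff1d(
            sector_mesh.nodes_in(Subdomain.AIRWAY_WALL, Subdomain.PARENCHYMA),
            sector_mesh.nodes_in(Subdomain.ELECTRODE, Subdomain.LUMEN_AIR))
        assert np.allclose(state.T[tissue_interior], 37.0)

    def test_pretreat_offset_reads_41_at_control_point(self, sector_mesh):
        state = apply_initial_conditions(sector_mesh, "pretreat_offset")
        electrode = sector_mesh.nodes_in(Subdomain.ELECTRODE)
        assert np.allclose(state.T[electrode], 41.0)
        # warmth decays: far tissue still at body temperature
        far = sector_mesh.cyl[:, 0] > 5e-3
        assert np.allclose(state.T[far], 37.0, atol=1e-6)

    def test_unknown_mode_rejected(self, sector_mesh):
        with pytest.raises(ValueError):
            apply_initial_conditions(sector_mesh, "warm_start")


class TestTimeStepper:
    def test_first_step_is_microsecond(self):
        stepper = TimeStepper()
        assert stepper.propose(0.0) == pytest.approx(1e-6)

    def test_growth_saturates_at_dt_max(self):
        stepper = TimeStepper()
        for _ in range(30):
            stepper.accept()
        assert stepper.dt == pytest.approx(0.03)
        stepper.accept()
        assert stepper.dt == pytest.approx(0.03)

    def test_proposal_truncated_to_control_boundary(self):
        stepper = TimeStepper()
        stepper.dt = 0.03
        assert stepper.propose(0.04) == pytest.approx(0.01)
        assert stepper.propose(0.05) == pytest.approx(0.03)

    def test_reject_halves_down_to_floor(self):
        stepper = TimeStepper()
        stepper.dt = 4e-6
        assert stepper.reject()
        assert stepper.dt == pytest.approx(2e-6)
        assert stepper.reject()
        assert not stepper.reject()  # already at dt_min

    def test_advance_adaptive_grows_then_proposes(self):
        stepper = TimeStepper()
        dt = advance_adaptive(stepper, t=0.0, converged=True)
        assert dt == pytest.approx(2e-6)
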