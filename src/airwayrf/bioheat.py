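"""Transient Pennes bioheat solver on the tagged sector mesh.

Advances

    rho c dT/dt = div(k grad T) + sigma |grad V|^2
                  - rho_b c_b w (T - Tbody) - hfg dm/dt

with a backward-implicit step: conduction and the perfusion sink are
treated implicitly, while the joule source and both evaporation sinks
(alveolar volumetric sink in parenchyma, diffusion-film flux on the
luminal surface) are evaluated at the previous iterate; the
orchestrator may wrap the step in a Picard loop.  Boundary conditions:
adiabatic symmetry planes and lumen-truncation face, fixed body
temperature on the outer surfaces.  Lumen air conducts (k = 0.030
W/m/K) but does not convect.

Mass is lumped (row-sum), which makes the discrete energy balance
exact: over any step, stored-heat change = joule input - perfusion
loss - evaporation loss - conduction outflow through the fixed-
temperature boundary, to round-off.  The solver reports those step
energies so the orchestrator can integrate the energy budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import fem, materials as mat
from .geometry import Boundary, Mesh, Subdomain, SUBDOMAIN_MATERIAL


@dataclass
class TemperatureField:
    """Nodal temperature snapshot (deg C) at a given time (s)."""

    T: np.ndarray
    time: float = 0.0


@dataclass
class StepEnergies:
    """Sector-level energy bookkeeping of one implicit step (J)."""

    joule: float = 0.0
    perfusion_parenchyma: float = 0.0
    perfusion_wall: float = 0.0
    evaporation_parenchyma: float = 0.0
    evaporation_luminal: float = 0.0
    stored: float = 0.0
    boundary_outflow: float = 0.0


@dataclass
class TimeStepper:
    """Adaptive implicit step size under solver control.

    Starts at dt_init (1e-6 s), grows geometrically on smooth steps up
    to dt_max (0.03 s), halves on a rejected step, and truncates
    proposals so that no step straddles a control-update boundary.
    """

    dt_init: float = 1e-6
    dt_min: float = 1e-6
    dt_max: float = 0.03
    growth: float = 2.0
    control_interval: float = 0.05
    dt: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.dt_min <= self.dt_init <= self.dt_max:
            raise ValueError("need 0 < dt_min <= dt_init <= dt_max")
        if self.growth <= 1.0:
            raise ValueError("growth factor must exceed 1")
        self.dt = self.dt_init

    def next_boundary(self, t: float) -> float:
        n = int(np.floor(t / self.control_interval + 1e-9)) + 1
        return n * self.control_interval

    def propose(self, t: float) -> float:
        """Step size from t: current dt, truncated to the next boundary."""
        dt = float(np.clip(self.dt, self.dt_min, self.dt_max))
        boundary = self.next_boundary(t)
        if t + dt >= boundary - 1e-12:
            dt = boundary - t
        return dt

    def accept(self) -> None:
        self.dt = min(self.dt * self.growth, self.dt_max)

    def reject(self) -> bool:
        """Halve dt; returns False when already at dt_min (hard failure)."""
        if self.dt <= self.dt_min * (1 + 1e-12):
            return False
        self.dt = max(self.dt / 2.0, self.dt_min)
        return True


def advance_adaptive(stepper: TimeStepper, t: float,
                     converged: bool = True) -> float:
    """Update the stepper from the last step's outcome; propose the next dt."""
    if converged:
        stepper.accept()
    elif not stepper.reject():
        raise fem.SolverError(f"time step underflow at t={t}")
    return stepper.propose(t)


class BioheatModel:
    """Assembled thermal operators for a tagged mesh.

    Conduction stiffness, lumped heat capacity, and perfusion sink are
    assembled once; implicit factors are cached per distinct dt (the
    matrix only changes through dt).
    """

    def __init__(
        self,
        mesh: Mesh,
        table: mat.MaterialTable | None = None,
        perfusion: mat.PerfusionParams | None = None,
        evaporation: mat.EvaporationParams | None = None,
        baseline_subtraction: bool = False,
        iterative_threshold: int = 200_000,
    ):
        self.mesh = mesh
        self.table = table or mat.MaterialTable()
        self.perfusion = perfusion or mat.PerfusionParams()
        self.evaporation = evaporation or mat.EvaporationParams()
        self.baseline_subtraction = baseline_subtraction
        self.Tbody = self.table.Tbody
        self._iterative_threshold = iterative_threshold

        n = mesh.num_nodes
        self.vols, self.grads = fem.tet_geometry(mesh.nodes, mesh.elems)
        k = np.empty(mesh.num_elements)
        rhoc = np.empty(mesh.num_elements)
        for sub, name in SUBDOMAIN_MATERIAL.items():
            m = self.table[name]
            sel = mesh.elem_tag == int(sub)
            k[sel] = m.k
            rhoc[sel] = m.rho * m.c
        self.K = fem.stiffness(mesh.nodes, mesh.elems, k,
                               vols=self.vols, grads=self.grads)
        self.mass = fem.lumped_mass(n, mesh.elems, rhoc, self.vols)

        rb_cb = self.perfusion.rho_blood * self.perfusion.c_blood
        par = mesh.elem_tag == int(Subdomain.PARENCHYMA)
        wall = mesh.elem_tag == int(Subdomain.AIRWAY_WALL)
        self.par_elems = par
        self.perf_par = fem.lumped_mass(
            n, mesh.elems,
            np.where(par, rb_cb * self.perfusion.omega_parenchyma, 0.0),
            self.vols)
        self.perf_wall = fem.lumped_mass(
            n, mesh.elems,
            np.where(wall, rb_cb * self.perfusion.omega_airway_wall, 0.0),
            self.vols)
        self.perf = self.perf_par + self.perf_wall

        self.fixed = mesh.nodes_on(Boundary.OUTER_SURFACE)
        lum = mesh.facets_with(Boundary.LUMINAL_SURFACE)
        self.lum_facets = mesh.facets[lum]
        self.lum_areas = mesh.facet_areas(lum)
        self._factors: dict[float, fem.DirichletSolver] = {}

    # -- sink evaluation (previous iterate) --------------------------------

    def _evaporation_loads(self, T: np.ndarray):
        """Nodal load vectors (<= 0) of both evaporation sinks at state T."""
        n = self.mesh.num_nodes
        ev = self.evaporation
        Te = T[self.mesh.elems].mean(axis=1)
        s = np.where(self.par_elems,
                     mat.evaporative_sink_parenchyma(Te, ev), 0.0)
        if self.baseline_subtraction:
            s0 = mat.evaporative_sink_parenchyma(self.Tbody, ev)
            s = np.where(self.par_elems, np.maximum(s - s0, 0.0), 0.0)
        f_vol = -fem.element_load(n, self.mesh.elems, self.vols, s)

        if len(self.lum_facets):
            Tf = T[self.lum_facets].mean(axis=1)
            flux = mat.evaporative_flux_luminal(Tf, ev)
            if self.baseline_subtraction:
                flux = np.maximum(
                    flux - mat.evaporative_flux_luminal(self.Tbody, ev), 0.0)
            f_surf = -fem.facet_load(n, self.lum_facets, self.lum_areas, flux)
        else:
            f_surf = np.zeros(n)
        return f_vol, f_surf

    def _solver_for(self, dt: float) -> fem.DirichletSolver:
        key = round(dt, 15)
        solver = self._factors.get(key)
        if solver is None:
            A = self.K + sp.diags(self.mass / dt + self.perf)
            solver = fem.DirichletSolver(
                A, self.fixed, self.mesh.num_nodes,
                self._iterative_threshold)
            if len(self._factors) > 40:
                self._factors.clear()
            self._factors[key] = solver
        return solver

    # -- the implicit step -------------------------------------------------

    def step(self, state: TemperatureField, q_elem: np.ndarray,
             dt: float) -> tuple[TemperatureField, StepEnergies]:
        """One backward-implicit step of length dt from `state`.

        q_elem is the per-element joule power density (W/m^3) held
        constant over the step.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(q_elem < 0):
            raise ValueError("joule power density must be non-negative")
        mesh = self.mesh
        n = mesh.num_nodes
        T_old = state.T

        f_joule = fem.element_load(n, mesh.elems, self.vols, q_elem)
        f_evap_vol, f_evap_surf = self._evaporation_loads(T_old)
        b = (self.mass / dt) * T_old + self.perf * self.Tbody \
            + f_joule + f_evap_vol + f_evap_surf

        solver = self._solver_for(dt)
        T_new = solver.solve(b, np.full(len(self.fixed), self.Tbody))
        if not np.all(np.isfinite(T_new)):
            raise fem.SolverError("non-finite temperature update")

        residual = solver.A @ T_new - b
        e = StepEnergies(
            joule=float((q_elem * self.vols).sum()) * dt,
            perfusion_parenchyma=float(
                (self.perf_par * (T_new - self.Tbody)).sum()) * dt,
            perfusion_wall=float(
                (self.perf_wall * (T_new - self.Tbody)).sum()) * dt,
            evaporation_parenchyma=float(-f_evap_vol.sum()) * dt,
            evaporation_luminal=float(-f_evap_surf.sum()) * dt,
            stored=float((self.mass * (T_new - T_old)).sum()),
            # Reactions at the fixed nodes measure boundary inflow;
            # outflow (heat lost through the 37 C surface) is its negative.
            boundary_outflow=float(-residual[self.fixed].sum()) * dt,
        )
        return TemperatureField(T_new, state.time + dt), e

    # -- diagnostics -------------------------------------------------------

    def interface_heat_flux(self, T: np.ndarray,
                            idx: np.ndarray | None = None) -> tuple[float, float]:
        """(total W, area-mean W/m^2) conducted across the wall/parenchyma
        interface, from the wall-side element gradients.

        idx optionally restricts the computation to a subset of the
        interface facets (e.g. the treatment zone).
        """
        mesh = self.mesh
        if idx is None:
            idx = mesh.facets_with(Boundary.WALL_PARENCHYMA_INTERFACE)
        if idx.size == 0:
            return 0.0, 0.0
        facets = mesh.facets[idx]
        owners = mesh.facet_elem[idx]
        areas = mesh.facet_areas(idx)
        gradT = np.einsum("fid,fi->fd", self.grads[owners], T[mesh.elems[owners]])
        p = mesh.nodes[facets]
        nvec = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        nvec /= np.linalg.norm(nvec, axis=1, keepdims=True)
        # Orient each normal away from the owner (wall-side) element.
        cent_f = p.mean(axis=1)
        cent_e = mesh.nodes[mesh.elems[owners]].mean(axis=1)
        sign = np.sign(np.einsum("fd,fd->f", nvec, cent_f - cent_e))
        k_wall = self.table[SUBDOMAIN_MATERIAL[Subdomain.AIRWAY_WALL]].k
        qn = -k_wall * np.einsum("fd,fd->f", gradT, nvec) * sign
        total = float((qn * areas).sum())
        return total, total / float(areas.sum())


def apply_initial_conditions(
    mesh: Mesh,
    mode: str = "nominal",
    Tbody: float = mat.TBODY_C,
    electrode_air_offset: float = 2.0,
    pretreat_temperature: float = 41.0,
    pretreat_length_scale: float = 0.5e-3,
) -> TemperatureField:
    """Initial nodal temperature field for a given pre-treatment mode.

    nominal         : tissue at Tbody, electrode and lumen air two
                      degrees below (cool catheter just deployed).
    pretreat_offset : additionally imprints the residual warmth of the
                      generator's pre-treatment test pulse so the
                      control point reads `pretreat_temperature`; the
                      bump decays as a Gaussian of the distance to the
                      electrode with scale `pretreat_length_scale`.
    pretreat_pulse  : same field as nominal; the orchestrator then
                      simulates the constant-current test pulse itself.
    """
    if mode not in ("nominal", "pretreat_offset", "pretreat_pulse"):
        raise ValueError(f"unknown initial-condition mode {mode!r}")
    T = np.full(mesh.num_nodes, Tbody)
    # Electrode and lumen air start two degrees cool; nodes shared with
    # tissue stay at body temperature (the contact surface equilibrates
    # with tissue on contact, and a cold luminal surface would put a
    # spurious jump against the fixed-temperature far boundary).
    cold = np.setdiff1d(
        mesh.nodes_in(Subdomain.LUMEN_AIR, Subdomain.ELECTRODE),
        mesh.nodes_in(Subdomain.AIRWAY_WALL, Subdomain.PARENCHYMA))
    T[cold] = Tbody - electrode_air_offset

    if mode == "pretreat_offset":
        g = mesh.geometry.params if mesh.geometry is not None else None
        if g is None:
            raise ValueError("pretreat_offset needs a sector mesh with geometry")
        r, th, z = mesh.cyl[:, 0], mesh.cyl[:, 1], mesh.cyl[:, 2]
        dr = np.maximum.reduce([
            g.electrode_back_radius - r, r - g.electrode_tip_radius,
            np.zeros_like(r)])
        dth = np.maximum(np.abs(th) - g.electrode_half_angle, 0.0) * r
        dz = np.maximum(np.abs(z) - g.electrode_half_length, 0.0)
        d2 = dr**2 + dth**2 + dz**2
        w = np.exp(-d2 / pretreat_length_scale**2)
        T = T + (pretreat_temperature - T) * w
    return TemperatureField(T, 0.0)


def step_bioheat(
    state: TemperatureField,
    q_elem: np.ndarray,
    dt: float,
    model: BioheatModel,
) -> tuple[TemperatureField, StepEnergies]:
    """Functional wrapper around :meth:`BioheatModel.step`."""
    return model.step(state, q_elem, dt)
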