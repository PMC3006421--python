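"""Closed-form verification suite for the discretized solvers.

Each check solves a small problem with a known analytic answer on the
same assembly/solver path as the full model: a uniform slab and a
concentric annulus for the electrical problem, an exponential
perfusion relaxation and a steady logarithmic profile for the thermal
problem, and a hand-evaluated PI controller step.  Exposed both to the
test suite and through the ``airwayrf verify`` CLI subcommand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import em, fem, materials as mat
from .bioheat import BioheatModel, TemperatureField
from .control import ControllerState, PIDController, TargetProfile
from .geometry import Boundary, Subdomain, build_annulus_mesh, build_box_mesh


@dataclass
class Check:
    name: str
    value: float
    expected: float
    rel_tol: float
    abs_tol: float = 0.0

    @property
    def passed(self) -> bool:
        err = abs(self.value - self.expected)
        return err <= self.abs_tol + self.rel_tol * abs(self.expected)


def slab_resistance_check(sigma: float = 0.359) -> Check:
    """Uniform slab between opposite Dirichlet faces: R = L / (sigma A)."""
    lx, ly, lz = 4e-3, 2e-3, 3e-3
    mesh = build_box_mesh(lx, ly, lz, 6, 4, 5)
    field = em.solve_potential(mesh, np.full(mesh.num_elements, sigma), 1.0)
    I = em.sector_current(mesh, field)
    R_expected = lx / (sigma * ly * lz)
    # Linear exact solution is in the P1 space: agreement to round-off.
    return Check("slab resistance", 1.0 / I, R_expected, 1e-10)


def annulus_resistance_check(refine: int = 1, sigma: float = 0.359) -> Check:
    """Concentric annulus sector: R = ln(b/a) / (angle sigma L)."""
    a, b, L, angle = 2e-3, 8e-3, 5e-3, math.pi / 6
    n = 8 * refine
    mesh = build_annulus_mesh(a, b, L, angle, n, n, max(n // 2, 2))
    field = em.solve_potential(mesh, np.full(mesh.num_elements, sigma), 1.0)
    I = em.sector_current(mesh, field)
    R_expected = math.log(b / a) / (angle * sigma * L)
    return Check(f"annulus resistance (refine={refine})",
                 1.0 / I, R_expected, 0.02 / refine)


def perfusion_relaxation_check() -> Check:
    """Zero-conduction perfusion decay: T - Tb ~ exp(-rb cb w t / (rho c)).

    Conduction is made irrelevant by a spatially uniform field with
    adiabatic boundaries, so each node follows the scalar ODE exactly
    up to the backward-Euler error, which is what the tolerance bounds.
    """
    table = mat.MaterialTable()
    perf = mat.PerfusionParams(omega_parenchyma=0.02)
    mesh = build_box_mesh(1e-3, 1e-3, 1e-3, 2, 2, 2,
                          subdomain=Subdomain.PARENCHYMA)
    # Retag the Dirichlet faces as adiabatic so no outer boundary exists.
    mesh.facet_tag[:] = int(Boundary.SYMMETRY_AXIAL_PLANE)
    model = BioheatModel(mesh, table, perf,
                         mat.EvaporationParams(Hr=1.0))
    p = table["parenchyma"]
    tau = p.rho * p.c / (perf.rho_blood * perf.c_blood * perf.omega_parenchyma)
    T0, dt, nsteps = 57.0, 1e-3, 200
    state = TemperatureField(np.full(mesh.num_nodes, T0), 0.0)
    q = np.zeros(mesh.num_elements)
    for _ in range(nsteps):
        state, _ = model.step(state, q, dt)
    expected = 37.0 + (T0 - 37.0) * math.exp(-nsteps * dt / tau)
    return Check("perfusion relaxation", float(state.T.mean()) - 37.0,
                 expected - 37.0, 5e-3)


def radial_conduction_check() -> Check:
    """Steady annulus conduction: T(r) = Ti + (To-Ti) ln(r/a)/ln(b/a).

    One huge implicit step drives the transient solver to its steady
    state, which must match the logarithmic profile within
    discretization error.
    """
    a, b, L, angle = 2e-3, 8e-3, 4e-3, math.pi / 6
    mesh = build_annulus_mesh(a, b, L, angle, 28, 16, 4)
    # Inner face hot Dirichlet, outer face at body temperature.
    table = mat.MaterialTable()
    model = BioheatModel(mesh, table, mat.PerfusionParams(0.0, 0.0),
                         mat.EvaporationParams(Hr=1.0))
    inner = mesh.nodes_on(Boundary.ELECTRODE_DRIVE_FACE)
    outer = mesh.nodes_on(Boundary.GROUND_PLANE)
    Ti, To = 65.0, 37.0
    n = mesh.num_nodes
    fixed = np.concatenate([inner, outer])
    vals = np.concatenate([np.full(len(inner), Ti), np.full(len(outer), To)])
    solver = fem.DirichletSolver(model.K, fixed, n)
    T = solver.solve(np.zeros(n), vals)
    r = mesh.cyl[:, 0]
    exact = Ti + (To - Ti) * np.log(r / a) / np.log(b / a)
    err = float(np.max(np.abs(T - exact)))
    return Check("steady radial conduction (max error, C)", err, 0.0,
                 rel_tol=0.0, abs_tol=0.05)


def pi_controller_check() -> Check:
    """Constant 1 C error held for 0.1 s: output 20 + 60 * 0.1 = 26 V."""
    profile = TargetProfile(T_start=42.0, T_hold=65.0,
                            ramp_duration=0.5, total_duration=3.0)
    ctrl = PIDController(ControllerState(), profile)
    out = 0.0
    for t in (0.0, 0.05, 0.1):
        out = ctrl.update(target_minus_one(t, profile), t)
    return Check("PI hand evaluation", out, 26.0, 1e-12)


def target_minus_one(t: float, profile: TargetProfile) -> float:
    from .control import target_temperature
    return target_temperature(t, profile) - 1.0


def run_all() -> list[Check]:
    return [
        slab_resistance_check(),
        annulus_resistance_check(1),
        annulus_resistance_check(2),
        perfusion_relaxation_check(),
        radial_conduction_check(),
        pi_controller_check(),
    ]
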