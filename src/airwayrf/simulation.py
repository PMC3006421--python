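"""Coupled control/electrical/thermal activation loop and sensitivity sweeps.

One activation runs the closed loop over a 3 s window: the PID sets
the drive voltage from the control-point temperature (by default at
every solver step; optionally only at the 50 ms generator boundaries),
and the solver takes adaptive implicit thermal steps, each preceded by
a re-solve of the electrical problem with the current sigma(T) so that
the joule source tracks the heating.
Telemetry (control temperature, device-level voltage, current,
impedance, power, cumulative energy) is sampled on the control cadence
and the energy budget is integrated every step.

The control point is the node on the electrode back surface (opposite
the tissue-contacting side) at the electrode's center, where the
physical catheter carries its thermocouple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import em, materials as mat
from .bioheat import (BioheatModel, TemperatureField, TimeStepper,
                      apply_initial_conditions)
from .config import RunConfig
from .control import PIDController
from .fem import SolverError
from .geometry import (Mesh, Subdomain, SUBDOMAIN_MATERIAL,
                       build_sector_geometry, generate_mesh)

logger = logging.getLogger(__name__)

TELEMETRY_COLUMNS = ["time_s", "T_ctrl_C", "V_V", "I_A", "Z_ohm", "P_W", "E_J"]


@dataclass
class EnergyBudget:
    """Device-level energy budget of one activation (J).

    tissue_heating bundles the net enthalpy change of all subdomains
    with the conduction outflow through the fixed-temperature outer
    boundary (therapeutic heating including heat redistributed away
    from the treatment site).  Airway-wall perfusion is computed but
    reported separately from the chart components; it is absorbed by
    the residual, which closes the balance against delivered energy.
    """

    delivered: float
    tissue_heating: float
    parenchyma_evaporation: float
    luminal_evaporation: float
    parenchyma_perfusion: float
    residual: float
    wall_perfusion: float = 0.0
    pretreat_pulse_energy: float = 0.0

    def as_dict(self) -> dict:
        return {
            "delivered_J": self.delivered,
            "tissue_heating_J": self.tissue_heating,
            "parenchyma_evaporation_J": self.parenchyma_evaporation,
            "luminal_evaporation_J": self.luminal_evaporation,
            "parenchyma_perfusion_J": self.parenchyma_perfusion,
            "residual_J": self.residual,
            "wall_perfusion_J": self.wall_perfusion,
            "pretreat_pulse_energy_J": self.pretreat_pulse_energy,
        }


@dataclass
class _Accumulators:
    """Sector-level running integrals over an activation."""

    joule: float = 0.0
    perf_par: float = 0.0
    perf_wall: float = 0.0
    evap_par: float = 0.0
    evap_lum: float = 0.0
    stored: float = 0.0
    outflow: float = 0.0
    wall_T_dt: float = 0.0
    iface_T_dt: float = 0.0
    iface_flux_dt: float = 0.0
    time: float = 0.0


@dataclass
class SimulationResult:
    telemetry: pd.DataFrame
    budget: EnergyBudget
    final_temperature: TemperatureField
    mesh: Mesh
    metrics: dict
    controller_log: pd.DataFrame
    config: RunConfig


def energy_budget(acc: _Accumulators, power_mult: float,
                  pulse_energy: float = 0.0) -> EnergyBudget:
    """Close the device-level energy balance from the step accumulators."""
    delivered = power_mult * acc.joule
    tissue = power_mult * (acc.stored + acc.outflow)
    evap_par = power_mult * acc.evap_par
    evap_lum = power_mult * acc.evap_lum
    perf_par = power_mult * acc.perf_par
    perf_wall = power_mult * acc.perf_wall
    residual = delivered - tissue - evap_par - evap_lum - perf_par
    return EnergyBudget(delivered, tissue, evap_par, evap_lum, perf_par,
                        residual, wall_perfusion=perf_wall,
                        pretreat_pulse_energy=pulse_energy)


class _CoupledRun:
    """State shared by the pulse pre-treatment and the activation loop."""

    def __init__(self, config: RunConfig):
        self.config = config
        geometry = build_sector_geometry(config.geometry.to_device_geometry())
        self.mesh = generate_mesh(geometry, config.solver.refinement)
        self.table = config.materials.to_table()
        self.model = BioheatModel(
            self.mesh, self.table,
            config.perfusion.to_params(config.materials),
            config.evaporation.to_params(),
            baseline_subtraction=config.mode.baseline_subtraction,
            iterative_threshold=config.solver.iterative_threshold,
        )
        self.convention = em.SymmetryConvention(
            config.geometry.n_electrodes)
        self.sigma0 = np.empty(self.mesh.num_elements)
        self._sub_material = {}
        for sub, name in SUBDOMAIN_MATERIAL.items():
            sel = self.mesh.elem_tag == int(sub)
            self.sigma0[sel] = self.table[name].sigma0
            self._sub_material[int(sub)] = name
        self._tdep = np.isin(
            self.mesh.elem_tag,
            [int(s) for s, name in SUBDOMAIN_MATERIAL.items()
             if self.table[name].temperature_dependent_sigma])
        g = geometry.params
        self.control_node = self._find_control_node(g)
        # Sensitivity metrics cover the treatment zone (the wall under
        # the electrode, z <= electrode half-length): a fixed region
        # that is comparable across domain-size variants.
        z_zone = g.electrode_half_length + 1e-12
        wall = self.mesh.elem_tag == int(Subdomain.AIRWAY_WALL)
        elem_zc = self.mesh.cyl[self.mesh.elems, 2].mean(axis=1)
        self._wall_elems = np.flatnonzero(wall & (elem_zc <= z_zone))
        vols = self.model.vols
        self._wall_vols = vols[self._wall_elems]
        self._wall_vol_total = float(self._wall_vols.sum())
        from .geometry import Boundary
        idx = self.mesh.facets_with(Boundary.WALL_PARENCHYMA_INTERFACE)
        facet_zc = self.mesh.cyl[self.mesh.facets[idx], 2].mean(axis=1)
        idx = idx[facet_zc <= z_zone]
        self._iface_idx = idx
        self._iface_facets = self.mesh.facets[idx]
        self._iface_areas = self.mesh.facet_areas(idx)
        self._iface_area_total = float(self._iface_areas.sum())

    def _find_control_node(self, g) -> int:
        target = np.array([g.electrode_back_radius, 0.0, 0.0])
        electrode_nodes = self.mesh.nodes_in(Subdomain.ELECTRODE)
        d = np.linalg.norm(self.mesh.nodes[electrode_nodes] - target, axis=1)
        return int(electrode_nodes[np.argmin(d)])

    def sigma_at(self, T: np.ndarray) -> np.ndarray:
        Te = T[self.mesh.elems].mean(axis=1)
        Tc = np.minimum(Te, self.table.sigma_clamp_T)
        sigma = self.sigma0.copy()
        sigma[self._tdep] *= np.exp(
            self.table.alpha * (Tc[self._tdep] - self.table.T0))
        return sigma

    def solve_em(self, T: np.ndarray, V_applied: float):
        sigma = self.sigma_at(T)
        field = em.solve_potential(
            self.mesh, sigma, V_applied,
            iterative_threshold=self.config.solver.iterative_threshold,
            tol=self.config.solver.em_tol)
        if V_applied > 0:
            q = em.joule_power_density(self.mesh, field, sigma)
            I_s = em.sector_current(self.mesh, field)
        else:
            q = np.zeros(self.mesh.num_elements)
            I_s = 0.0
        return field, q, I_s

    def metrics_sample(self, T: np.ndarray):
        Te = T[self.mesh.elems[self._wall_elems]].mean(axis=1)
        wall_T = float((Te * self._wall_vols).sum() / self._wall_vol_total)
        Tf = T[self._iface_facets].mean(axis=1)
        iface_T = float((Tf * self._iface_areas).sum() / self._iface_area_total)
        _, iface_flux = self.model.interface_heat_flux(T, self._iface_idx)
        return wall_T, iface_T, iface_flux


def _advance_interval(run: _CoupledRun, state: TemperatureField,
                      stepper: TimeStepper, controller, V: float,
                      t_end: float, acc: _Accumulators) -> tuple:
    """Adaptive implicit steps from state.time to the next boundary.

    In per-step control mode the PID is re-evaluated at the start of
    every step (the boundary update has already happened when this is
    called).  A step whose largest temperature change exceeds the
    configured accuracy limit is rejected and retried with dt halved.
    Returns (state, V).
    """
    cfg = run.config.solver
    per_step = (controller is not None
                and run.config.controller.cadence == "per_step")
    while state.time < t_end - 1e-12:
        if per_step and state.time > controller.state.prev_time + 1e-12:
            V = controller.update(float(state.T[run.control_node]),
                                  state.time)
        rejected = False
        while True:
            dt = min(stepper.propose(state.time), t_end - state.time)
            T_prev_iter = state.T
            for _ in range(cfg.picard_max):
                _, q, _ = run.solve_em(T_prev_iter, V)
                new_state, energies = run.model.step(state, q, dt)
                delta = float(np.max(np.abs(new_state.T - T_prev_iter)))
                T_prev_iter = new_state.T
                if delta < cfg.picard_tol:
                    break
            dT = float(np.max(np.abs(new_state.T - state.T)))
            if dT <= cfg.max_dT_per_step or not stepper.reject():
                break
            rejected = True
        state = new_state
        if not rejected:
            stepper.accept()
        acc.joule += energies.joule
        acc.perf_par += energies.perfusion_parenchyma
        acc.perf_wall += energies.perfusion_wall
        acc.evap_par += energies.evaporation_parenchyma
        acc.evap_lum += energies.evaporation_luminal
        acc.stored += energies.stored
        acc.outflow += energies.boundary_outflow
        wall_T, iface_T, iface_flux = run.metrics_sample(state.T)
        acc.wall_T_dt += wall_T * dt
        acc.iface_T_dt += iface_T * dt
        acc.iface_flux_dt += iface_flux * dt
        acc.time += dt
    return state, V


def _run_pretreat_pulse(run: _CoupledRun, state: TemperatureField) -> tuple:
    """Constant-current test pulse before t = 0; returns (state, energy_J)."""
    cfg = run.config.mode
    if cfg.pretreat_current_A <= 0 or cfg.pretreat_duration_s <= 0:
        return state, 0.0
    conv = run.convention
    stepper = TimeStepper(
        run.config.solver.dt_init, run.config.solver.dt_min,
        run.config.solver.dt_max, run.config.solver.growth,
        control_interval=run.config.controller.update_interval)
    energy = 0.0
    t = 0.0
    while t < cfg.pretreat_duration_s - 1e-12:
        dt = min(stepper.propose(t), cfg.pretreat_duration_s - t)
        # Voltage that sources the requested device current at sigma(T).
        _, _, I_s_unit = run.solve_em(state.T, 1.0)
        V = cfg.pretreat_current_A / (conv.current * I_s_unit)
        _, q, _ = run.solve_em(state.T, V)
        state, energies = run.model.step(state, q, dt)
        stepper.accept()
        energy += conv.power * energies.joule
        t += dt
    return TemperatureField(state.T, 0.0), energy


def run_simulation(config: RunConfig | None = None) -> SimulationResult:
    """One temperature-controlled activation with full telemetry.

    Deterministic: identical configs produce bit-identical telemetry.
    """
    config = config or RunConfig()
    run = _CoupledRun(config)
    conv = run.convention
    ctl_cfg = config.controller

    state = apply_initial_conditions(
        run.mesh, config.mode.initial_mode,
        Tbody=run.table.Tbody,
        electrode_air_offset=config.mode.electrode_air_offset,
        pretreat_temperature=config.mode.pretreat_temperature,
        pretreat_length_scale=config.mode.pretreat_length_scale)
    pulse_energy = 0.0
    if config.mode.initial_mode == "pretreat_pulse":
        state, pulse_energy = _run_pretreat_pulse(run, state)

    T_ctrl0 = float(state.T[run.control_node])
    profile = ctl_cfg.to_profile(T_ctrl0)
    controller = PIDController(
        ctl_cfg.to_state(), profile,
        enforce_cadence=(ctl_cfg.cadence == "interval"))
    stepper = TimeStepper(
        config.solver.dt_init, config.solver.dt_min, config.solver.dt_max,
        config.solver.growth, control_interval=ctl_cfg.update_interval)

    acc = _Accumulators()
    rows = []
    energy_dev = 0.0

    def sample(t: float, V: float):
        T_ctrl = float(state.T[run.control_node])
        if V > 0:
            _, _, I_s = run.solve_em(state.T, V)
            I_dev = conv.current * I_s
            V_dev = conv.voltage * V
            Z = V_dev / I_dev
            P = V_dev * I_dev
        else:
            I_dev, V_dev, Z, P = 0.0, 0.0, float("nan"), 0.0
        rows.append((t, T_ctrl, V_dev, I_dev, Z, P, energy_dev))

    n_intervals = int(round(ctl_cfg.total_duration / ctl_cfg.update_interval))
    t = 0.0
    V = controller.update(float(state.T[run.control_node]), t)
    sample(t, V)
    for i in range(n_intervals):
        t_end = (i + 1) * ctl_cfg.update_interval
        try:
            state, V = _advance_interval(run, state, stepper, controller,
                                         V, t_end, acc)
        except SolverError as exc:
            raise SolverError(
                f"thermal solve failed at t={state.time:.6f} s "
                f"(dt={stepper.dt:.3e} s): {exc}") from exc
        state = TemperatureField(state.T, t_end)  # avoid drift accumulation
        energy_dev = conv.power * acc.joule
        if i + 1 < n_intervals:
            V = controller.update(float(state.T[run.control_node]), t_end)
        sample(t_end, V)

    telemetry = pd.DataFrame(rows, columns=TELEMETRY_COLUMNS)
    budget = energy_budget(acc, conv.power, pulse_energy)
    total_t = acc.time
    metrics = {
        "E_total_J": budget.delivered,
        "E_ramp_J": float(np.interp(ctl_cfg.ramp_duration,
                                    telemetry.time_s, telemetry.E_J)),
        "T_ctrl_ramp_end_C": float(np.interp(ctl_cfg.ramp_duration,
                                             telemetry.time_s,
                                             telemetry.T_ctrl_C)),
        "T_ctrl_hold_mean_C": float(
            telemetry.T_ctrl_C[telemetry.time_s >= 1.0].mean()),
        "wall_T_timeavg_C": acc.wall_T_dt / total_t,
        "interface_T_timeavg_C": acc.iface_T_dt / total_t,
        "interface_flux_timeavg_W_m2": acc.iface_flux_dt / total_t,
        "num_elements": run.mesh.num_elements,
        "num_nodes": run.mesh.num_nodes,
    }
    logger.info("activation complete: E_total=%.2f J, hold T=%.2f C",
                metrics["E_total_J"], metrics["T_ctrl_hold_mean_C"])
    return SimulationResult(telemetry, budget, state, run.mesh, metrics,
                            pd.DataFrame(controller.log), config)


SWEEP_PARAMETERS = ("alveolar_ratio", "domain_size", "lumen_diameter",
                    "wall_thickness_fraction")


def _apply_multiplier(config: RunConfig, parameter: str,
                      m: float) -> RunConfig:
    c = config.model_copy(deep=True)
    if parameter == "alveolar_ratio":
        c.evaporation.alveolar_ratio_scale = \
            config.evaporation.alveolar_ratio_scale * m
    elif parameter in ("domain_size", "outer_radius+half_length"):
        # Scale the modeled parenchyma margin beyond the device (the
        # domain exists only to surround the airway; shrinking it below
        # the electrode extent would be a different device, not a
        # smaller domain).
        g = config.geometry.to_device_geometry()
        c.geometry.outer_radius = g.wall_outer_radius + m * (
            g.outer_radius - g.wall_outer_radius)
        c.geometry.half_length = g.electrode_half_length + m * (
            g.half_length - g.electrode_half_length)
    elif parameter == "lumen_diameter":
        c.geometry.lumen_diameter = config.geometry.lumen_diameter * m
        c.geometry.core_radius = config.geometry.core_radius * m
    elif parameter == "wall_thickness_fraction":
        c.geometry.wall_thickness_fraction = \
            config.geometry.wall_thickness_fraction * m
    else:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; "
            f"choose from {SWEEP_PARAMETERS}")
    return c


def sensitivity_sweep(
    config: RunConfig, parameter: str, multipliers: list[float],
    baseline: SimulationResult | None = None,
) -> pd.DataFrame:
    """Rerun the activation per multiplier and tabulate relative changes.

    The baseline (multiplier 1.0) is always included; relative deltas
    are in percent of the baseline value.
    """
    if parameter not in SWEEP_PARAMETERS + ("outer_radius+half_length",):
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; "
            f"choose from {SWEEP_PARAMETERS}")
    if baseline is None:
        baseline = run_simulation(config)
    results = {1.0: baseline}
    for m in multipliers:
        if m <= 0:
            raise ValueError("multipliers must be positive")
        if abs(m - 1.0) < 1e-12:
            continue
        results[m] = run_simulation(_apply_multiplier(config, parameter, m))

    base = baseline.metrics
    rows = []
    for m in sorted(set([1.0] + list(multipliers))):
        r = results[m].metrics

        def rel(key):
            return 100.0 * (r[key] - base[key]) / base[key]

        rows.append({
            "multiplier": m,
            "E_total_J": r["E_total_J"],
            "E_ramp_J": r["E_ramp_J"],
            "wall_T_timeavg_C": r["wall_T_timeavg_C"],
            "interface_T_timeavg_C": r["interface_T_timeavg_C"],
            "interface_flux_timeavg_W_m2": r["interface_flux_timeavg_W_m2"],
            "dE_total_pct": rel("E_total_J"),
            "dE_ramp_pct": rel("E_ramp_J"),
            "dwall_T_pct": rel("wall_T_timeavg_C"),
            "diface_T_pct": rel("interface_T_timeavg_C"),
            "diface_flux_pct": rel("interface_flux_timeavg_W_m2"),
        })
    return pd.DataFrame(rows)
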