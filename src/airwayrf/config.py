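"""Run configuration: schema, defaults, YAML serialization.

All defaults equal the published model conditions (4 mm airway, 10 %
wall, six 10 mm electrodes, the tissue property table, kp = 20 /
ki = 60 / kd = 0 at a 50 ms cadence, 0.5 s ramp to 65 C over a 3 s
activation).  An empty config file therefore reproduces the nominal
simulation.  Unknown keys are rejected with an explicit message, and a
config round-trips losslessly through YAML.
"""

from __future__ import annotations

import hashlib
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import materials as mat
from .control import ControllerState, TargetProfile
from .geometry import DeviceGeometry


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Block):
    lumen_diameter: float = Field(4e-3, gt=0)
    wall_thickness_fraction: float = Field(0.10, gt=0, lt=1)
    electrode_length: float = Field(10e-3, gt=0)
    electrode_width: float = Field(0.5e-3, gt=0)
    electrode_height: float = Field(0.25e-3, gt=0)
    embed_depth: float = Field(0.1e-3, gt=0)
    n_electrodes: int = Field(6, ge=1)
    outer_radius: float = Field(10e-3, gt=0)
    half_length: float = Field(10e-3, gt=0)
    core_radius: float = Field(0.4e-3, gt=0)

    def to_device_geometry(self) -> DeviceGeometry:
        g = DeviceGeometry(**self.model_dump())
        g.validate()
        return g


class MaterialRow(_Block):
    sigma0: float = Field(ge=0)
    k: float = Field(gt=0)
    c: float = Field(gt=0)
    rho: float = Field(gt=0)


_DEFAULT_ROWS = {
    name: {"sigma0": m.sigma0, "k": m.k, "c": m.c, "rho": m.rho}
    for name, m in mat.default_materials().items()
}


class MaterialsConfig(_Block):
    air: MaterialRow = MaterialRow(**_DEFAULT_ROWS["air"])
    blood: MaterialRow = MaterialRow(**_DEFAULT_ROWS["blood"])
    trachea: MaterialRow = MaterialRow(**_DEFAULT_ROWS["trachea"])
    parenchyma: MaterialRow = MaterialRow(**_DEFAULT_ROWS["parenchyma"])
    stainless_steel_304: MaterialRow = MaterialRow(
        **_DEFAULT_ROWS["stainless_steel_304"])
    alpha: float = Field(0.015, ge=0)
    T0: float = 37.0
    Tbody: float = 37.0
    sigma_clamp_T: float = 100.0

    def to_table(self) -> mat.MaterialTable:
        tdep = {"trachea", "parenchyma"}
        mats = {
            name: mat.Material(name, row.sigma0, row.k, row.c, row.rho,
                               name in tdep)
            for name, row in (
                ("air", self.air), ("blood", self.blood),
                ("trachea", self.trachea), ("parenchyma", self.parenchyma),
                ("stainless_steel_304", self.stainless_steel_304),
            )
        }
        return mat.MaterialTable(mats, self.alpha, self.T0, self.Tbody,
                                 self.sigma_clamp_T)


class PerfusionConfig(_Block):
    omega_parenchyma: float = Field(0.02, ge=0)
    omega_airway_wall: float = Field(0.6e-3, ge=0)

    def to_params(self, m: MaterialsConfig) -> mat.PerfusionParams:
        return mat.PerfusionParams(
            self.omega_parenchyma, self.omega_airway_wall,
            rho_blood=m.blood.rho, c_blood=m.blood.c)


class EvaporationConfig(_Block):
    hfg: float = Field(2.4e6, gt=0)
    d_alv: float = Field(0.3e-3, gt=0)
    M: float = Field(0.018, gt=0)
    Hr: float = Field(0.95, ge=0, le=1)
    N_alv: float = Field(3e8, gt=0)
    V_lung: float = Field(4.3e-3, gt=0)
    cs_coeff: tuple[float, float] = (0.2821, 0.0588)
    d_coeff: tuple[float, float] = (0.171, 20.84)
    delta_lum: float = Field(1e-3, gt=0)
    alveolar_ratio_scale: float = Field(1.0, gt=0)

    def to_params(self) -> mat.EvaporationParams:
        return mat.EvaporationParams(
            hfg=self.hfg, d_alv=self.d_alv, M=self.M, Hr=self.Hr,
            N_alv=self.N_alv, V_lung=self.V_lung,
            cs_coeff=tuple(self.cs_coeff), d_coeff=tuple(self.d_coeff),
            delta_lum=self.delta_lum,
            alveolar_ratio_scale=self.alveolar_ratio_scale)


class ControllerConfig(_Block):
    kp: float = 20.0
    ki: float = 60.0
    kd: float = 0.0
    #: "per_step": the PID error terms are evaluated continuously, at
    #: every solver step (the control law lives inside the transient
    #: solve); "interval": classic zero-order hold at update_interval.
    cadence: Literal["per_step", "interval"] = "per_step"
    update_interval: float = Field(0.05, gt=0)
    v_min: float = 0.0
    v_max: float = 50.0
    T_start: Optional[float] = None  # None -> initial control-point reading
    T_hold: float = 65.0
    ramp_duration: float = Field(0.5, gt=0)
    total_duration: float = Field(3.0, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.v_max <= self.v_min:
            raise ValueError("v_max must exceed v_min")
        if self.ramp_duration > self.total_duration:
            raise ValueError("ramp_duration must not exceed total_duration")
        return self

    def to_state(self) -> ControllerState:
        return ControllerState(self.kp, self.ki, self.kd,
                               self.update_interval, self.v_min, self.v_max)

    def to_profile(self, T_start: float) -> TargetProfile:
        return TargetProfile(
            self.T_start if self.T_start is not None else T_start,
            self.T_hold, self.ramp_duration, self.total_duration)


class SolverConfig(_Block):
    refinement: Literal["tiny", "coarse", "medium", "fine", "paper"] = "coarse"
    dt_init: float = Field(1e-6, gt=0)
    dt_min: float = Field(1e-6, gt=0)
    dt_max: float = Field(0.03, gt=0)
    growth: float = Field(2.0, gt=1)
    #: A step whose largest nodal temperature change exceeds this is
    #: rejected and retried with dt halved (transient accuracy control).
    max_dT_per_step: float = Field(1.0, gt=0)
    picard_max: int = Field(1, ge=1, le=5)
    picard_tol: float = Field(1e-6, gt=0)
    em_tol: float = Field(1e-8, gt=0)
    iterative_threshold: int = Field(200_000, gt=0)


class ModeConfig(_Block):
    initial_mode: Literal["nominal", "pretreat_offset", "pretreat_pulse"] = \
        "pretreat_offset"
    electrode_air_offset: float = 2.0
    pretreat_temperature: float = 41.0
    pretreat_length_scale: float = Field(0.5e-3, gt=0)
    pretreat_current_A: float = Field(0.1, ge=0)
    pretreat_duration_s: float = Field(0.3, ge=0)
    #: Reference both evaporation sinks to their body-temperature value,
    #: so they model the heat removed by *increased* evaporation during
    #: the acute heating (the resting evaporative loss is part of the
    #: physiological steady state, not of the treatment energy budget).
    baseline_subtraction: bool = True


class OutputConfig(_Block):
    telemetry_cadence: float = Field(0.05, gt=0)
    write_vtk: bool = False


class RunConfig(_Block):
    """Top-level configuration; every block has paper-default values."""

    schema_version: int = 1
    seed: int = 0
    geometry: GeometryConfig = GeometryConfig()
    materials: MaterialsConfig = MaterialsConfig()
    perfusion: PerfusionConfig = PerfusionConfig()
    evaporation: EvaporationConfig = EvaporationConfig()
    controller: ControllerConfig = ControllerConfig()
    solver: SolverConfig = SolverConfig()
    mode: ModeConfig = ModeConfig()
    output: OutputConfig = OutputConfig()


def load_config(path: str | None = None) -> RunConfig:
    """Load and validate a YAML config; an empty/missing body yields defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data)}")
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig) -> str:
    """Canonical YAML form (sorted keys) — used for hashing and round-trips."""
    return yaml.safe_dump(_plain(config.model_dump()), sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(dump_config(config).encode()).hexdigest()
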