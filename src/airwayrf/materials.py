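"""Physical constants and constitutive laws for airway RF heating.

Everything material-related lives here: the electrical/thermal property
table for the five media in the model (lumen air, blood, airway wall,
lung parenchyma, stainless-steel electrode), the exponential temperature
dependence of tissue electrical conductivity, the air/blood volume
mixture rule used to derive parenchyma properties, the blood-perfusion
coefficients of the Pennes bioheat sink, and the evaporative heat sinks
(alveolar volumetric sink and luminal surface flux).

Units are SI throughout except temperature, which is degrees Celsius
(the governing equations only ever use temperature differences, and the
empirical vapor-property fits below are written in Celsius).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Reference body temperature (deg C).
TBODY_C = 37.0


@dataclass(frozen=True)
class Material:
    """Bulk properties of a single medium.

    sigma0 : electrical conductivity at the reference temperature, S/m
    k      : thermal conductivity, W/(m K)
    c      : specific heat, J/(kg K)
    rho    : density, kg/m^3
    temperature_dependent_sigma : whether sigma follows the exponential
        tissue law (metals and air are held constant).
    """

    name: str
    sigma0: float
    k: float
    c: float
    rho: float
    temperature_dependent_sigma: bool = False

    def __post_init__(self) -> None:
        for attr in ("k", "c", "rho"):
            if getattr(self, attr) <= 0.0:
                raise ValueError(f"{self.name}.{attr} must be positive")
        if self.sigma0 < 0.0:
            raise ValueError(f"{self.name}.sigma0 must be non-negative")


def default_materials() -> dict[str, Material]:
    """Property table at body temperature (37 deg C).

    Electrical conductivities are for soft tissue at ~480 kHz, where
    tissue is essentially resistive; parenchyma is an 80/20 air/blood
    mixture (see :func:`parenchyma_mixture`), with its thermal
    conductivity and density taken from published lung measurements
    rather than from the mixture rule.
    """
    return {
        "air": Material("air", 1e-16, 0.030, 1009.0, 0.995),
        "blood": Material("blood", 0.748, 0.52, 4176.0, 1060.0),
        "trachea": Material("trachea", 0.359, 0.5, 3000.0, 1500.0, True),
        "parenchyma": Material("parenchyma", 0.15, 0.451, 1643.0, 199.0, True),
        "stainless_steel_304": Material(
            "stainless_steel_304", 1.39e6, 16.2, 500.0, 8030.0
        ),
    }


@dataclass(frozen=True)
class MaterialTable:
    """Material set plus the shared conductivity temperature law.

    alpha : fractional conductivity rise per degree C (0.015 = 1.5 %/C)
    T0    : reference temperature of sigma0, deg C
    Tbody : ambient body temperature, deg C
    sigma_clamp_T : temperature above which sigma(T) is held constant.
        Purely a numerical guard for off-nominal parameter sweeps; the
        nominal 65 C control never approaches it.
    """

    materials: dict[str, Material] = field(default_factory=default_materials)
    alpha: float = 0.015
    T0: float = TBODY_C
    Tbody: float = TBODY_C
    sigma_clamp_T: float = 100.0

    def __getitem__(self, name: str) -> Material:
        try:
            return self.materials[name]
        except KeyError:
            raise KeyError(
                f"unknown material {name!r}; known: {sorted(self.materials)}"
            ) from None

    def conductivity(self, name: str, T):
        """Electrical conductivity sigma(T) in S/m.

        Tissues follow sigma0 * exp(alpha * (T - T0)); the electrode
        metal and lumen air are temperature-independent.  Accepts a
        scalar or an ndarray of temperatures.
        """
        mat = self[name]
        T = np.asarray(T, dtype=float)
        if not np.all(np.isfinite(T)):
            raise ValueError("temperature must be finite")
        if not mat.temperature_dependent_sigma:
            return np.broadcast_to(np.float64(mat.sigma0), T.shape).copy() \
                if T.shape else float(mat.sigma0)
        Tc = np.minimum(T, self.sigma_clamp_T)
        sigma = mat.sigma0 * np.exp(self.alpha * (Tc - self.T0))
        return sigma if sigma.shape else float(sigma)


def conductivity_at_temperature(material: str, T, table: MaterialTable | None = None):
    """Convenience wrapper: sigma(T) for a named material."""
    return (table or MaterialTable()).conductivity(material, T)


def parenchyma_mixture(air_fraction: float, table: MaterialTable | None = None) -> dict:
    """Volume-weighted air/blood average for parenchyma properties.

    Returns a dict with sigma0, k, c, rho.  The default property table
    carries measured lung values for k and rho; this rule is exposed for
    sensitivity studies and reproduces the tabulated sigma0 (0.8 air /
    0.2 blood -> 0.2 * 0.748 ~= 0.15 S/m, air being non-conducting).
    """
    if not 0.0 <= air_fraction <= 1.0:
        raise ValueError("air_fraction must lie in [0, 1]")
    table = table or MaterialTable()
    air, blood = table["air"], table["blood"]
    w_a, w_b = air_fraction, 1.0 - air_fraction
    return {
        "sigma0": w_a * air.sigma0 + w_b * blood.sigma0,
        "k": w_a * air.k + w_b * blood.k,
        "c": w_a * air.c + w_b * blood.c,
        "rho": w_a * air.rho + w_b * blood.rho,
    }


@dataclass(frozen=True)
class PerfusionParams:
    """Blood-perfusion coefficients of the Pennes sink rho_b c_b w (T - Tbody).

    omega_parenchyma : 1/s, cardiac output spread over lung volume
        (5.25 L/min over 4.3 L ~= 0.02 1/s).
    omega_airway_wall : 1/s, resting skeletal-muscle perfusion estimate.
    """

    omega_parenchyma: float = 0.02
    omega_airway_wall: float = 0.6e-3
    rho_blood: float = 1060.0
    c_blood: float = 4176.0

    def __post_init__(self) -> None:
        if self.omega_parenchyma < 0 or self.omega_airway_wall < 0:
            raise ValueError("perfusion coefficients must be non-negative")


def perfusion_coefficient(cardiac_output_m3_s: float, perfused_volume_m3: float) -> float:
    """omega = blood volume flow per unit perfused tissue volume, 1/s."""
    if cardiac_output_m3_s < 0.0:
        raise ValueError("cardiac output must be non-negative")
    if perfused_volume_m3 <= 0.0:
        raise ValueError("perfused volume must be positive")
    return cardiac_output_m3_s / perfused_volume_m3


@dataclass(frozen=True)
class EvaporationParams:
    """Parameters of the diffusive evaporation model.

    The volumetric parenchymal sink treats each alveolus as a moist
    sphere losing water vapor by diffusion; the per-alveolus loss is
    scaled by the alveolar number density N_alv / V_lung.  The luminal
    sink is the same physics reduced to a planar diffusion film of
    thickness delta_lum over the inner airway surface.

    hfg    : latent heat of vaporization, J/kg (water at ~42 C)
    d_alv  : alveolus diameter, m
    M      : molar mass of water, kg/mol
    Hr     : relative humidity of alveolar/luminal air (0..1)
    N_alv  : alveoli per lung
    V_lung : total lung volume, m^3
    cs_coeff : (A, B) of the saturation concentration fit Cs = A exp(B T)
    d_coeff  : (a, b) of the vapor diffusivity fit D = (a T + b) * d_scale
    delta_lum : luminal diffusion-film thickness, m
    alveolar_ratio_scale : multiplier on N_alv/V_lung for sensitivity sweeps
    """

    hfg: float = 2.4e6
    d_alv: float = 0.3e-3
    M: float = 0.018
    Hr: float = 0.95
    N_alv: float = 3e8
    V_lung: float = 4.3e-3
    cs_coeff: tuple[float, float] = (0.2821, 0.0588)
    d_coeff: tuple[float, float] = (0.171, 20.84)
    d_scale: float = 1e-6
    delta_lum: float = 1e-3
    alveolar_ratio_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.Hr <= 1.0:
            raise ValueError("relative humidity Hr must lie in [0, 1]")
        for attr in ("hfg", "d_alv", "M", "N_alv", "V_lung", "delta_lum",
                     "alveolar_ratio_scale"):
            if getattr(self, attr) <= 0.0:
                raise ValueError(f"{attr} must be positive")


def water_vapor_diffusivity(T, params: EvaporationParams | None = None):
    """Diffusion coefficient of water vapor in air, m^2/s (empirical fit)."""
    p = params or EvaporationParams()
    a, b = p.d_coeff
    return (a * np.asarray(T, dtype=float) + b) * p.d_scale


def saturation_concentration(T, params: EvaporationParams | None = None):
    """Saturation concentration of water vapor, mol/m^3 (empirical fit).

    The molar unit is inferred from the presence of the molar mass M in
    the evaporation rate expression; the fit coefficients reproduce
    published saturated-vapor tables over the physiological range.
    """
    p = params or EvaporationParams()
    A, B = p.cs_coeff
    return A * np.exp(B * np.asarray(T, dtype=float))


def evaporative_power_per_alveolus(T, params: EvaporationParams | None = None):
    """Evaporative heat loss of a single alveolus, W.

    hfg * 2 pi d * M * D(T) * (1 - Hr) * Cs(T): steady diffusive loss
    from a moist sphere of diameter d into air at humidity Hr.
    """
    p = params or EvaporationParams()
    return (
        p.hfg * 2.0 * math.pi * p.d_alv * p.M
        * water_vapor_diffusivity(T, p) * (1.0 - p.Hr)
        * saturation_concentration(T, p)
    )


def evaporative_sink_parenchyma(T, params: EvaporationParams | None = None):
    """Volumetric evaporative heat sink in parenchyma, W/m^3 (>= 0).

    The per-alveolus loss multiplied by the alveolar number density
    N_alv / V_lung (alveoli assumed uniformly distributed).
    """
    p = params or EvaporationParams()
    density = p.N_alv / p.V_lung * p.alveolar_ratio_scale
    return evaporative_power_per_alveolus(T, p) * density


def evaporative_flux_luminal(T, params: EvaporationParams | None = None):
    """Evaporative heat flux on the luminal (air/wall) surface, W/m^2 (>= 0).

    Planar diffusion-film form of the alveolar expression: vapor
    diffuses across a film of thickness delta_lum from the saturated
    wet surface into luminal air at humidity Hr.
    """
    p = params or EvaporationParams()
    return (
        p.hfg * p.M * water_vapor_diffusivity(T, p)
        * (1.0 - p.Hr) * saturation_concentration(T, p) / p.delta_lum
    )


def scale_alveolar_ratio(params: EvaporationParams, multiplier: float) -> EvaporationParams:
    """Return params with the alveolar surface-to-volume ratio scaled."""
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return replace(params, alveolar_ratio_scale=params.alveolar_ratio_scale * multiplier)
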