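"""Constant-pressure dead-end cake filtration.

Darcy's law for an incompressible cake growing at constant pressure drop:

    dV/dt = dP * A / (mu * (alpha * w * V / A + R_m))

with specific cake resistance alpha from Carman-Kozeny,

    alpha = 180 * (1 - eps) / (rho_s * x_sv^2 * eps^3),

w the dry cake mass deposited per unit filtrate volume, and x_sv the
sphericity-scaled Sauter mean diameter of the suspension PSD. Filtration is
halted at *dryland* (free slurry liquid exhausted; cake saturated with
mother liquor) or continued to *breakthrough*, modelled as bookkeeping
removal of pore liquor down to a residual fraction of the void volume (no
deliquoring physics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .materials import (
    DegenerateInputError,
    LiquidState,
    MaterialSystem,
    mixture_density,
    mixture_viscosity,
)
from .psd import ParticleSizeDistribution, sauter_mean

__all__ = [
    "OperatingConditions",
    "SuspensionState",
    "FiltrationResult",
    "CakeState",
    "carman_kozeny_alpha",
    "permeability_from_alpha",
    "constant_pressure_filtration",
    "hindered_settling_velocity",
    "make_initial_wash_cake",
]

G_ACCEL = 9.80665  # m/s^2


@dataclass(frozen=True)
class OperatingConditions:
    """Equipment and operating parameters (SI units internally)."""

    pressure_drop: float  # Pa
    filter_diameter: float  # m
    media_resistance: float = 0.0  # 1/m
    temperature: float = 25.0  # degC
    endpoint_mode: str = "dryland"
    breakthrough_residual_fraction: float = 0.10
    settling_enabled: bool = False
    settling_exponent: float = 4.65  # Richardson-Zaki n

    def __post_init__(self) -> None:
        if not self.pressure_drop > 0:
            raise ValueError("pressure_drop must be > 0")
        if not self.filter_diameter > 0:
            raise ValueError("filter_diameter must be > 0")
        if self.media_resistance < 0:
            raise ValueError("media_resistance must be >= 0")
        if self.endpoint_mode not in ("dryland", "breakthrough"):
            raise ValueError(f"unknown endpoint_mode {self.endpoint_mode!r}")
        if not 0 < self.breakthrough_residual_fraction < 1:
            raise ValueError("breakthrough_residual_fraction must lie in (0, 1)")

    @property
    def filter_area(self) -> float:
        return math.pi * self.filter_diameter**2 / 4.0


@dataclass
class SuspensionState:
    """The slurry fed to the filter. cake_porosity is an empirical input."""

    solid_mass: float  # kg
    psd: ParticleSizeDistribution
    liquid: LiquidState
    cake_porosity: float

    def __post_init__(self) -> None:
        if not self.solid_mass > 0:
            raise ValueError("solid_mass must be > 0")
        if not 0 < self.cake_porosity < 1:
            raise ValueError("cake_porosity must lie in (0, 1)")


@dataclass
class FiltrationResult:
    filtration_time: float  # s
    times: np.ndarray  # s
    filtrate_volumes: np.ndarray  # m^3
    flow_rates: np.ndarray  # m^3/s
    specific_cake_resistance: float  # m/kg
    cake_volume: float  # m^3
    cake_height: float  # m
    residual_liquid_volume: float  # m^3
    residual_liquid: LiquidState
    endpoint_mode: str = "dryland"
    cake_solids_per_filtrate_volume: float = 0.0  # w, kg/m^3
    liquid_viscosity: float = 0.0  # Pa s
    liquid_density: float = 0.0  # kg/m^3


@dataclass
class CakeState:
    """Layered cake. Index 0 is layer 1 (top, wash inlet); the last layer
    adjoins the filter medium. Layers have equal thickness and equal initial
    void volume."""

    solid_mass: np.ndarray  # (n_layers,) kg
    psds: list  # list[ParticleSizeDistribution]
    liquids: list  # list[LiquidState]
    porosity: np.ndarray  # (n_layers,)
    area: float  # m^2
    height: float  # m
    saturation: np.ndarray  # (n_layers,) fraction of void holding liquid

    def __post_init__(self) -> None:
        self.solid_mass = np.asarray(self.solid_mass, dtype=float)
        self.porosity = np.asarray(self.porosity, dtype=float)
        self.saturation = np.asarray(self.saturation, dtype=float)
        n = self.solid_mass.size
        if not (len(self.psds) == len(self.liquids) == self.porosity.size == n):
            raise ValueError("per-layer fields must have equal length")
        if np.any((self.porosity <= 0) | (self.porosity >= 1)):
            raise ValueError("porosity must lie in (0, 1) per layer")
        if np.any((self.saturation < 0) | (self.saturation > 1)):
            raise ValueError("saturation must lie in [0, 1]")

    @property
    def n_layers(self) -> int:
        return self.solid_mass.size

    @property
    def layer_volume(self) -> float:
        """Bulk volume of one layer (fixed geometry), m^3."""
        return self.area * self.height / self.n_layers

    def void_volumes(self, crystal_density: float) -> np.ndarray:
        """Per-layer void volume from fixed geometry and current solid, m^3."""
        return self.layer_volume - self.solid_mass / crystal_density

    def copy(self) -> "CakeState":
        return CakeState(
            self.solid_mass.copy(),
            [p.copy() for p in self.psds],
            [liq.copy() for liq in self.liquids],
            self.porosity.copy(),
            self.area,
            self.height,
            self.saturation.copy(),
        )


def carman_kozeny_alpha(eps: float, x_sv: float, rho_s: float) -> float:
    """Specific (mass-based) cake resistance, m/kg.

    alpha = 180 * (1 - eps) / (rho_s * x_sv^2 * eps^3).
    """
    if not 0 < eps < 1:
        raise ValueError("porosity must lie in (0, 1)")
    if not (x_sv > 0 and rho_s > 0):
        raise ValueError("x_sv and rho_s must be > 0")
    return 180.0 * (1.0 - eps) / (rho_s * x_sv**2 * eps**3)


def permeability_from_alpha(alpha: float, eps: float, rho_s: float) -> float:
    """Cake permeability k = 1 / (alpha * rho_s * (1 - eps)), m^2."""
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if not eps < 1:
        raise ValueError("eps must be < 1")
    return 1.0 / (alpha * rho_s * (1.0 - eps))


def hindered_settling_velocity(
    d: float,
    rho_s: float,
    rho_l: float,
    mu: float,
    solid_volume_fraction: float,
    n: float = 4.65,
) -> float:
    """Richardson-Zaki hindered settling: u = u_Stokes * (1 - phi_v)^n, m/s."""
    if not 0 <= solid_volume_fraction < 1:
        raise ValueError("solid_volume_fraction must lie in [0, 1)")
    u_stokes = (rho_s - rho_l) * G_ACCEL * d**2 / (18.0 * mu)
    return u_stokes * (1.0 - solid_volume_fraction) ** n


def _closed_form_time(V, mu, alpha, w, R_m, A, dP):
    """Constant-pressure quadratic t(V)."""
    return mu * alpha * w * V**2 / (2.0 * A**2 * dP) + mu * R_m * V / (A * dP)


def constant_pressure_filtration(
    suspension: SuspensionState,
    conditions: OperatingConditions,
    system: MaterialSystem,
    n_samples: int = 201,
) -> tuple[FiltrationResult, CakeState]:
    """Integrate Darcy constant-pressure filtration to the configured endpoint.

    Returns the trajectory plus a single-layer CakeState holding the
    residual mother liquor. With ``settling_enabled`` the Richardson-Zaki
    hindered settling velocity (at the Sauter size) pre-concentrates the
    depositing slurry: the effective solids load per filtrate volume is
    raised by the ratio of settling to mean filtrate velocity.
    """
    A = conditions.filter_area
    dP = conditions.pressure_drop
    rho_s = system.solute.crystal_density
    eps = suspension.cake_porosity
    liquid = suspension.liquid
    if liquid.total_mass <= 0:
        raise DegenerateInputError("suspension carries no liquid")

    mu = mixture_viscosity(liquid, system)
    rho_l = mixture_density(liquid, system)
    x_sv = sauter_mean(suspension.psd, system.solute.sphericity)
    alpha = carman_kozeny_alpha(eps, x_sv, rho_s)

    V_solid = suspension.solid_mass / rho_s
    V_cake = V_solid / (1.0 - eps)
    V_void = V_cake - V_solid
    L = V_cake / A
    V_liq = liquid.total_mass / rho_l
    V_end = V_liq - V_void  # filtrate collected at dryland
    if V_end <= 0:
        raise ValueError(
            "suspension liquid does not fill the cake voids; dryland unreachable"
        )
    w = suspension.solid_mass / V_end

    if conditions.settling_enabled:
        phi_v = V_solid / (V_solid + V_liq)
        u_h = hindered_settling_velocity(
            x_sv, rho_s, rho_l, mu, phi_v, conditions.settling_exponent
        )
        t0 = _closed_form_time(V_end, mu, alpha, w, conditions.media_resistance, A, dP)
        u_mean = V_end / (A * t0)
        w = w * (1.0 + max(u_h, 0.0) / u_mean)

    R_m = conditions.media_resistance
    t_end = _closed_form_time(V_end, mu, alpha, w, R_m, A, dP)

    def rhs(t, y):
        V = y[0]
        return [dP * A / (mu * (alpha * w * V / A + R_m))]

    t_eval = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(rhs, (0.0, t_end), [0.0], t_eval=t_eval, rtol=1e-10, atol=V_end * 1e-12)
    if not sol.success:
        raise RuntimeError(f"filtration ODE solver failed: {sol.message}")
    V_traj = sol.y[0]
    Q_traj = np.array([rhs(t, [v])[0] for t, v in zip(sol.t, V_traj)])

    frac = liquid.mass_fractions()
    if conditions.endpoint_mode == "breakthrough":
        residual_volume = conditions.breakthrough_residual_fraction * V_void
        saturation = conditions.breakthrough_residual_fraction
    else:
        residual_volume = V_void
        saturation = 1.0
    residual_mass = residual_volume * rho_l
    residual = LiquidState(
        mass_solute=residual_mass * frac["solute"],
        mass_crystallization_solvent=residual_mass * frac["crystallization_solvent"],
        mass_wash_solvent=residual_mass * frac["wash_solvent"],
        temperature=liquid.temperature,
    )

    result = FiltrationResult(
        filtration_time=float(sol.t[-1]),
        times=sol.t,
        filtrate_volumes=V_traj,
        flow_rates=Q_traj,
        specific_cake_resistance=alpha,
        cake_volume=V_cake,
        cake_height=L,
        residual_liquid_volume=residual_volume,
        residual_liquid=residual,
        endpoint_mode=conditions.endpoint_mode,
        cake_solids_per_filtrate_volume=w,
        liquid_viscosity=mu,
        liquid_density=rho_l,
    )
    cake = CakeState(
        solid_mass=np.array([suspension.solid_mass]),
        psds=[suspension.psd.copy()],
        liquids=[residual],
        porosity=np.array([eps]),
        area=A,
        height=L,
        saturation=np.array([saturation]),
    )
    return result, cake


def make_initial_wash_cake(
    filtration: tuple[FiltrationResult, CakeState], n_layers: int
) -> CakeState:
    """Split the filtered cake into equal-thickness layers for washing.

    Solid mass, PSD and residual liquid are divided uniformly; layer 1 is
    the wash inlet. Saturation follows the filtration endpoint (1 at
    dryland, the residual fraction at breakthrough).
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    _, cake = filtration
    if cake.n_layers != 1:
        raise ValueError("expected the single-layer cake from filtration")
    liq = cake.liquids[0]
    n = n_layers

    def split_liquid() -> LiquidState:
        return LiquidState(
            liq.mass_solute / n,
            liq.mass_crystallization_solvent / n,
            liq.mass_wash_solvent / n,
            liq.temperature,
        )

    return CakeState(
        solid_mass=np.full(n, cake.solid_mass[0] / n),
        psds=[cake.psds[0].scaled(1.0 / n) for _ in range(n)],
        liquids=[split_liquid() for _ in range(n)],
        porosity=np.full(n, cake.porosity[0]),
        area=cake.area,
        height=cake.height,
        saturation=np.full(n, cake.saturation[0]),
    )
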