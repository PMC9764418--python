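"""The six filter-cake washing models.

Case 1 (frozen solid phase) and case 2 (solid-liquid equilibrium) each come
in three transport flavours:

* ``a`` - pure displacement: the wash pushes the mother liquor out as a
  plug; filtrate composition is a piecewise constant in the wash ratio.
* ``b`` - pure dilution: the cake liquid is one perfectly mixed holdup.
* ``c`` - diffusion-dispersion: either a 1-D axial advection-dispersion
  PDE (plug-flow form) or a cascade of N well-mixed layers
  (tanks-in-series form; N = 10 reproduces the layered-cake picture).

All balances are integrated in wash-ratio space: with volume-matched
outflow the flow rate cancels from the species balances, so wash curves
depend only on W_r = V_w / V_v. Hydraulics (constant-pressure Darcy or
constant flow) only set the time axis t(W_r) and the kinetic-relaxation
rates; the case-2 equilibrium enforcement makes accepted runs insensitive
to the latter.

Case-2 dissolution/deposition is driven by the binary solubility curve:
each holdup's liquid is compared with c_sat at its local wash-solvent
fraction and relaxed to equilibrium, either kinetically (power-law rate
with auto-escalated rate constant) or by an instantaneous algebraic flash.
Solid updates go through the PSD module (McCabe delta-L), which dissolves
fines first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .filtration import CakeState, carman_kozeny_alpha
from .materials import (
    BinarySolubilityCurve,
    LiquidState,
    MaterialSystem,
    csat_lookup,
    mixture_viscosity,
)
from .psd import (
    DissolutionKinetics,
    InfeasibleDissolutionError,
    ParticleSizeDistribution,
    advance_growth_dissolution,
    sauter_mean,
    shift_to_exchange,
    specific_surface_area,
    uniform_dissolve,
)

__all__ = [
    "WashProtocol",
    "WashCurve",
    "EquilibriumWarning",
    "wash_ratio",
    "wr_from_time",
    "axial_dispersion_coefficient",
    "nernst_brunner_rate",
    "wash_displacement",
    "wash_dilution",
    "wash_cstr_cascade",
    "wash_dispersion_pde",
    "mass_balance_audit",
]

SPECIES = ("solute", "crystallization_solvent", "wash_solvent")


class EquilibriumWarning(UserWarning):
    """Kinetic relaxation could not keep |sigma| within tolerance."""


@dataclass(frozen=True)
class WashProtocol:
    """How the wash is run and discretized."""

    wash_ratio_max: float = 2.0
    flow_mode: str = "constant_pressure"
    wash_flow_rate: float = 1e-7  # m^3/s, constant_flow mode
    n_layers: int = 10
    molecular_diffusivity: float = 1e-9  # m^2/s
    dispersion_model: str = "fixed_D"  # or "correlation"
    outflow_matched: bool = True
    wr_grid_step: float = 0.01
    wr_substep: float = 0.005  # kinetics operator-splitting step
    equilibrium_tol: float = 1e-3  # max |sigma| for accepted case-2 runs
    n_nodes: int = 200  # dispersion PDE grid
    checkpoints: tuple = ()

    def __post_init__(self) -> None:
        if not self.wash_ratio_max > 0:
            raise ValueError("wash_ratio_max must be > 0")
        if self.flow_mode not in ("constant_pressure", "constant_flow"):
            raise ValueError(f"unknown flow_mode {self.flow_mode!r}")
        if not self.molecular_diffusivity > 0:
            raise ValueError("molecular_diffusivity must be > 0")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")

    def grid(self) -> np.ndarray:
        n = max(1, round(self.wash_ratio_max / self.wr_grid_step))
        return np.linspace(0.0, self.wash_ratio_max, n + 1)

    def checkpoint_list(self) -> list[float]:
        if self.checkpoints:
            return sorted(set(float(c) for c in self.checkpoints))
        stops = list(np.arange(0.0, self.wash_ratio_max + 1e-9, 0.5))
        if stops[-1] < self.wash_ratio_max - 1e-9:
            stops.append(self.wash_ratio_max)
        return stops


@dataclass
class WashCurve:
    """Wash-curve outputs indexed by wash ratio.

    ``cumulative_solid_mass_change`` is positive for deposition and
    negative for dissolution. ``c_over_c0`` is the filtrate solute
    concentration (mass per liquid volume) over the mother-liquor value at
    wash start. Checkpoint dicts map wash ratio -> per-layer snapshots.
    """

    wash_ratio: np.ndarray
    time: np.ndarray
    filtrate_mass_fractions: dict
    c_over_c0: np.ndarray
    cumulative_filtrate_mass: dict
    cumulative_solid_mass_change: np.ndarray
    psd_checkpoints: dict = field(default_factory=dict)
    porosity_checkpoints: dict = field(default_factory=dict)
    saturation_checkpoints: dict = field(default_factory=dict)
    w_wash_checkpoints: dict = field(default_factory=dict)
    final_cake: CakeState | None = None
    fed_wash_mass: float = 0.0  # kg of wash solvent supplied
    metadata: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        data = {"wash_ratio": self.wash_ratio, "time_s": self.time, "c_over_c0": self.c_over_c0}
        for sp in SPECIES:
            data[f"x_{sp}"] = self.filtrate_mass_fractions[sp]
            data[f"filtrate_{sp}_kg"] = self.cumulative_filtrate_mass[sp]
        data["solid_mass_change_kg"] = self.cumulative_solid_mass_change
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# small operations


def wash_ratio(V_w: float, V_v: float) -> float:
    """W_r = volume of wash fed / void volume of the cake."""
    if not V_v > 0:
        raise ValueError("void volume must be > 0")
    return V_w / V_v


def wr_from_time(t: float, u_s: float, L: float, eps: float) -> float:
    """W_r from elapsed time, superficial velocity and cake height."""
    if not (L > 0 and 0 < eps < 1):
        raise ValueError("need L > 0 and porosity in (0, 1)")
    return u_s * t / (eps * L)


def axial_dispersion_coefficient(u_s: float, d_p: float, D: float, mode: str = "fixed_D") -> float:
    """Axial dispersion coefficient D_L, m^2/s.

    ``fixed_D`` returns the molecular diffusivity; ``correlation`` uses the
    packed-bed form D_L = D + 0.5 * u_s * d_p.
    """
    if u_s < 0:
        raise ValueError("u_s must be >= 0")
    if mode == "fixed_D":
        return D
    if mode == "correlation":
        return D + 0.5 * u_s * d_p
    raise ValueError(f"unknown dispersion mode {mode!r}")


def nernst_brunner_rate(
    liquid: LiquidState,
    psd: ParticleSizeDistribution,
    curve: BinarySolubilityCurve,
    D: float,
    boundary_layer: float,
    solid_mass: float,
    system: MaterialSystem,
) -> float:
    """Nernst-Brunner dissolution rate dm/dt = (D/delta) A_tot (c_sat - c), kg/s.

    Concentrations are per liquid volume; positive = dissolution into the
    liquid, negative = deposition. Zero exactly at saturation.
    """
    if not boundary_layer > 0:
        raise ValueError("boundary_layer must be > 0")
    if solid_mass <= 0 or psd.total_mass <= 0:
        return 0.0
    from .materials import mixture_density

    rho_l = mixture_density(liquid, system)
    V_liq = liquid.total_mass / rho_l
    c = liquid.mass_solute / V_liq
    csat = csat_lookup(curve, liquid.w_wash) * liquid.solvent_mass / V_liq
    a_tot = specific_surface_area(psd, system.solute.crystal_density, system.solute.sphericity)
    return (D / boundary_layer) * a_tot * solid_mass * (csat - c)


# ---------------------------------------------------------------------------
# shared helpers


def _cake_void_volume(cake: CakeState, rho_s: float) -> float:
    return float(np.sum(cake.void_volumes(rho_s)))


def _liquid_masses(cake: CakeState) -> np.ndarray:
    """(3, n_layers) species masses of the layer liquids."""
    return np.array(
        [
            [liq.mass_solute for liq in cake.liquids],
            [liq.mass_crystallization_solvent for liq in cake.liquids],
            [liq.mass_wash_solvent for liq in cake.liquids],
        ]
    )


def _time_axis(grid: np.ndarray, cake: CakeState, protocol: WashProtocol,
               system: MaterialSystem, V_v: float, mean_w_wash: np.ndarray | None) -> np.ndarray:
    """Map the W_r grid to time via the configured hydraulics."""
    if protocol.flow_mode == "constant_flow":
        return grid * V_v / protocol.wash_flow_rate
    # constant pressure: Darcy through the formed cake with evolving viscosity
    meta = getattr(cake, "_hydraulics", None)
    dP, A, R_m = 5e4, cake.area, 0.0
    if meta:
        dP, R_m = meta["pressure_drop"], meta["media_resistance"]
    alpha = carman_kozeny_alpha(
        float(np.mean(cake.porosity)),
        sauter_mean(_combined_psd(cake), system.solute.sphericity),
        system.solute.crystal_density,
    )
    m_c = float(np.sum(cake.solid_mass))
    if mean_w_wash is None:
        mean_w_wash = np.linspace(0.0, 1.0, grid.size)
    mu = np.array(
        [
            mixture_viscosity(
                LiquidState(0.0, 1.0 - w, w), system.solvents
            )
            for w in np.clip(mean_w_wash, 0.0, 1.0)
        ]
    )
    Q = dP * A / (mu * (alpha * m_c / A + R_m))
    dt_dwr = V_v / Q
    t = np.concatenate(([0.0], np.cumsum(0.5 * (dt_dwr[1:] + dt_dwr[:-1]) * np.diff(grid))))
    return t


def _combined_psd(cake: CakeState) -> ParticleSizeDistribution:
    """Merge the per-layer PSDs onto a common grid (for cake-level stats)."""
    psds = [p for p in cake.psds if p.total_mass > 0]
    if not psds:
        return cake.psds[0].copy()
    base = psds[0]
    if all(
        p.bin_edges.size == base.bin_edges.size and np.allclose(p.bin_edges, base.bin_edges)
        for p in psds
    ):
        total = np.sum([p.bin_mass for p in psds], axis=0)
        return ParticleSizeDistribution(base.bin_edges.copy(), total)
    # fall back: rebin everything onto the widest grid via zero-shift
    from .psd import _shift_and_rebin  # conservative overlap rebin

    edges = max(psds, key=lambda p: p.bin_edges[-1]).bin_edges
    total = np.zeros(edges.size - 1)
    out_lo, out_hi = edges[:-1], edges[1:]
    from .psd import _quartic_overlap

    for p in psds:
        a, b = p.bin_edges[:-1], p.bin_edges[1:]
        mask = p.bin_mass > 0
        for ai, bi, mi in zip(a[mask], b[mask], p.bin_mass[mask]):
            dens = 4.0 * mi / (bi**4 - ai**4)
            total += dens * _quartic_overlap(ai, bi, out_lo, out_hi)
    return ParticleSizeDistribution(edges, total)


# ---------------------------------------------------------------------------
# models a: displacement


def wash_displacement(
    cake: CakeState,
    protocol: WashProtocol,
    system: MaterialSystem,
    dissolve: bool = False,
) -> WashCurve:
    """Pure displacement washing (model 1a; model 2a with ``dissolve``).

    The wash front displaces the mother liquor as a plug: the filtrate is
    mother liquor for W_r < 1 and wash input thereafter. With ``dissolve``
    the wash liquor in the cake leaves saturated at c_sat(w_wash = 1),
    removing solid homogeneously (uniform diameter scaling) up to one cake
    volume of wash.
    """
    if np.any(cake.saturation < 1.0 - 1e-9):
        raise ValueError("displacement washing requires a dryland (saturated) cake")
    rho_s = system.solute.crystal_density
    rho_w = system.wash_solvent.density
    V_v = _cake_void_volume(cake, rho_s)
    grid = protocol.grid()
    masses = _liquid_masses(cake).sum(axis=1)  # total mother liquor species
    m_ml = masses.sum()
    from .materials import mixture_density

    ml = LiquidState(*masses)
    rho_ml = mixture_density(ml, system)
    frac_ml = masses / m_ml

    csat_w = csat_lookup(system.curve, 1.0) if (dissolve and system.curve is not None) else 0.0
    solid0 = float(np.sum(cake.solid_mass))
    m_diss_full = csat_w * rho_w * V_v
    if dissolve and m_diss_full > solid0:
        raise InfeasibleDissolutionError(
            f"displacement wash would dissolve {m_diss_full} kg from {solid0} kg of solid"
        )

    before = grid < 1.0
    fractions = {
        "solute": np.where(before, frac_ml[0], 0.0),
        "crystallization_solvent": np.where(before, frac_ml[1], 0.0),
        "wash_solvent": np.where(before, frac_ml[2], 1.0),
    }
    c_over_c0 = np.where(before, 1.0, 0.0)

    ml_out = np.minimum(grid, 1.0) * V_v * rho_ml  # displaced mother liquor mass
    wash_out = np.maximum(grid - 1.0, 0.0) * V_v * rho_w
    cumulative = {
        "solute": ml_out * frac_ml[0],
        "crystallization_solvent": ml_out * frac_ml[1],
        "wash_solvent": ml_out * frac_ml[2] + wash_out,
    }
    m_diss = m_diss_full * np.minimum(grid, 1.0) if dissolve else np.zeros_like(grid)
    solid_change = -m_diss

    combined = _combined_psd(cake)
    psd_cp, poro_cp, sat_cp, ww_cp = {}, {}, {}, {}
    layer_bulk = cake.layer_volume
    for wr in protocol.checkpoint_list():
        md = float(np.interp(wr, grid, m_diss))
        frac_per_layer = md / solid0
        psds = [uniform_dissolve(p, p.total_mass * frac_per_layer) for p in cake.psds]
        psd_cp[wr] = psds
        poro_cp[wr] = 1.0 - (cake.solid_mass * (1.0 - frac_per_layer) / rho_s) / layer_bulk
        sat_cp[wr] = np.ones(cake.n_layers)
        ww_cp[wr] = np.full(cake.n_layers, min(wr, 1.0))

    # final cake: voids hold (1 - W_r) mother liquor + wash (saturated if dissolving)
    wr_end = grid[-1]
    ml_left = max(1.0 - wr_end, 0.0) * V_v * rho_ml
    wash_in_cake = min(wr_end, 1.0) * V_v * rho_w
    final_liquid_tot = np.array(
        [
            ml_left * frac_ml[0] + m_diss[-1],
            ml_left * frac_ml[1],
            ml_left * frac_ml[2] + wash_in_cake,
        ]
    )
    n = cake.n_layers
    frac_solid_diss = m_diss[-1] / solid0
    final = CakeState(
        solid_mass=cake.solid_mass * (1.0 - frac_solid_diss),
        psds=[uniform_dissolve(p, p.total_mass * frac_solid_diss) for p in cake.psds],
        liquids=[LiquidState(*(final_liquid_tot / n)) for _ in range(n)],
        porosity=1.0 - (cake.solid_mass * (1.0 - frac_solid_diss) / rho_s) / layer_bulk,
        area=cake.area,
        height=cake.height,
        saturation=np.ones(n),
    )
    time = _time_axis(grid, cake, protocol, system, V_v, np.minimum(grid, 1.0))
    return WashCurve(
        wash_ratio=grid,
        time=time,
        filtrate_mass_fractions=fractions,
        c_over_c0=c_over_c0,
        cumulative_filtrate_mass=cumulative,
        cumulative_solid_mass_change=solid_change,
        psd_checkpoints=psd_cp,
        porosity_checkpoints=poro_cp,
        saturation_checkpoints=sat_cp,
        w_wash_checkpoints=ww_cp,
        final_cake=final,
        fed_wash_mass=float(wr_end * V_v * rho_w),
        metadata={"model": "2a" if dissolve else "1a", "max_abs_sigma": 0.0},
    )


# ---------------------------------------------------------------------------
# models b/c: well-mixed cascade engine (N = 1 is pure dilution)


def _flow_propagator(N: int, V_layers: np.ndarray, V_v: float, rho_w: float, h: float):
    """Exact affine propagator for one W_r step of the cascade balances.

    States: species masses per layer (3N, volume-concentration outflow) then
    cumulative filtrate masses (3). Inlet is pure wash solvent.
    """
    n_states = 3 * N + 3
    A = np.zeros((n_states + 1, n_states + 1))
    b = np.zeros(n_states)
    for j in range(3):
        for i in range(N):
            k = 3 * i + j
            A[k, k] = -V_v / V_layers[i]
            if i > 0:
                A[k, 3 * (i - 1) + j] = V_v / V_layers[i - 1]
        A[3 * N + j, 3 * (N - 1) + j] = V_v / V_layers[N - 1]
    b[2] = V_v * rho_w  # wash solvent into layer 1
    A[:n_states, -1] = b
    return expm(A * h)


def _apply(P: np.ndarray, y: np.ndarray) -> np.ndarray:
    aug = np.concatenate([y, [1.0]])
    return (P @ aug)[:-1]


class _CascadeRun:
    """Stateful cascade integration shared by models 1b/2b/1c(tanks)/2c."""

    def __init__(self, cake, protocol, system, kinetics):
        self.cake = cake.copy()
        self.protocol = protocol
        self.system = system
        self.kinetics = kinetics
        self.rho_s = system.solute.crystal_density
        self.rho_w = system.wash_solvent.density
        self.N = cake.n_layers
        self.V_layers = cake.void_volumes(self.rho_s)  # flow volumes, held fixed
        self.V_v = float(self.V_layers.sum())
        m = _liquid_masses(cake)  # (3, N)
        self.sat0 = cake.saturation.copy()
        self.y = np.concatenate([m.T.ravel(), np.zeros(3)])
        liq_vol0 = float(np.sum(self.sat0 * self.V_layers))
        self.c0 = m[0].sum() / liq_vol0  # mother-liquor solute conc, kg/m^3
        self.solid0 = float(np.sum(cake.solid_mass))
        self.max_abs_sigma = 0.0
        self.tol = protocol.equilibrium_tol
        self.fed = 0.0  # kg wash solvent supplied
        self.fill = np.zeros(self.N)  # rewetting progress per layer

    # -- state views -------------------------------------------------------
    def layer_masses(self) -> np.ndarray:
        return self.y[: 3 * self.N].reshape(self.N, 3)

    def layer_liquid(self, i: int) -> LiquidState:
        m = self.layer_masses()[i]
        return LiquidState(m[0], m[1], m[2])

    def outlet_concentrations(self) -> np.ndarray:
        return self.layer_masses()[-1] / self.V_layers[-1]

    # -- rewetting (breakthrough feeds) ------------------------------------
    def rewet_wr(self) -> float:
        return float(np.sum((1.0 - self.sat0) * self.V_layers) / self.V_v)

    def rewet_step(self, dwr: float) -> None:
        """Fill layers top-down with wash solvent; no outflow."""
        vol = dwr * self.V_v
        m = self.layer_masses()
        for i in range(self.N):
            deficit = (1.0 - self.sat0[i]) * self.V_layers[i] * (1.0 - self.fill[i])
            take = min(vol, deficit)
            if take > 0:
                m[i, 2] += take * self.rho_w
                self.fill[i] += take / max((1.0 - self.sat0[i]) * self.V_layers[i], 1e-300)
                vol -= take
                self.fed += take * self.rho_w
            if vol <= 0:
                break
        self.y[: 3 * self.N] = m.ravel()

    # -- equilibrium exchange ----------------------------------------------
    def exchange(self, dt_real: float) -> None:
        """Relax every layer's liquid toward the solubility curve.

        Flash mode solves the solid/liquid partition algebraically (the
        wash-solvent fraction is unchanged by solute exchange, so the
        equilibrium solute mass is csat(w) * solvent mass directly).
        Kinetic mode advances the McCabe delta-L rate within the substep's
        real-time budget; if the budget runs out off equilibrium the run is
        aborted for rate-constant escalation.
        """
        curve = self.system.curve
        if self.kinetics is None or curve is None:
            return
        m = self.layer_masses()
        flash = self.kinetics.mode == "instantaneous_flash"
        for i in range(self.N):
            psd = self.cake.psds[i]
            solute, solv = m[i, 0], m[i, 1] + m[i, 2]
            if solv <= 0:
                continue
            w = min(max(m[i, 2] / solv, 0.0), 1.0)
            csat = csat_lookup(curve, w)
            m_eq = csat * solv
            if flash:
                delta = m_eq - solute  # >0: dissolve this much from solid
                if delta > 0:
                    delta = min(delta, psd.total_mass)
                elif psd.total_mass <= 0:
                    delta = 0.0  # no crystal surface: no deposition (no nucleation)
                if delta != 0.0:
                    new_psd, actual = shift_to_exchange(psd, delta)
                    self.cake.psds[i] = new_psd
                    m[i, 0] += actual
            else:
                remaining = dt_real
                while remaining > 0 and psd.total_mass > 0:
                    solute = m[i, 0]
                    sigma = (solute / solv) / csat - 1.0 if csat > 0 else (
                        1e6 if solute > 0 else 0.0
                    )
                    sigma = max(min(sigma, 1e6), -1.0)
                    if csat > 0 and abs(sigma) <= 0.3 * self.tol:
                        break
                    G = self.kinetics.linear_rate(sigma)
                    if G == 0.0:
                        break
                    x_sv = sauter_mean(psd, 1.0)
                    rate = 3.0 * psd.total_mass * abs(G) / x_sv  # kg/s, shrinking-sphere
                    gap = abs(m_eq - solute)
                    dt_i = min(remaining, 0.7 * gap / rate) if rate > 0 else remaining
                    if dt_i <= 0:
                        break
                    psd, dm = advance_growth_dissolution(psd, self.kinetics, sigma, dt_i)
                    m[i, 0] += dm
                    remaining -= dt_i
                self.cake.psds[i] = psd
            # record post-exchange supersaturation
            solute = m[i, 0]
            if csat > 0:
                sig = abs((solute / solv) / csat - 1.0)
            else:
                sig = math.inf if solute > 0 else 0.0
            if sig > self.max_abs_sigma:
                self.max_abs_sigma = sig
            if (
                not flash
                and psd.total_mass > 0
                and self.max_abs_sigma > self.tol
            ):
                self.y[: 3 * self.N] = m.ravel()
                raise _NotEquilibrated(self.max_abs_sigma)
        self.y[: 3 * self.N] = m.ravel()

    def solid_mass_total(self) -> float:
        return float(sum(p.total_mass for p in self.cake.psds))

    # -- snapshots ----------------------------------------------------------
    def snapshot(self):
        layer_bulk = self.cake.layer_volume
        solids = np.array([p.total_mass for p in self.cake.psds])
        porosity = 1.0 - (solids / self.rho_s) / layer_bulk
        m = self.layer_masses()
        solv = m[:, 1] + m[:, 2]
        w = np.divide(m[:, 2], solv, out=np.zeros(self.N), where=solv > 0)
        from .materials import mixture_density

        liq_vol = np.array(
            [
                mixture_density(self.layer_liquid(i), self.system) ** -1 * m[i].sum()
                if m[i].sum() > 0
                else 0.0
                for i in range(self.N)
            ]
        )
        sat = np.clip(liq_vol / (layer_bulk - solids / self.rho_s), 0.0, 1.0)
        return (
            [p.copy() for p in self.cake.psds],
            porosity,
            sat,
            w,
        )


def _run_cascade(
    cake: CakeState,
    protocol: WashProtocol,
    system: MaterialSystem,
    kinetics: DissolutionKinetics | None,
    model_label: str,
) -> WashCurve:
    run = _CascadeRun(cake, protocol, system, kinetics)
    N, V_v = run.N, run.V_v
    grid = protocol.grid()
    wr_rw = run.rewet_wr()
    use_kinetics = kinetics is not None and system.curve is not None

    h = protocol.wr_substep if use_kinetics else protocol.wr_grid_step
    P = _flow_propagator(N, run.V_layers, V_v, run.rho_w, h)

    n_pts = grid.size
    conc_out = np.zeros((n_pts, 3))
    cum_out = np.zeros((n_pts, 3))
    solid_change = np.zeros(n_pts)
    checkpoints = protocol.checkpoint_list()
    psd_cp, poro_cp, sat_cp, ww_cp = {}, {}, {}, {}

    if wr_rw > 0:
        run.exchange(0.0)  # breakthrough feed may start off-equilibrium

    def record(idx):
        conc_out[idx] = run.outlet_concentrations()
        cum_out[idx] = run.y[3 * N :]
        solid_change[idx] = run.solid_mass_total() - run.solid0

    def maybe_checkpoint(wr):
        for cp in checkpoints:
            if cp not in psd_cp and wr >= cp - 1e-9:
                psd_cp[cp], poro_cp[cp], sat_cp[cp], ww_cp[cp] = run.snapshot()

    record(0)
    maybe_checkpoint(0.0)
    wr = 0.0
    idx = 1
    # kinetic dt per substep (constant_flow exact; constant_pressure uses Darcy Q)
    def dt_real(step):
        if protocol.flow_mode == "constant_flow":
            return step * V_v / protocol.wash_flow_rate
        meta = getattr(cake, "_hydraulics", None)
        dP = meta["pressure_drop"] if meta else 5e4
        R_m = meta["media_resistance"] if meta else 0.0
        m = run.layer_masses().sum(axis=0)
        liq = LiquidState(0.0, max(m[1], 0.0), max(m[2], 0.0))
        mu = mixture_viscosity(liq, system.solvents) if liq.solvent_mass > 0 else 1e-3
        alpha = run._alpha if hasattr(run, "_alpha") else carman_kozeny_alpha(
            float(np.mean(cake.porosity)),
            sauter_mean(_combined_psd(cake), system.solute.sphericity),
            run.rho_s,
        )
        run._alpha = alpha
        Q = dP * cake.area / (mu * (alpha * run.solid0 / cake.area + R_m))
        return step * V_v / Q

    while idx < n_pts:
        target = grid[idx]
        while wr < target - 1e-12:
            step = min(h, target - wr)
            if wr < wr_rw:  # rewetting: no outflow
                step = min(step, wr_rw - wr)
                run.rewet_step(step)
            else:
                Pstep = P if abs(step - h) < 1e-15 else _flow_propagator(
                    N, run.V_layers, V_v, run.rho_w, step
                )
                run.y = _apply(Pstep, run.y)
                run.fed += step * V_v * run.rho_w
            if use_kinetics:
                run.exchange(dt_real(step))
            wr += step
        record(idx)
        maybe_checkpoint(wr)
        idx += 1
    maybe_checkpoint(protocol.wash_ratio_max)

    if use_kinetics and kinetics.mode == "kinetic" and run.max_abs_sigma > protocol.equilibrium_tol:
        raise _NotEquilibrated(run.max_abs_sigma)

    rewetted = grid < wr_rw - 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        totals = conc_out.sum(axis=1)
        fracs = np.where(totals[:, None] > 0, conc_out / np.where(totals[:, None] > 0, totals[:, None], 1.0), np.nan)
    fracs[rewetted] = np.nan
    c_over_c0 = conc_out[:, 0] / run.c0
    c_over_c0[rewetted] = np.nan

    m = run.layer_masses()
    layer_bulk = run.cake.layer_volume
    solids = np.array([p.total_mass for p in run.cake.psds])
    final = CakeState(
        solid_mass=solids,
        psds=[p.copy() for p in run.cake.psds],
        liquids=[LiquidState(*m[i]) for i in range(N)],
        porosity=1.0 - (solids / run.rho_s) / layer_bulk,
        area=cake.area,
        height=cake.height,
        saturation=np.ones(N),
    )
    mean_ww = np.full(grid.size, np.nan)
    time = _time_axis(grid, cake, protocol, system, V_v, None)
    return WashCurve(
        wash_ratio=grid,
        time=time,
        filtrate_mass_fractions={sp: fracs[:, k] for k, sp in enumerate(SPECIES)},
        c_over_c0=c_over_c0,
        cumulative_filtrate_mass={sp: cum_out[:, k] for k, sp in enumerate(SPECIES)},
        cumulative_solid_mass_change=solid_change,
        psd_checkpoints=psd_cp,
        porosity_checkpoints=poro_cp,
        saturation_checkpoints=sat_cp,
        w_wash_checkpoints=ww_cp,
        final_cake=final,
        fed_wash_mass=run.fed,
        metadata={
            "model": model_label,
            "max_abs_sigma": run.max_abs_sigma,
            "rewet_wash_ratio": wr_rw,
            "n_layers": N,
        },
    )


class _NotEquilibrated(Exception):
    def __init__(self, sigma):
        self.sigma = sigma


def _with_escalation(cake, protocol, system, kinetics, label):
    """Re-run with k_g * 10 until the equilibrium tolerance holds."""
    if kinetics is None or kinetics.mode != "kinetic":
        return _run_cascade(cake, protocol, system, kinetics, label)
    kg = kinetics.rate_constant
    last_sigma = None
    for _ in range(12):
        try:
            from dataclasses import replace

            return _run_cascade(cake, protocol, system, replace(kinetics, rate_constant=kg), label)
        except _NotEquilibrated as exc:
            last_sigma = exc.sigma
            kg *= 10.0
    warnings.warn(
        f"equilibrium tolerance not reached at rate-constant cap (max |sigma| = {last_sigma:.3g})",
        EquilibriumWarning,
    )
    curve = _run_cascade_no_check(cake, protocol, system, kinetics, kg, label)
    return curve


def _run_cascade_no_check(cake, protocol, system, kinetics, kg, label):
    from dataclasses import replace

    relaxed = replace(protocol, equilibrium_tol=math.inf)
    return _run_cascade(cake, relaxed, system, replace(kinetics, rate_constant=kg), label)


def wash_dilution(
    cake: CakeState,
    protocol: WashProtocol,
    system: MaterialSystem,
    kinetics: DissolutionKinetics | None = None,
) -> WashCurve:
    """Perfectly mixed (dilution/reslurry) washing: model 1b, or 2b with kinetics.

    The cake liquid is one well-mixed holdup with volume-matched outflow;
    without kinetics the solute follows c/c0 = exp(-W_r). Breakthrough
    feeds are first rewetted to full saturation before outflow starts.
    """
    if cake.n_layers != 1:
        raise ValueError("dilution washing expects a single-layer cake (n_layers=1)")
    label = "2b" if kinetics is not None else "1b"
    return _with_escalation(cake, protocol, system, kinetics, label)


def wash_cstr_cascade(
    cake: CakeState,
    protocol: WashProtocol,
    system: MaterialSystem,
    kinetics: DissolutionKinetics | None = None,
) -> WashCurve:
    """Tanks-in-series washing: model 1c (no kinetics) or 2c (with kinetics).

    Layer 1 (top) receives fresh wash; each layer feeds the next; the last
    layer feeds the filtrate. With kinetics every layer independently
    equilibrates with the solubility curve at its local solvent
    composition, so dissolution/deposition propagates down the cake with
    the solvent front.
    """
    label = "2c" if kinetics is not None else "1c"
    return _with_escalation(cake, protocol, system, kinetics, label)


# ---------------------------------------------------------------------------
# model 1c, plug-flow (advection-dispersion PDE) form


def wash_dispersion_pde(
    cake: CakeState,
    protocol: WashProtocol,
    system: MaterialSystem,
) -> WashCurve:
    """1-D axial advection-dispersion washing (model 1c, plug-flow form).

    Solves du/dW_r = (1/Pe) d2u/dz2 - du/dz on z in [0, 1] for the local
    mother-liquor fraction u (method of lines, finite volume; u = 1
    initially, pure wash at the inlet with no inlet dispersive flux, zero
    dispersive flux at the outlet). The filtrate curve is u at the medium.
    Central differencing of advection switches to upwind when the cell
    Peclet number exceeds 2.
    """
    if np.any(cake.saturation < 1.0 - 1e-9):
        raise ValueError("dispersion washing requires a dryland (saturated) cake")
    rho_s = system.solute.crystal_density
    rho_w = system.wash_solvent.density
    V_v = _cake_void_volume(cake, rho_s)
    eps = float(np.mean(cake.porosity))
    L = cake.height

    # superficial velocity for the Peclet number
    if protocol.flow_mode == "constant_flow":
        u_s = protocol.wash_flow_rate / cake.area
    else:
        meta = getattr(cake, "_hydraulics", None)
        dP = meta["pressure_drop"] if meta else 5e4
        R_m = meta["media_resistance"] if meta else 0.0
        masses = _liquid_masses(cake).sum(axis=1)
        ml = LiquidState(*masses)
        mu = mixture_viscosity(ml, system.solvents)
        alpha = carman_kozeny_alpha(
            eps, sauter_mean(_combined_psd(cake), system.solute.sphericity), rho_s
        )
        m_c = float(np.sum(cake.solid_mass))
        u_s = dP / (mu * (alpha * m_c / cake.area + R_m))
    d_p = sauter_mean(_combined_psd(cake), system.solute.sphericity)
    D_L = axial_dispersion_coefficient(u_s, d_p, protocol.molecular_diffusivity,
                                       protocol.dispersion_model)
    v = u_s / eps
    Pe = v * L / D_L

    n = protocol.n_nodes
    if n < 100:
        raise ValueError("dispersion PDE needs at least 100 nodes")
    dz = 1.0 / n
    cell_pe = Pe * dz
    upwind = cell_pe > 2.0

    def rhs(wr, y):
        u = y[:n]
        F = np.empty(n + 1)
        F[0] = 0.0  # inlet: pure wash, no inlet dispersive flux
        if upwind:
            F[1:n] = u[:-1]
        else:
            F[1:n] = 0.5 * (u[:-1] + u[1:])
        F[1:n] -= (u[1:] - u[:-1]) / (Pe * dz)
        F[n] = u[-1]  # outlet: advective only (zero dispersive gradient)
        dudt = -(F[1:] - F[:-1]) / dz
        return np.concatenate([dudt, [u[-1]]])  # last state: integral of outlet u

    from scipy.sparse import lil_matrix

    spars = lil_matrix((n + 1, n + 1))
    for i in range(n):
        for k in (i - 1, i, i + 1):
            if 0 <= k < n:
                spars[i, k] = 1
    spars[n, n - 1] = 1
    y0 = np.concatenate([np.ones(n), [0.0]])
    grid = protocol.grid()
    sol = solve_ivp(
        rhs,
        (0.0, grid[-1]),
        y0,
        t_eval=grid,
        method="BDF",
        jac_sparsity=spars,
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"dispersion PDE solver failed: {sol.message}")
    u_out = sol.y[n - 1]
    int_u_out = sol.y[n]

    masses = _liquid_masses(cake).sum(axis=1)
    from .materials import mixture_density

    ml = LiquidState(*masses)
    rho_ml = mixture_density(ml, system)
    frac_ml = masses / masses.sum()
    c0 = masses[0] / V_v

    # instantaneous filtrate composition: u_out parts mother liquor by volume
    ml_mass_rate = u_out * rho_ml
    wash_mass_rate = (1.0 - u_out) * rho_w
    tot = ml_mass_rate + wash_mass_rate
    fractions = {
        "solute": ml_mass_rate * frac_ml[0] / tot,
        "crystallization_solvent": ml_mass_rate * frac_ml[1] / tot,
        "wash_solvent": (ml_mass_rate * frac_ml[2] + wash_mass_rate) / tot,
    }
    int_wash_out = sol.t - int_u_out
    cumulative = {
        "solute": int_u_out * V_v * rho_ml * frac_ml[0],
        "crystallization_solvent": int_u_out * V_v * rho_ml * frac_ml[1],
        "wash_solvent": int_u_out * V_v * rho_ml * frac_ml[2] + int_wash_out * V_v * rho_w,
    }
    # final cake liquid from the final field
    u_final = sol.y[:n, -1]
    ml_vol_left = max(float(u_final.mean()), 0.0) * V_v  # clip solver round-off
    wash_vol_in_cake = V_v - ml_vol_left
    final_liquid = np.array(
        [
            ml_vol_left * rho_ml * frac_ml[0],
            ml_vol_left * rho_ml * frac_ml[1],
            ml_vol_left * rho_ml * frac_ml[2] + wash_vol_in_cake * rho_w,
        ]
    )
    nl = cake.n_layers
    final = CakeState(
        solid_mass=cake.solid_mass.copy(),
        psds=[p.copy() for p in cake.psds],
        liquids=[LiquidState(*(final_liquid / nl)) for _ in range(nl)],
        porosity=cake.porosity.copy(),
        area=cake.area,
        height=cake.height,
        saturation=np.ones(nl),
    )
    psd_cp = {wr: [p.copy() for p in cake.psds] for wr in protocol.checkpoint_list()}
    time = _time_axis(grid, cake, protocol, system, V_v, 1.0 - np.clip(u_out, 0, 1))
    return WashCurve(
        wash_ratio=grid,
        time=time,
        filtrate_mass_fractions=fractions,
        c_over_c0=u_out.copy(),
        cumulative_filtrate_mass=cumulative,
        cumulative_solid_mass_change=np.zeros_like(grid),
        psd_checkpoints=psd_cp,
        porosity_checkpoints={wr: cake.porosity.copy() for wr in protocol.checkpoint_list()},
        final_cake=final,
        fed_wash_mass=float(grid[-1] * V_v * rho_w),
        metadata={
            "model": "1c-pde",
            "peclet": Pe,
            "cell_peclet": cell_pe,
            "upwind": upwind,
            "dispersion_coefficient": D_L,
            "holdup_field": sol.y[:n, -1],
            "max_abs_sigma": 0.0,
        },
    )


# ---------------------------------------------------------------------------
# audit


def mass_balance_audit(curve: WashCurve, initial_cake: CakeState) -> dict:
    """Species-wise closure of a completed wash run.

    For each species: initial(solid + cake liquid) + fed wash must equal
    final(solid + cake liquid) + cumulative filtrate. Returns relative
    residuals (scaled by the largest inventory) plus the worst case under
    "max_relative_residual".
    """
    if curve.final_cake is None:
        raise ValueError("curve carries no final cake state")
    init_liq = _liquid_masses(initial_cake).sum(axis=1)
    final_liq = _liquid_masses(curve.final_cake).sum(axis=1)
    init_solid = float(np.sum(initial_cake.solid_mass))
    final_solid = float(sum(p.total_mass for p in curve.final_cake.psds))
    out = {sp: curve.cumulative_filtrate_mass[sp][-1] for sp in SPECIES}
    fed = {"solute": 0.0, "crystallization_solvent": 0.0, "wash_solvent": curve.fed_wash_mass}

    residuals = {}
    scale = max(init_solid, init_liq.sum(), curve.fed_wash_mass)
    for k, sp in enumerate(SPECIES):
        lhs = init_liq[k] + fed[sp]
        rhs = final_liq[k] + out[sp]
        if sp == "solute":
            lhs += init_solid
            rhs += final_solid
        residuals[sp] = abs(lhs - rhs) / scale
    residuals["max_relative_residual"] = max(residuals[sp] for sp in SPECIES)
    return residuals
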