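"""Material properties, liquid-phase state, and binary solubility curves.

The washing models track a three-species liquid phase (solute,
crystallization solvent, wash solvent). Saturation solubility is carried
as a *binary plot*: saturation concentration of the solute, in grams of
solute per gram of solute-free solvent mixture, as a function of the wash
solvent's mass fraction of that solvent mixture. Dissolution/deposition
driving force is the relative supersaturation sigma = c/c_sat - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SolventSpec",
    "SoluteSpec",
    "LiquidState",
    "BinarySolubilityCurve",
    "MaterialSystem",
    "DegenerateInputError",
    "mixture_density",
    "mixture_viscosity",
    "csat_lookup",
    "supersaturation",
]


class DegenerateInputError(ValueError):
    """Raised when an operation receives an empty/zero-mass state."""


@dataclass(frozen=True)
class SolventSpec:
    """A pure solvent at the (isothermal) run temperature.

    density in kg/m^3, viscosity in Pa s. ``role`` is either
    ``"crystallization"`` or ``"wash"``.
    """

    name: str
    density: float
    viscosity: float
    role: str = "crystallization"

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"solvent {self.name!r}: density must be > 0")
        if not self.viscosity > 0:
            raise ValueError(f"solvent {self.name!r}: viscosity must be > 0")
        if self.role not in ("crystallization", "wash"):
            raise ValueError(f"solvent {self.name!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class SoluteSpec:
    """The crystalline product (API). crystal_density in kg/m^3."""

    name: str
    crystal_density: float
    sphericity: float = 1.0

    def __post_init__(self) -> None:
        if not self.crystal_density > 0:
            raise ValueError("crystal_density must be > 0")
        if not 0 < self.sphericity <= 1:
            raise ValueError("sphericity must lie in (0, 1]")


@dataclass
class LiquidState:
    """Species masses (kg) of a liquid holdup; isothermal temperature in degC.

    Mass fractions and the wash-solvent fraction of the solute-free solvent
    mixture are derived properties.
    """

    mass_solute: float
    mass_crystallization_solvent: float
    mass_wash_solvent: float
    temperature: float = 25.0

    def __post_init__(self) -> None:
        for name in ("mass_solute", "mass_crystallization_solvent", "mass_wash_solvent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_mass(self) -> float:
        return self.mass_solute + self.mass_crystallization_solvent + self.mass_wash_solvent

    @property
    def solvent_mass(self) -> float:
        return self.mass_crystallization_solvent + self.mass_wash_solvent

    @property
    def w_wash(self) -> float:
        """Wash-solvent mass fraction of the solute-free solvent mixture."""
        s = self.solvent_mass
        if s <= 0:
            raise DegenerateInputError("no solvent present")
        return self.mass_wash_solvent / s

    @property
    def solute_concentration(self) -> float:
        """g solute per g solute-free solvent mixture (the binary-plot basis)."""
        s = self.solvent_mass
        if s <= 0:
            raise DegenerateInputError("no solvent present")
        return self.mass_solute / s

    def mass_fractions(self) -> dict[str, float]:
        m = self.total_mass
        if m <= 0:
            raise DegenerateInputError("zero total liquid mass")
        return {
            "solute": self.mass_solute / m,
            "crystallization_solvent": self.mass_crystallization_solvent / m,
            "wash_solvent": self.mass_wash_solvent / m,
        }

    def copy(self) -> "LiquidState":
        return replace(self)


@dataclass
class BinarySolubilityCurve:
    """Saturation solubility vs wash-solvent fraction of the solvent pair.

    ``w_grid`` is ascending in [0, 1] with endpoints 0 and 1; ``csat_grid``
    is in g solute per g solute-free solvent mixture. ``shape_tag`` is one
    of {"maximum", "monotone_decreasing", "monotone_increasing", "flat"}
    and is validated against the tabulated values on construction.
    """

    w_grid: np.ndarray
    csat_grid: np.ndarray
    shape_tag: str = ""

    def __post_init__(self) -> None:
        self.w_grid = np.asarray(self.w_grid, dtype=float)
        self.csat_grid = np.asarray(self.csat_grid, dtype=float)
        if self.w_grid.ndim != 1 or self.w_grid.shape != self.csat_grid.shape:
            raise ValueError("w_grid and csat_grid must be 1-D and of equal length")
        if self.w_grid.size < 2:
            raise ValueError("need at least two nodes")
        if np.any(np.diff(self.w_grid) <= 0):
            raise ValueError("w_grid must be strictly ascending")
        if not (self.w_grid[0] == 0.0 and self.w_grid[-1] == 1.0):
            raise ValueError("w_grid must span [0, 1] exactly")
        if np.any(self.csat_grid < 0):
            raise ValueError("csat_grid must be non-negative")
        inferred = self._infer_shape()
        if not self.shape_tag:
            self.shape_tag = inferred
        elif self.shape_tag != inferred:
            raise ValueError(
                f"shape_tag {self.shape_tag!r} inconsistent with tabulated values "
                f"(inferred {inferred!r})"
            )

    def _infer_shape(self) -> str:
        c = self.csat_grid
        rtol = 1e-12 * max(1.0, float(np.max(c)))
        d = np.diff(c)
        if np.all(np.abs(d) <= rtol):
            return "flat"
        interior_max = float(np.max(c[1:-1])) if c.size > 2 else -np.inf
        if interior_max > max(c[0], c[-1]) + rtol:
            return "maximum"
        if np.all(d <= rtol):
            return "monotone_decreasing"
        if np.all(d >= -rtol):
            return "monotone_increasing"
        return "maximum" if interior_max >= max(c[0], c[-1]) else "flat"

    def __call__(self, w_wash: float) -> float:
        return csat_lookup(self, w_wash)


@dataclass(frozen=True)
class MaterialSystem:
    """The solute + crystallization/wash solvent pair + solubility curve of a run."""

    solute: SoluteSpec
    crystallization_solvent: SolventSpec
    wash_solvent: SolventSpec
    curve: BinarySolubilityCurve | None = None

    @property
    def solvents(self) -> dict[str, SolventSpec]:
        return {
            "crystallization_solvent": self.crystallization_solvent,
            "wash_solvent": self.wash_solvent,
        }


def mixture_density(liquid: LiquidState, solvents, solute: SoluteSpec | None = None) -> float:
    """Ideal (volume-additive) density of the liquid phase, kg/m^3.

    1/rho = sum_i w_i / rho_i over the species present. The dissolved solute
    contributes with its crystal density when a ``solute`` spec is given;
    otherwise the liquid must be solute-free.

    ``solvents`` maps {"crystallization_solvent": SolventSpec,
    "wash_solvent": SolventSpec} (a MaterialSystem works via ``.solvents``).
    """
    if isinstance(solvents, MaterialSystem):
        solute = solute or solvents.solute
        solvents = solvents.solvents
    m = liquid.total_mass
    if m <= 0:
        raise DegenerateInputError("zero total liquid mass")
    if liquid.mass_solute > 0 and solute is None:
        raise ValueError("solute present but no SoluteSpec given")
    inv = (
        liquid.mass_crystallization_solvent / solvents["crystallization_solvent"].density
        + liquid.mass_wash_solvent / solvents["wash_solvent"].density
    )
    if liquid.mass_solute > 0:
        inv += liquid.mass_solute / solute.crystal_density
    return m / inv


def mixture_viscosity(liquid: LiquidState, solvents) -> float:
    """Arrhenius (log-linear, mass-fraction) blend of the solvent viscosities, Pa s.

    ln(mu) = sum_i x_i ln(mu_i) over the solute-free solvent mixture; the
    dissolved solute is not assigned a viscosity contribution.
    """
    if isinstance(solvents, MaterialSystem):
        solvents = solvents.solvents
    s = liquid.solvent_mass
    if s <= 0:
        raise DegenerateInputError("zero solvent mass")
    x_cs = liquid.mass_crystallization_solvent / s
    x_ws = liquid.mass_wash_solvent / s
    return math.exp(
        x_cs * math.log(solvents["crystallization_solvent"].viscosity)
        + x_ws * math.log(solvents["wash_solvent"].viscosity)
    )


def csat_lookup(curve: BinarySolubilityCurve, w_wash: float) -> float:
    """Saturation solubility (g/g solvent) at a wash-solvent fraction in [0, 1].

    Piecewise-linear on the tabulated nodes; exact at nodes; no extrapolation.
    """
    if not 0.0 <= w_wash <= 1.0:
        raise ValueError(f"w_wash={w_wash} outside [0, 1]; no extrapolation")
    return float(np.interp(w_wash, curve.w_grid, curve.csat_grid))


def supersaturation(liquid: LiquidState, curve: BinarySolubilityCurve) -> float:
    """Relative supersaturation sigma = c/c_sat - 1 of the liquid against the curve.

    c is the solute concentration on the binary-plot basis (g/g solvent
    mixture) and c_sat is looked up at the liquid's wash-solvent fraction.
    sigma > 0 drives deposition, sigma < 0 dissolution. A zero c_sat with
    solute present is signalled as +inf.
    """
    c = liquid.solute_concentration
    csat = csat_lookup(curve, liquid.w_wash)
    if csat == 0.0:
        return math.inf if c > 0 else 0.0
    return c / csat - 1.0
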