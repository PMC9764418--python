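"""Discretized particle size distributions and dissolution/growth updates.

Mass-by-size representation: strictly ascending diameter bin edges (m) and
the solid mass held in each bin (kg). Within a bin the *number* density is
taken uniform in diameter, which makes every mass integral a closed-form
quartic and lets shrinkage/growth be applied as exact edge motion (McCabe
delta-L: a size-independent linear rate) followed by conservative
re-binning. Mass bookkeeping is therefore exact to round-off: for every
update, new mass + mass_exchanged == old mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .materials import DegenerateInputError

__all__ = [
    "ParticleSizeDistribution",
    "DissolutionKinetics",
    "DiscretizationError",
    "InfeasibleDissolutionError",
    "fit_lognormal_psd",
    "lognormal_psd_from_d50",
    "quantile",
    "sauter_mean",
    "uniform_dissolve",
    "advance_growth_dissolution",
    "shift_to_exchange",
    "specific_surface_area",
    "number_moments",
]

DEFAULT_N_BINS = 80
DEFAULT_SPAN = (0.1e-6, 1000e-6)  # m, geometric


class DiscretizationError(ValueError):
    """Raised when a requested grid cannot represent the distribution."""


class InfeasibleDissolutionError(ValueError):
    """Raised when more mass is asked to dissolve than the PSD holds."""


@dataclass
class ParticleSizeDistribution:
    bin_edges: np.ndarray  # (n+1,) strictly ascending, >= 0, m
    bin_mass: np.ndarray  # (n,) kg

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_mass = np.asarray(self.bin_mass, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size != self.bin_mass.size + 1:
            raise ValueError("need n+1 edges for n bin masses")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")
        if self.bin_edges[0] < 0:
            raise ValueError("bin_edges must be >= 0")
        if np.any(self.bin_mass < -0.0):
            self.bin_mass = np.where(np.abs(self.bin_mass) < 1e-300, 0.0, self.bin_mass)
        if np.any(self.bin_mass < 0):
            raise ValueError("bin_mass must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.bin_mass.size

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_mass(self) -> float:
        return float(self.bin_mass.sum())

    def mass_fractions(self) -> np.ndarray:
        m = self.total_mass
        if m <= 0:
            raise DegenerateInputError("empty particle size distribution")
        return self.bin_mass / m

    def copy(self) -> "ParticleSizeDistribution":
        return ParticleSizeDistribution(self.bin_edges.copy(), self.bin_mass.copy())

    def scaled(self, mass_factor: float) -> "ParticleSizeDistribution":
        return ParticleSizeDistribution(self.bin_edges.copy(), self.bin_mass * mass_factor)

    # convenience wrappers
    def quantile(self, p: float) -> float:
        return quantile(self, p)

    def sauter_mean(self, sphericity: float = 1.0) -> float:
        return sauter_mean(self, sphericity)


@dataclass(frozen=True)
class DissolutionKinetics:
    """Empirical power-law growth/dissolution rate G = sign(sigma)*k_g*|sigma|**g.

    The rate constant is a relaxation parameter only: runs escalate it until
    the liquid stays at solid-liquid equilibrium (|sigma| below tolerance),
    as the washing models assume. ``mode="instantaneous_flash"`` replaces
    the kinetic relaxation by an algebraic equilibrium solve each step.
    activation_energy is carried for completeness and fixed at zero
    (isothermal runs).
    """

    rate_constant: float = 1e-6  # m/s per unit driving force
    exponent: float = 1.0
    activation_energy: float = 0.0
    mode: str = "kinetic"

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be >= 0")
        if not self.exponent > 0:
            raise ValueError("exponent must be > 0")
        if self.mode not in ("kinetic", "instantaneous_flash"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def linear_rate(self, sigma: float) -> float:
        """Signed linear growth rate G (m/s); negative = dissolution."""
        if sigma == 0.0 or self.rate_constant == 0.0:
            return 0.0
        return math.copysign(self.rate_constant * abs(sigma) ** self.exponent, sigma)


# ---------------------------------------------------------------------------
# construction


def _lognormal_shape_from_cv(mean: float, std: float) -> tuple[float, float]:
    """(mu, s) of a lognormal with the given mean and standard deviation."""
    s2 = math.log1p((std / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def _discretize_mass_lognormal(
    mu_mass: float, s: float, n_bins: int, span, total_mass: float
) -> ParticleSizeDistribution:
    """Bin masses from exact CDF differences of the mass-weighted lognormal."""
    if span is None:
        lo = math.exp(mu_mass - 3 * s * s - 5 * s) if s > 0 else math.exp(mu_mass) / 2
        hi = math.exp(mu_mass + 5 * s) if s > 0 else math.exp(mu_mass) * 2
    else:
        lo, hi = span
        if not 0 < lo < hi:
            raise ValueError("span must be (lo, hi) with 0 < lo < hi")
    edges = np.geomspace(lo, hi, n_bins + 1)
    dist = stats.lognorm(s=max(s, 1e-12), scale=math.exp(mu_mass))
    cdf = dist.cdf(edges)
    coverage = cdf[-1] - cdf[0]
    if coverage < 0.99:
        raise DiscretizationError(
            f"span ({lo:.3g}, {hi:.3g}) m captures only {100 * coverage:.1f}% of the mass"
        )
    mass = np.diff(cdf)
    return ParticleSizeDistribution(edges, total_mass * mass / mass.sum())


def fit_lognormal_psd(
    mean: float,
    std: float,
    n_bins: int = 120,
    span: tuple[float, float] | None = None,
    *,
    weighting: str = "number",
    total_mass: float = 1.0,
) -> ParticleSizeDistribution:
    """Discretize a lognormal PSD with the requested mean and std (both in m).

    ``weighting`` states which density the moments describe: ``"number"``
    (default) or ``"mass"``. The corresponding mass-weighted density of a
    number lognormal(mu, s) is lognormal(mu + 3 s^2, s); bin masses are
    exact partial third moments either way. When ``span`` is omitted it is
    widened automatically so both the number and mass weightings are
    captured (heavy-tailed inputs like std >> mean need a span far beyond
    the visible sizes).
    """
    if not (mean > 0 and std > 0):
        raise ValueError("mean and std must be > 0")
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    mu, s = _lognormal_shape_from_cv(mean, std)
    if weighting == "number":
        mu_mass = mu + 3 * s * s
    elif weighting == "mass":
        mu_mass = mu
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return _discretize_mass_lognormal(mu_mass, s, n_bins, span, total_mass)


def lognormal_psd_from_d50(
    d50: float,
    std: float,
    n_bins: int = 120,
    span: tuple[float, float] | None = None,
    *,
    total_mass: float = 1.0,
) -> ParticleSizeDistribution:
    """Mass-weighted lognormal parameterized by its mass median (D50) and std.

    Particle-size analyzers report the volume/mass-weighted median; this
    constructor reproduces that D50 exactly on the discretized grid. For a
    mass lognormal with median d50, std fixes s via
    std^2 = d50^2 * y * (y - 1), y = exp(s^2).
    """
    if not (d50 > 0 and std >= 0):
        raise ValueError("d50 must be > 0 and std >= 0")
    r2 = (std / d50) ** 2
    y = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * r2))
    s = math.sqrt(math.log(y)) if y > 1 else 0.0
    return _discretize_mass_lognormal(math.log(d50), s, n_bins, span, total_mass)


# ---------------------------------------------------------------------------
# descriptive statistics


def quantile(psd: ParticleSizeDistribution, p: float) -> float:
    """Mass-weighted diameter quantile, linear inside the straddling bin."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    total = psd.total_mass
    if total <= 0:
        raise DegenerateInputError("empty particle size distribution")
    cum = np.concatenate(([0.0], np.cumsum(psd.bin_mass))) / total
    return float(np.interp(p, cum, psd.bin_edges))


def number_moments(psd: ParticleSizeDistribution) -> tuple[float, float]:
    """(mean, std) of the number-weighted diameter distribution.

    Reconstructs per-bin particle numbers from the uniform-in-diameter
    number-density convention.
    """
    a, b = psd.bin_edges[:-1], psd.bin_edges[1:]
    mask = psd.bin_mass > 0
    if not mask.any():
        raise DegenerateInputError("empty particle size distribution")
    a, b, m = a[mask], b[mask], psd.bin_mass[mask]
    dens = 4.0 * m / (b**4 - a**4)  # number density (internal mass units)
    n = dens * (b - a)
    m1 = dens * (b**2 - a**2) / 2.0
    m2 = dens * (b**3 - a**3) / 3.0
    ntot, mean = n.sum(), m1.sum() / n.sum()
    var = m2.sum() / ntot - mean**2
    return mean, math.sqrt(max(var, 0.0))


def sauter_mean(psd: ParticleSizeDistribution, sphericity: float = 1.0) -> float:
    """Sphericity-scaled surface-volume (Sauter) mean diameter x_sv, m.

    x_sv = sphericity * (sum m_i) / (sum m_i / d_i) over bin midpoints.
    """
    total = psd.total_mass
    if total <= 0:
        raise DegenerateInputError("empty particle size distribution")
    mask = psd.bin_mass > 0
    harm = np.sum(psd.bin_mass[mask] / psd.midpoints[mask])
    return float(sphericity * total / harm)


def specific_surface_area(
    psd: ParticleSizeDistribution, crystal_density: float, sphericity: float = 1.0
) -> float:
    """Surface area per unit solid mass, m^2/kg: sum 6 m_i/(rho_s d_i phi) / sum m_i."""
    total = psd.total_mass
    if total <= 0:
        raise DegenerateInputError("empty particle size distribution")
    mask = psd.bin_mass > 0
    area = np.sum(6.0 * psd.bin_mass[mask] / (crystal_density * psd.midpoints[mask] * sphericity))
    return float(area / total)


# ---------------------------------------------------------------------------
# dissolution / growth updates


def uniform_dissolve(
    psd: ParticleSizeDistribution, dissolved_mass: float
) -> ParticleSizeDistribution:
    """Homogeneous volume removal: every diameter scaled by (1 - f)^(1/3).

    f = dissolved_mass / total mass; bin mass ratios are preserved exactly
    (shape-preserving) and total mass drops by exactly dissolved_mass.
    """
    total = psd.total_mass
    if dissolved_mass < 0 or dissolved_mass > total * (1 + 1e-12):
        raise InfeasibleDissolutionError(
            f"cannot dissolve {dissolved_mass} kg from {total} kg of solid"
        )
    f = min(dissolved_mass / total, 1.0) if total > 0 else 0.0
    if f >= 1.0:
        return ParticleSizeDistribution(psd.bin_edges.copy(), np.zeros(psd.n_bins))
    scale = (1.0 - f) ** (1.0 / 3.0)
    return ParticleSizeDistribution(psd.bin_edges * scale, psd.bin_mass * (1.0 - f))


def _quartic_overlap(a, b, lo, hi):
    """integral of d^3 over [max(a,lo), min(b,hi)] (0 if empty)."""
    lo2 = np.maximum(a, lo)
    hi2 = np.minimum(b, hi)
    out = (hi2**4 - lo2**4) / 4.0
    return np.where(hi2 > lo2, out, 0.0)


def _shifted_total_mass(psd: ParticleSizeDistribution, dL: float) -> float:
    """Total mass after shifting every diameter by dL (clipped at zero)."""
    a, b = psd.bin_edges[:-1], psd.bin_edges[1:]
    mask = psd.bin_mass > 0
    if not mask.any():
        return 0.0
    a, b, m = a[mask], b[mask], psd.bin_mass[mask]
    dens = 4.0 * m / (b**4 - a**4)
    lo = np.maximum(a + dL, 0.0)
    hi = np.maximum(b + dL, 0.0)
    return float(np.sum(dens * (hi**4 - lo**4) / 4.0))


def _extend_edges(edges: np.ndarray, lo_needed: float, hi_needed: float) -> np.ndarray:
    """Geometrically extend a grid to cover [lo_needed, hi_needed]."""
    edges = list(edges)
    ratio = edges[-1] / edges[-2] if edges[-2] > 0 else 2.0
    ratio = max(ratio, 1.0 + 1e-9)
    while edges[-1] < hi_needed:
        edges.append(edges[-1] * ratio)
    if lo_needed < edges[0]:
        head = []
        first = edges[0]
        if first > 0:
            while first > lo_needed and first > 1e-12 * edges[-1]:
                first = first / ratio
                head.append(first)
            if first > lo_needed:
                head.append(0.0)
        edges = sorted(head) + edges
    return np.asarray(edges)


def _shift_and_rebin(psd: ParticleSizeDistribution, dL: float) -> ParticleSizeDistribution:
    """Move all diameters by dL (method of characteristics) and re-bin.

    Bins pushed through zero lose their mass (it dissolves); the target grid
    is the source grid, geometrically extended where growth requires it.
    Re-binning uses conservative overlap of the quartic mass integrals.
    """
    if dL == 0.0:
        return psd.copy()
    a_all, b_all = psd.bin_edges[:-1], psd.bin_edges[1:]
    mask = psd.bin_mass > 0
    edges = psd.bin_edges
    if mask.any():
        hi_needed = float(b_all[mask].max() + max(dL, 0.0))
        lo_needed = float(max(a_all[mask].min() + min(dL, 0.0), 0.0))
        edges = _extend_edges(edges, lo_needed, hi_needed)
    new_mass = np.zeros(edges.size - 1)
    lo_t, hi_t = edges[:-1], edges[1:]
    for a, b, m in zip(a_all[mask], b_all[mask], psd.bin_mass[mask]):
        dens = 4.0 * m / (b**4 - a**4)
        sa = max(a + dL, 0.0)
        sb = b + dL
        if sb <= 0:
            continue  # fully dissolved
        new_mass += dens * _quartic_overlap(sa, sb, lo_t, hi_t)
    return ParticleSizeDistribution(edges, new_mass)


def advance_growth_dissolution(
    psd: ParticleSizeDistribution,
    kinetics: DissolutionKinetics,
    sigma: float,
    dt: float,
) -> tuple[ParticleSizeDistribution, float]:
    """One McCabe delta-L step: all diameters move by G(sigma)*dt.

    Returns (new psd, mass_exchanged) with mass_exchanged > 0 meaning
    dissolution (solid -> liquid); the solid mass change is exactly
    -mass_exchanged. sigma = 0 is the identity.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    G = kinetics.linear_rate(sigma)
    if G == 0.0 or psd.total_mass == 0.0:
        return psd.copy(), 0.0
    old = psd.total_mass
    new = _shift_and_rebin(psd, G * dt)
    return new, old - new.total_mass


def shift_to_exchange(
    psd: ParticleSizeDistribution, delta_mass: float
) -> tuple[ParticleSizeDistribution, float]:
    """Find the delta-L that exchanges exactly ``delta_mass`` with the liquid.

    delta_mass > 0 dissolves (fines first, small bins emptying through
    zero), delta_mass < 0 deposits uniformly in delta-L. Used by the
    instantaneous-flash equilibrium mode. Returns (new psd, actual
    exchange); the actual exchange equals delta_mass up to round-off,
    clipped at total dissolution.
    """
    total = psd.total_mass
    if total == 0.0 or abs(delta_mass) <= 1e-13 * total:
        return psd.copy(), 0.0
    if delta_mass >= total * (1.0 - 1e-12):
        empty = ParticleSizeDistribution(psd.bin_edges.copy(), np.zeros(psd.n_bins))
        return empty, total
    target = total - delta_mass

    def f(dL: float) -> float:
        return _shifted_total_mass(psd, dL) - target

    if delta_mass > 0:
        lo, hi = -float(psd.bin_edges[-1]), 0.0
    else:
        step = float(psd.bin_edges[-1])
        lo, hi = 0.0, step
        while f(hi) < 0:
            hi *= 2.0
    dL = optimize.brentq(f, lo, hi, xtol=1e-18, rtol=8.9e-16)
    new = _shift_and_rebin(psd, dL)
    return new, total - new.total_mass
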