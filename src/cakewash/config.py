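"""Run configuration: a nested key/value document <-> validated model objects.

The on-disk format is YAML with sections ``equipment``, ``operation``,
``suspension``, ``materials``, ``psd``, ``solubility``, ``wash`` and
optional ``kinetics``. Bench units match the way isolation conditions are
usually tabulated (mbar, mm, g, um); everything is converted to SI on
load. Validation collects *all* offending fields before raising.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from .filtration import OperatingConditions, SuspensionState
from .materials import (
    BinarySolubilityCurve,
    LiquidState,
    MaterialSystem,
    SoluteSpec,
    SolventSpec,
)
from .psd import (
    DissolutionKinetics,
    ParticleSizeDistribution,
    fit_lognormal_psd,
    lognormal_psd_from_d50,
)
from .washing import WashProtocol

__all__ = ["CaseFixture", "ConfigError", "load_config", "dump_config", "read_config_file"]

MBAR = 100.0  # Pa
UM = 1e-6
MM = 1e-3
GRAM = 1e-3


class ConfigError(ValueError):
    """All validation problems of a config document, reported at once."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass
class CaseFixture:
    """A fully specified, validated isolation case.

    ``config`` is the canonical nested document the fixture round-trips
    through; ``provenance`` records where each headline value comes from.
    """

    name: str
    suspension: SuspensionState
    conditions: OperatingConditions
    protocol: WashProtocol
    system: MaterialSystem
    kinetics: DissolutionKinetics | None
    config: dict
    provenance: dict = field(default_factory=dict)


def _get(section: dict, key: str, problems: list[str], where: str, default=None, required=True):
    if key in section:
        return section[key]
    if required and default is None:
        problems.append(f"{where}.{key} is missing")
    return default


def load_config(doc: dict) -> CaseFixture:
    """Validate a config document and build the model objects."""
    problems: list[str] = []

    def section(name: str) -> dict:
        s = doc.get(name)
        if not isinstance(s, dict):
            problems.append(f"section {name!r} is missing")
            return {}
        return s

    eq = section("equipment")
    op = section("operation")
    susp = section("suspension")
    mats = section("materials")
    psd_sec = section("psd")
    sol = section("solubility")
    wash = section("wash")
    kin = doc.get("kinetics")

    d_mm = _get(eq, "filter_diameter_mm", problems, "equipment")
    dp_mbar = _get(op, "driving_force_mbar", problems, "operation")
    r_m = _get(op, "media_resistance_per_m", problems, "operation")
    temp = op.get("temperature_c", 25.0)
    endpoint = op.get("endpoint", "dryland")
    residual = op.get("breakthrough_residual_fraction", 0.10)

    solid_g = _get(susp, "solid_mass_g", problems, "suspension")
    liquid_g = _get(susp, "liquid_mass_g", problems, "suspension")
    x_cs = _get(susp, "crystallization_solvent_mass_fraction", problems, "suspension")
    x_solute = _get(susp, "solute_mass_fraction", problems, "suspension")
    x_ws = susp.get("wash_solvent_mass_fraction", 0.0)
    porosity = _get(susp, "cake_porosity", problems, "suspension")

    if None not in (x_cs, x_solute) and abs(x_cs + x_solute + x_ws - 1.0) > 1e-9:
        problems.append("suspension mass fractions must sum to 1")

    def solvent(key: str, role: str) -> SolventSpec | None:
        m = mats.get(key)
        if not isinstance(m, dict):
            problems.append(f"materials.{key} is missing")
            return None
        try:
            return SolventSpec(
                m.get("name", key), m["density_kg_m3"], m["viscosity_Pa_s"], role
            )
        except (KeyError, ValueError) as exc:
            problems.append(f"materials.{key}: {exc}")
            return None

    solute_spec = None
    m = mats.get("solute")
    if not isinstance(m, dict):
        problems.append("materials.solute is missing")
    else:
        try:
            solute_spec = SoluteSpec(
                m.get("name", "solute"), m["crystal_density_kg_m3"], m.get("sphericity", 1.0)
            )
        except (KeyError, ValueError) as exc:
            problems.append(f"materials.solute: {exc}")
    cs = solvent("crystallization_solvent", "crystallization")
    ws = solvent("wash_solvent", "wash")

    curve = None
    if sol:
        try:
            curve = BinarySolubilityCurve(
                np.asarray(sol["w_wash"], dtype=float),
                np.asarray(sol["csat_g_per_g"], dtype=float),
                sol.get("shape", ""),
            )
        except (KeyError, ValueError) as exc:
            problems.append(f"solubility: {exc}")

    psd = None
    if psd_sec and solute_spec is not None and solid_g is not None:
        total = solid_g * GRAM
        try:
            if "table" in psd_sec:
                t = psd_sec["table"]
                lo = np.asarray(t["edge_low_um"], dtype=float) * UM
                hi = np.asarray(t["edge_high_um"], dtype=float) * UM
                frac = np.asarray(t["mass_fraction"], dtype=float)
                if not np.allclose(lo[1:], hi[:-1]):
                    raise ValueError("PSD table bins must be contiguous")
                edges = np.concatenate([lo, hi[-1:]])
                psd = ParticleSizeDistribution(edges, total * frac / frac.sum())
            elif "d50_um" in psd_sec:
                psd = lognormal_psd_from_d50(
                    psd_sec["d50_um"] * UM,
                    psd_sec["std_um"] * UM,
                    psd_sec.get("n_bins", 120),
                    total_mass=total,
                )
            else:
                psd = fit_lognormal_psd(
                    psd_sec["mean_um"] * UM,
                    psd_sec["std_um"] * UM,
                    psd_sec.get("n_bins", 120),
                    weighting=psd_sec.get("weighting", "number"),
                    total_mass=total,
                )
        except (KeyError, ValueError) as exc:
            problems.append(f"psd: {exc}")
    elif not psd_sec:
        problems.append("section 'psd' is missing")

    protocol = None
    try:
        protocol = WashProtocol(
            wash_ratio_max=wash.get("wash_ratio", 2.0),
            flow_mode=wash.get("flow_mode", "constant_pressure"),
            wash_flow_rate=wash.get("wash_flow_rate_m3_s", 1e-7),
            n_layers=wash.get("n_layers", 10),
            molecular_diffusivity=wash.get("molecular_diffusivity_m2_s", 1e-9),
            dispersion_model=wash.get("dispersion_model", "fixed_D"),
            outflow_matched=wash.get("outflow_matched", True),
        )
    except ValueError as exc:
        problems.append(f"wash: {exc}")

    kinetics = None
    if kin is not None:
        try:
            kinetics = DissolutionKinetics(
                rate_constant=kin.get("rate_constant_m_s", 1e-6),
                exponent=kin.get("exponent", 1.0),
                mode=kin.get("mode", "kinetic"),
            )
        except ValueError as exc:
            problems.append(f"kinetics: {exc}")

    conditions = None
    if None not in (dp_mbar, d_mm, r_m):
        try:
            conditions = OperatingConditions(
                pressure_drop=dp_mbar * MBAR,
                filter_diameter=d_mm * MM,
                media_resistance=r_m,
                temperature=temp,
                endpoint_mode=endpoint,
                breakthrough_residual_fraction=residual,
                settling_enabled=op.get("settling_enabled", False),
                settling_exponent=op.get("settling_exponent", 4.65),
            )
        except ValueError as exc:
            problems.append(f"operation: {exc}")

    suspension = None
    if None not in (solid_g, liquid_g, x_cs, x_solute, porosity) and psd is not None:
        try:
            liquid = LiquidState(
                mass_solute=liquid_g * GRAM * x_solute,
                mass_crystallization_solvent=liquid_g * GRAM * x_cs,
                mass_wash_solvent=liquid_g * GRAM * x_ws,
                temperature=temp,
            )
            suspension = SuspensionState(solid_g * GRAM, psd, liquid, porosity)
        except ValueError as exc:
            problems.append(f"suspension: {exc}")

    if problems:
        raise ConfigError(problems)

    system = MaterialSystem(solute_spec, cs, ws, curve)
    return CaseFixture(
        name=doc.get("name", "case"),
        suspension=suspension,
        conditions=conditions,
        protocol=protocol,
        system=system,
        kinetics=kinetics,
        config=doc,
        provenance=doc.get("provenance", {}),
    )


def dump_config(fixture_or_doc) -> str:
    """Serialize the canonical config document to YAML (stable key order)."""
    doc = fixture_or_doc.config if isinstance(fixture_or_doc, CaseFixture) else fixture_or_doc
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


def read_config_file(path) -> CaseFixture:
    with open(path, "r", encoding="utf-8") as fh:
        return load_config(yaml.safe_load(fh))
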