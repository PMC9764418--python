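"""Benchmark case fixtures: the two tabulated isolation cases.

Paracetamol crystallized from isopropanol (washed with water, heptane,
acetonitrile or dodecane) and mefenamic acid from 2-butanol (washed with
heptane). Operating conditions, compositions, porosity and sphericity are
the benchmark values; pure-component densities/viscosities are
literature values at 25 degC and the binary solubility curves are
synthetic curves shipped in ``properties/`` (anchored so the mother liquor
is exactly saturated at wash start), all substitutable by editing the CSVs
or the generated config.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

from .config import CaseFixture, load_config

__all__ = ["FIXTURE_KINDS", "generate_fixture", "fixture_config"]

FIXTURE_KINDS = ("pcm_water", "pcm_heptane", "pcm_acetonitrile", "pcm_dodecane", "ma_heptane")

_WASH_SOLVENT = {
    "pcm_water": "water",
    "pcm_heptane": "heptane",
    "pcm_acetonitrile": "acetonitrile",
    "pcm_dodecane": "dodecane",
    "ma_heptane": "heptane",
}

# bench-tabulated initial filtration conditions (paracetamol / mefenamic acid)
_CASES = {
    "pcm": dict(
        solute="paracetamol",
        crystallization_solvent="isopropanol",
        media_resistance=1e7,
        sphericity=0.4127,
        cake_porosity=0.44,
        solid_mass_g=5.895,
        liquid_mass_g=39.9,
        x_cs=0.88,
        x_solute=0.12,
        d50_um=77.0,
        std_um=174.0,
    ),
    "ma": dict(
        solute="mefenamic_acid",
        crystallization_solvent="2-butanol",
        media_resistance=7.05e7,
        sphericity=0.4680,
        cake_porosity=0.3916,
        solid_mass_g=4.34,
        liquid_mass_g=43.4,
        x_cs=0.93,
        x_solute=0.07,
        d50_um=94.0,
        std_um=174.0,
    ),
}


def _read_properties(filename: str) -> list[dict]:
    ref = resources.files("cakewash").joinpath("properties", filename)
    with ref.open("r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def _solvent_row(name: str) -> dict:
    for row in _read_properties("solvents.csv"):
        if row["name"] == name:
            return row
    raise KeyError(f"unknown solvent {name!r}")


def _solute_row(name: str) -> dict:
    for row in _read_properties("solutes.csv"):
        if row["name"] == name:
            return row
    raise KeyError(f"unknown solute {name!r}")


def _curve_table(kind: str) -> tuple[list[float], list[float]]:
    rows = _read_properties(f"solubility_{kind}.csv")
    return (
        [float(r["w_wash"]) for r in rows],
        [float(r["csat_g_per_g"]) for r in rows],
    )


def fixture_config(kind: str) -> dict:
    """The canonical config document of a named benchmark fixture."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    case = _CASES[kind.split("_", 1)[0]]
    wash_name = _WASH_SOLVENT[kind]
    cs = _solvent_row(case["crystallization_solvent"])
    ws = _solvent_row(wash_name)
    solute = _solute_row(case["solute"])
    w_grid, csat = _curve_table(kind)

    doc = {
        "name": kind,
        "equipment": {
            "filter_diameter_mm": 27,
            "equipment_volume_ml": 50,
        },
        "operation": {
            "driving_force_mbar": 500,
            "media_resistance_per_m": case["media_resistance"],
            "temperature_c": 25,
            "endpoint": "dryland",
            "breakthrough_residual_fraction": 0.10,
            "settling_enabled": False,
            "settling_exponent": 4.65,
        },
        "suspension": {
            "solid_mass_g": case["solid_mass_g"],
            "liquid_mass_g": case["liquid_mass_g"],
            "crystallization_solvent_mass_fraction": case["x_cs"],
            "solute_mass_fraction": case["x_solute"],
            "wash_solvent_mass_fraction": 0.0,
            "cake_porosity": case["cake_porosity"],
        },
        "materials": {
            "solute": {
                "name": case["solute"],
                "crystal_density_kg_m3": float(solute["crystal_density_kg_m3"]),
                "sphericity": case["sphericity"],
            },
            "crystallization_solvent": {
                "name": cs["name"],
                "density_kg_m3": float(cs["density_kg_m3"]),
                "viscosity_Pa_s": float(cs["viscosity_Pa_s"]),
            },
            "wash_solvent": {
                "name": ws["name"],
                "density_kg_m3": float(ws["density_kg_m3"]),
                "viscosity_Pa_s": float(ws["viscosity_Pa_s"]),
            },
        },
        "psd": {"d50_um": case["d50_um"], "std_um": case["std_um"], "n_bins": 120},
        "solubility": {"w_wash": w_grid, "csat_g_per_g": csat},
        "wash": {
            "wash_ratio": 2.0,
            "n_layers": 10,
            "flow_mode": "constant_pressure",
            "wash_flow_rate_m3_s": 1.0e-7,
            "molecular_diffusivity_m2_s": 1.0e-9,
            "dispersion_model": "fixed_D",
            "outflow_matched": True,
        },
        "kinetics": {"rate_constant_m_s": 1.0e-6, "exponent": 1.0, "mode": "kinetic"},
        "provenance": {
            "operating_conditions": "benchmark filtration conditions table (both cases)",
            "densities_viscosities": "literature pure-component values at 25 degC; substitutable",
            "solubility_curve": "synthetic curve anchored at mother-liquor saturation; substitutable",
            "psd": "mass-weighted lognormal matching the tabulated D50 and spread",
        },
    }
    return doc


def generate_fixture(kind: str) -> CaseFixture:
    """Build and validate a complete benchmark fixture by name."""
    return load_config(fixture_config(kind))
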