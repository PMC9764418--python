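"""Model-selection guideline.

A deterministic decision tree mapping suspension traits to the recommended
filtration endpoint and washing model: displacement models for large
particles (low-tortuosity cakes, minimal liquor entrapment) or immiscible
solvent pairs; diffusion-dispersion models for small particles with
miscible solvents; the case-2 (dissolution) variants whenever the solute
is soluble in the solvent mixture. The dilution models (1b/2b) are
reslurry simulators and are never the washing recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GuidelineTraits", "select_model_guideline"]

_OBJECTIVES = ("minimize_residual_liquor", "avoid_cake_stress", "minimize_solvent_use")


@dataclass(frozen=True)
class GuidelineTraits:
    particle_size_class: str  # "large" | "small"
    solvents_miscible: bool
    solute_soluble_in_mixture: bool
    isolation_objective: str = "minimize_residual_liquor"

    def __post_init__(self) -> None:
        if self.particle_size_class not in ("large", "small"):
            raise ValueError("particle_size_class must be 'large' or 'small'")
        if self.isolation_objective not in _OBJECTIVES:
            raise ValueError(f"isolation_objective must be one of {_OBJECTIVES}")


def select_model_guideline(traits: GuidelineTraits) -> tuple[str, str, str]:
    """Return (filtration endpoint, washing model id, rationale)."""
    large = traits.particle_size_class == "large"
    case = "2" if traits.solute_soluble_in_mixture else "1"
    if large or not traits.solvents_miscible:
        mech, mech_why = "a", (
            "displacement: low cake tortuosity / plug-like solvent front"
            if large
            else "displacement: immiscible solvent pair forms a plug interface"
        )
    else:
        mech, mech_why = "c", (
            "diffusion-dispersion: small particles, high tortuosity, "
            "risk of mother-liquor entrapment"
        )
    if large:
        endpoint, end_why = "breakthrough", "large particles deliquor readily"
    elif traits.isolation_objective == "minimize_residual_liquor":
        endpoint, end_why = "breakthrough", "minimize mother liquor left before washing"
    else:
        endpoint, end_why = "dryland", (
            "avoid cake stress during deliquoring"
            if traits.isolation_objective == "avoid_cake_stress"
            else "no rewetting solvent needed"
        )
    sol = (
        "solute soluble in the mixture: include dissolution/deposition"
        if case == "2"
        else "solute insoluble: frozen solid phase"
    )
    return endpoint, case + mech, f"{mech_why}; {sol}; endpoint {endpoint}: {end_why}"
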