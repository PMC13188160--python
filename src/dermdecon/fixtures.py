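"""Named preset scenarios used throughout the docs, CLI, and tests.

The presets bracket the regime spectrum: VX with RSDL is a
diffusion-dominated, low-surface-loss case built from literature
transport and kinetics estimates; the Tabun presets use an evaporation
surface-loss number measured for a highly volatile agent, with and
without a strongly reactive bulk decontaminant.
"""

from __future__ import annotations

from .parameters import AgentScenario, DimensionlessScenario

__all__ = ["FIXTURES", "VX_AGENT", "get_fixture"]

#: Dimensional VX/RSDL inputs (literature estimates): diffusivity,
#: barrier thickness, and the RSDL first-order neutralization rate.
VX_AGENT = AgentScenario(
    name="vx",
    D_sc=4.3e-10,
    h=13.4,
    k_bulk=2.1e-4,
)

FIXTURES: dict[str, DimensionlessScenario] = {
    # VX + RSDL: Da ~ 0.88 from the dimensional inputs above; the surface
    # loss number ~0.17 is an evaporation-only literature estimate (the
    # underlying evaporation inputs are not republished here, so the
    # dimensionless value is stored directly).
    "vx": DimensionlessScenario(Da=0.88, pi_surf=0.17, beta=0.1, name="vx"),
    # Highly volatile agent (Tabun evaporation data) under a strongly
    # reactive bulk decontaminant.
    "tabun-rsdl": DimensionlessScenario(Da=10.0, pi_surf=11.2, beta=0.1, name="tabun-rsdl"),
    # Same surface clearance, no bulk reaction.
    "tabun-evaporation": DimensionlessScenario(
        Da=0.0, pi_surf=11.2, beta=0.1, name="tabun-evaporation"
    ),
    # Diffusion into the sink as the only removal pathway.
    "pure-diffusion": DimensionlessScenario(Da=0.0, pi_surf=0.0, beta=0.1, name="pure-diffusion"),
}


def get_fixture(name: str) -> DimensionlessScenario:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        ) from None
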