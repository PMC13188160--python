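"""Scenario definitions and dimensionless-group computation.

The model reduces a dermal exposure scenario to three dimensionless
numbers:

* ``Da`` — the bulk Damköhler number, ``k_bulk * h**2 / D_sc``, comparing
  the neutralization rate inside the stratum corneum to diffusive
  transport across it.
* ``pi_surf`` — the surface-loss number, the sum of an evaporation part
  ``kappa_evap = k_evap * h / D_sc`` and a surface-reaction part
  ``Da_surf = k_surf * h / D_sc``.  It acts as the Robin (radiation)
  coefficient at the exposed surface.
* ``beta`` — the fraction of the barrier depth over which the finite
  dose is initially deposited.

The characteristic diffusion time ``h**2 / D_sc`` converts dimensionless
time ``tau`` back to minutes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "AgentScenario",
    "DimensionlessScenario",
    "TimeScale",
    "compute_groups",
    "scenario_from_dimensionless",
    "load_scenario",
]

#: Default initial deposit depth fraction for finite-dose exposures.
DEFAULT_BETA = 0.1

_UM_TO_CM = 1e-4
_SEC_TO_MIN = 1.0 / 60.0


class AgentScenario(BaseModel):
    """Dimensional description of an agent/decontaminant/exposure triple.

    Units follow common experimental reporting: diffusivity in cm²/s,
    thickness in μm, the bulk neutralization rate constant in s⁻¹, and
    the surface mass-transfer velocities in cm/s.  Vapor pressure is
    carried as metadata only; no evaporation correlation is applied, so
    evaporative clearance must be supplied as ``k_evap``.
    """

    model_config = ConfigDict(frozen=True)

    name: str = "scenario"
    D_sc: float = Field(gt=0, description="Stratum corneum diffusivity, cm²/s")
    h: float = Field(gt=0, description="Stratum corneum thickness, μm")
    k_bulk: float = Field(default=0.0, ge=0, description="First-order bulk neutralization rate, s⁻¹")
    k_surf: float = Field(default=0.0, ge=0, description="Interfacial reaction mass-transfer velocity, cm/s")
    k_evap: float = Field(default=0.0, ge=0, description="Evaporation mass-transfer velocity, cm/s")
    P_vap: Optional[float] = Field(default=None, description="Vapor pressure, mmHg (metadata only)")
    beta: float = Field(default=DEFAULT_BETA, gt=0, le=1, description="Initial deposit depth fraction")


class DimensionlessScenario(BaseModel):
    """A ``(Da, pi_surf, beta)`` triple, optionally with the surface split.

    When ``kappa_evap`` and ``Da_surf`` are both given they must sum to
    ``pi_surf``; the split lets downstream consumers build an
    evaporation-only baseline for decontamination comparisons.
    """

    model_config = ConfigDict(frozen=True)

    Da: float = Field(ge=0)
    pi_surf: float = Field(ge=0)
    beta: float = Field(default=DEFAULT_BETA, gt=0, le=1)
    kappa_evap: Optional[float] = Field(default=None, ge=0)
    Da_surf: Optional[float] = Field(default=None, ge=0)
    name: str = "scenario"

    @model_validator(mode="after")
    def _check_split(self) -> "DimensionlessScenario":
        if (self.kappa_evap is None) != (self.Da_surf is None):
            raise ValueError("kappa_evap and Da_surf must be supplied together")
        if self.kappa_evap is not None:
            total = self.kappa_evap + self.Da_surf
            if abs(total - self.pi_surf) > 1e-9 * max(1.0, self.pi_surf):
                raise ValueError(
                    f"pi_surf split inconsistent: kappa_evap + Da_surf = {total!r} "
                    f"but pi_surf = {self.pi_surf!r}"
                )
        return self

    @property
    def has_split(self) -> bool:
        return self.kappa_evap is not None


class TimeScale(BaseModel):
    """Characteristic diffusion time ``h**2 / D_sc`` in minutes.

    Multiplying a dimensionless time ``tau`` by :attr:`to_minutes`
    yields wall-clock minutes.
    """

    model_config = ConfigDict(frozen=True)

    t_diff: float = Field(gt=0, description="Characteristic diffusion time, minutes")

    @property
    def to_minutes(self) -> float:
        return self.t_diff


def compute_groups(agent: AgentScenario) -> tuple[DimensionlessScenario, TimeScale]:
    """Reduce a dimensional scenario to its dimensionless groups.

    Returns the ``(Da, pi_surf, beta)`` scenario (with the
    evaporation/surface-reaction split of ``pi_surf``) and the diffusion
    time scale in minutes.
    """
    h_cm = agent.h * _UM_TO_CM
    Da = agent.k_bulk * h_cm**2 / agent.D_sc
    kappa_evap = agent.k_evap * h_cm / agent.D_sc
    Da_surf = agent.k_surf * h_cm / agent.D_sc
    scenario = DimensionlessScenario(
        Da=Da,
        pi_surf=kappa_evap + Da_surf,
        beta=agent.beta,
        kappa_evap=kappa_evap,
        Da_surf=Da_surf,
        name=agent.name,
    )
    t_diff_min = h_cm**2 / agent.D_sc * _SEC_TO_MIN
    return scenario, TimeScale(t_diff=t_diff_min)


def scenario_from_dimensionless(
    Da: float,
    pi_surf: float,
    beta: float = DEFAULT_BETA,
    name: str = "scenario",
) -> DimensionlessScenario:
    """Validate and wrap a directly supplied ``(Da, pi_surf, beta)`` triple."""
    return DimensionlessScenario(Da=Da, pi_surf=pi_surf, beta=beta, name=name)


_SCENARIO_KEYS = {
    "D_sc_cm2_s": "D_sc",
    "h_um": "h",
    "k_bulk_per_s": "k_bulk",
    "k_surf_cm_s": "k_surf",
    "k_evap_cm_s": "k_evap",
    "P_vap_mmHg": "P_vap",
    "beta": "beta",
    "name": "name",
}


def load_scenario(path: Union[str, Path]) -> AgentScenario:
    """Read a dimensional scenario from a JSON file.

    Expected keys: ``name``, ``D_sc_cm2_s``, ``h_um``, ``k_bulk_per_s``,
    ``k_surf_cm_s``, ``k_evap_cm_s``, optional ``P_vap_mmHg`` and
    ``beta`` (default 0.1).
    """
    raw = json.loads(Path(path).read_text())
    unknown = set(raw) - set(_SCENARIO_KEYS)
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return AgentScenario(**{_SCENARIO_KEYS[k]: v for k, v in raw.items()})
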