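"""Closed-form steady-state mass partitioning.

The asymptotic fate of the deposit follows from splitting probabilities:
for a particle started at depth x, the probability of reaching the inner
sink before being removed at the surface or consumed in the bulk solves
the stationary boundary-value problem

    u_abs'' = Da·u_abs,  u_abs(1) = 1,  u_abs'(0) = pi_surf·u_abs(0),

and the surface-exit probability solves the companion problem

    u_surf'' = Da·u_surf,  u_surf(1) = 0,  u_surf'(0) = pi_surf·(u_surf(0) − 1).

Averaging each over the deposit depth [0, beta] (exact antiderivatives,
no quadrature) gives M_abs(inf) and M_surf(inf); the reacted fraction is
the complement.  With q = sqrt(Da):

    u_abs(x)  = [pi_surf·sinh(qx) + q·cosh(qx)] / [pi_surf·sinh(q) + q·cosh(q)]
    u_surf(x) = pi_surf·sinh(q(1 − x)) / [pi_surf·sinh(q) + q·cosh(q)]

For Da = 0 these degenerate to the linear splitting solution
``u_abs = (pi_surf·x + 1)/(pi_surf + 1)``.  The implementation rescales
the hyperbolic forms by exp(−q) so that large Da cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import DimensionlessScenario

__all__ = ["SteadyFractions", "steady_fractions", "steady_absorbed"]


@dataclass(frozen=True)
class SteadyFractions:
    """Asymptotic absorbed / surface-lost / reacted fractions (sum to 1)."""

    M_abs_inf: float
    M_surf_inf: float
    M_reac_inf: float
    scenario: DimensionlessScenario


def _absorbed(Da, pi_surf, beta):
    """Deposit-averaged absorption probability; array-safe in Da and pi_surf."""
    Da = np.asarray(Da, dtype=float)
    pi_surf = np.asarray(pi_surf, dtype=float)
    q = np.sqrt(Da)
    with np.errstate(invalid="ignore", divide="ignore"):
        # Scaled by 2·exp(−q): every exponent is ≤ 0, so no overflow.
        num = np.exp(-q) * (
            4.0 * pi_surf * np.sinh(q * beta / 2.0) ** 2 / q + 2.0 * np.sinh(q * beta)
        )
        den = pi_surf * (-np.expm1(-2.0 * q)) + q * (1.0 + np.exp(-2.0 * q))
        hyperbolic = num / (beta * den)
    linear = (pi_surf * beta / 2.0 + 1.0) / (pi_surf + 1.0)
    return np.where(Da > 0, hyperbolic, linear)


def _surface(Da, pi_surf, beta):
    """Deposit-averaged surface-exit probability; array-safe."""
    Da = np.asarray(Da, dtype=float)
    pi_surf = np.asarray(pi_surf, dtype=float)
    q = np.sqrt(Da)
    with np.errstate(invalid="ignore", divide="ignore"):
        # 2·exp(−q)·(cosh q − cosh(q(1−beta))) = expm1(−q·beta)·expm1(−q(2−beta))
        num = pi_surf * np.expm1(-q * beta) * np.expm1(-q * (2.0 - beta))
        den = pi_surf * (-np.expm1(-2.0 * q)) + q * (1.0 + np.exp(-2.0 * q))
        hyperbolic = num / (q * beta * den)
    linear = pi_surf * (1.0 - beta / 2.0) / (pi_surf + 1.0)
    return np.where(Da > 0, hyperbolic, linear)


def steady_absorbed(Da, pi_surf, beta: float = 0.1):
    """Vectorized steady-state absorbed fraction (used by the risk map)."""
    return _absorbed(Da, pi_surf, beta)


def steady_fractions(scenario: DimensionlessScenario) -> SteadyFractions:
    """Exact steady-state partitioning of the deposit for ``scenario``.

    The absorbed and surface fractions come from the closed-form
    splitting probabilities; the reacted fraction is obtained by mass
    conservation, so the three always sum to one.
    """
    m_abs = float(_absorbed(scenario.Da, scenario.pi_surf, scenario.beta))
    m_surf = float(_surface(scenario.Da, scenario.pi_surf, scenario.beta))
    return SteadyFractions(
        M_abs_inf=m_abs,
        M_surf_inf=m_surf,
        M_reac_inf=1.0 - m_abs - m_surf,
        scenario=scenario,
    )
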