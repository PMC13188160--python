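"""Sturm–Liouville eigensystem of the slab with surface loss.

The dimensionless governing system is

    dc/dtau = d²c/dx² − Da·c            on x in (0, 1)
    dc/dx(0, tau) = pi_surf · c(0, tau)  (Robin surface loss at x = 0)
    c(1, tau) = 0                        (perfect sink at x = 1)
    c(x, 0) = 1/beta on [0, beta], 0 elsewhere (unit total deposit)

Separation of variables with eigenfunctions phi_n(x) = sin(lambda_n (1 − x))
requires the spatial eigenvalues to satisfy the transcendental condition

    lambda·cos(lambda) + pi_surf·sin(lambda) = 0,

with exactly one root per interval ((n − 1/2)·pi, n·pi).  The temporal
decay rates are mu_n = lambda_n² + Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .parameters import DimensionlessScenario

__all__ = ["EigenSystem", "solve_eigenvalues", "build_eigensystem"]

#: Default number of series terms.  Chosen so that the truncated initial
#: deposit carries unit mass to well under 1e-6 even for strongly
#: loss-dominated surfaces (pi_surf > 10), where the expansion converges
#: most slowly.
DEFAULT_N_TERMS = 400

_BRACKET_EPS = 1e-9


def _characteristic(lam: float, pi_surf: float) -> float:
    return lam * np.cos(lam) + pi_surf * np.sin(lam)


def solve_eigenvalues(pi_surf: float, n_terms: int) -> np.ndarray:
    """First ``n_terms`` roots of ``lambda·cos(lambda) = −pi_surf·sin(lambda)``.

    One root lies in each interval ``((n − 1/2)·pi, n·pi]``.  For
    ``pi_surf = 0`` the roots are exactly ``(n − 1/2)·pi`` (no-flux
    surface); as ``pi_surf → ∞`` they approach ``n·pi`` (Dirichlet
    surface).

    Parameters
    ----------
    pi_surf
        Surface-loss number (Robin coefficient), ≥ 0.
    n_terms
        Number of eigenvalues, ≥ 1.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if pi_surf < 0:
        raise ValueError("pi_surf must be >= 0")
    n = np.arange(1, n_terms + 1)
    if pi_surf == 0.0:
        return (n - 0.5) * np.pi

    lambdas = np.empty(n_terms)
    for i, k in enumerate(n):
        lo = (k - 0.5) * np.pi + _BRACKET_EPS
        hi = k * np.pi - _BRACKET_EPS
        try:
            lambdas[i] = brentq(
                _characteristic, lo, hi, args=(pi_surf,), xtol=1e-14, rtol=8.9e-16
            )
        except ValueError as exc:  # pragma: no cover - bracket is provably sign-changing
            raise RuntimeError(
                f"eigenvalue search failed in interval ({lo}, {hi}): {exc}"
            ) from exc
        # Residual guard against a silently bad root.  A machine-accurate
        # root still carries a residual of order lam * |f'(lam)| * eps
        # (f' ~ lam + pi_surf), so the tolerance scales accordingly.
        lam_i = lambdas[i]
        res = _characteristic(lam_i, pi_surf)
        tol = max(1e-10, 1e3 * np.finfo(float).eps * lam_i * (lam_i + pi_surf + 1.0))
        if abs(res) > tol:
            raise RuntimeError(
                f"eigenvalue in interval ({lo}, {hi}) did not converge: residual {res:g}"
            )
    return lambdas


@dataclass(frozen=True)
class EigenSystem:
    """Eigenvalues and expansion coefficients for one scenario.

    ``c(x, tau) = sum_n A_n exp(−mu_n tau) sin(lambda_n (1 − x))`` with
    ``A_n`` projecting the uniform deposit on ``[0, beta]`` (unit total
    mass) onto the eigenbasis.
    """

    lambdas: np.ndarray
    mus: np.ndarray
    A: np.ndarray
    n_terms: int
    Da: float
    pi_surf: float
    beta: float
    # cached trigonometric factors reused by every pathway formula
    sin_lam: np.ndarray = field(repr=False, default=None)
    one_minus_cos: np.ndarray = field(repr=False, default=None)

    @property
    def deposit_mass(self) -> float:
        """Mass of the truncated series representation of the deposit.

        Approaches 1 as ``n_terms`` grows; the shortfall bounds the
        conservation error of every transient curve.
        """
        return float(np.sum(self.A * self.one_minus_cos / self.lambdas))

    def pathway_weights(self) -> dict[str, np.ndarray]:
        """Modal rate coefficients ``r_n`` of the three cumulative pathways.

        ``M_p(tau) = sum_n (r_n / mu_n) (1 − exp(−mu_n tau))`` for each
        pathway p in {abs, surf, reac}.
        """
        return {
            "abs": self.A * self.lambdas,
            "surf": self.pi_surf * self.A * self.sin_lam,
            "reac": self.Da * self.A * self.one_minus_cos / self.lambdas,
        }


def build_eigensystem(
    scenario: DimensionlessScenario, n_terms: int = DEFAULT_N_TERMS
) -> EigenSystem:
    """Assemble the eigen expansion of the initial deposit for ``scenario``.

    The expansion coefficients follow from orthogonality of
    ``sin(lambda_n (1 − x))`` under the Robin/Dirichlet boundary pair:

        A_n = [cos(lambda_n (1 − beta)) − cos(lambda_n)] / (beta lambda_n N_n)
        N_n = 1/2 − sin(2 lambda_n) / (4 lambda_n)
    """
    lam = solve_eigenvalues(scenario.pi_surf, n_terms)
    norm = 0.5 - np.sin(2 * lam) / (4 * lam)
    A = (np.cos(lam * (1 - scenario.beta)) - np.cos(lam)) / (scenario.beta * lam * norm)
    mu = lam**2 + scenario.Da
    return EigenSystem(
        lambdas=lam,
        mus=mu,
        A=A,
        n_terms=n_terms,
        Da=scenario.Da,
        pi_surf=scenario.pi_surf,
        beta=scenario.beta,
        sin_lam=np.sin(lam),
        one_minus_cos=1.0 - np.cos(lam),
    )
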