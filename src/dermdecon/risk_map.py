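"""Steady-state absorption risk map over the Da–pi_surf plane.

A deterministic grid sweep of the closed-form steady absorbed fraction,
labeled into risk zones: "safer" where less than 20% of the deposit is
ever absorbed, "high-risk" where the majority (more than 50%) is
absorbed, and "intermediate" between.  Both thresholds are arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .steady_state import steady_absorbed

__all__ = ["RiskMap", "build_risk_map", "DEFAULT_DA_RANGE", "DEFAULT_PI_RANGE"]

#: Default sweep ranges spanning diffusion- to reaction-dominated
#: behavior and surface-loss numbers typical of volatile agents.
DEFAULT_DA_RANGE = (0.0, 10.0)
DEFAULT_PI_RANGE = (0.4, 2.0)

SAFER_THRESHOLD = 0.20
HIGH_RISK_THRESHOLD = 0.50


@dataclass(frozen=True)
class RiskMap:
    """Grid of steady absorbed fractions with risk-zone labels.

    ``m_abs_inf`` and ``zone`` are indexed ``[i_pi, i_da]``.
    """

    da_axis: np.ndarray
    pi_axis: np.ndarray
    m_abs_inf: np.ndarray
    zone: np.ndarray
    beta: float
    safer_threshold: float = SAFER_THRESHOLD
    high_risk_threshold: float = HIGH_RISK_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (da, pi_surf) grid node."""
        da, pi = np.meshgrid(self.da_axis, self.pi_axis)
        return pd.DataFrame(
            {
                "da": da.ravel(),
                "pi_surf": pi.ravel(),
                "m_abs_inf": self.m_abs_inf.ravel(),
                "zone": self.zone.ravel(),
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def plot(self, path: Optional[Union[str, Path]] = None):
        """Heat map with the safer-zone contour; returns the figure."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6.5, 5))
        mesh = ax.pcolormesh(
            self.da_axis, self.pi_axis, self.m_abs_inf, shading="auto", cmap="RdYlGn_r"
        )
        ax.contour(
            self.da_axis,
            self.pi_axis,
            self.m_abs_inf,
            levels=[self.safer_threshold],
            colors="k",
            linewidths=1.5,
        )
        fig.colorbar(mesh, ax=ax, label=r"$M_{abs}(\infty)$")
        ax.set_xlabel(r"$Da$")
        ax.set_ylabel(r"$\pi_{surf}$")
        ax.set_title(f"Steady-state absorption risk map (beta = {self.beta:g})")
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig


def build_risk_map(
    da_range: tuple[float, float] = DEFAULT_DA_RANGE,
    pi_range: tuple[float, float] = DEFAULT_PI_RANGE,
    resolution: int = 101,
    beta: float = 0.1,
    safer_threshold: float = SAFER_THRESHOLD,
    high_risk_threshold: float = HIGH_RISK_THRESHOLD,
) -> RiskMap:
    """Evaluate the steady absorbed fraction on a ``resolution²`` grid.

    The absorbed fraction is non-increasing in both Da and pi_surf, so
    the safer zone is always an upper-right region of the map.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if not (da_range[1] > da_range[0]) or not (pi_range[1] > pi_range[0]):
        raise ValueError("ranges must be non-degenerate (max > min)")
    if not (0 <= safer_threshold < high_risk_threshold <= 1):
        raise ValueError("thresholds must satisfy 0 <= safer < high-risk <= 1")
    da_axis = np.linspace(da_range[0], da_range[1], resolution)
    pi_axis = np.linspace(pi_range[0], pi_range[1], resolution)
    da, pi = np.meshgrid(da_axis, pi_axis)
    m = steady_absorbed(da, pi, beta)
    zone = np.where(
        m < safer_threshold, "safer", np.where(m > high_risk_threshold, "high-risk", "intermediate")
    )
    return RiskMap(
        da_axis=da_axis,
        pi_axis=pi_axis,
        m_abs_inf=m,
        zone=zone,
        beta=beta,
        safer_threshold=safer_threshold,
        high_risk_threshold=high_risk_threshold,
    )
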