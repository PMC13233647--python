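"""Interstitial fluid pressure (IFP) and velocity, and the steplike
post-sonication modulation of transport parameters.

The fluid problem is the steady source-sink Darcy balance of the
Baxter-Jain framework: vessels leak plasma at rate Lp Sv (p_v - p) inside
the tumor, the interstitium conducts with hydraulic conductivity k_th, and
the far boundary is the zero-pressure gauge where host lymphatics drain.
Fluid equilibrates within minutes, so the IFP field is re-solved
quasi-statically whenever a modulated parameter changes rather than being
integrated in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import SECONDS_PER_HOUR
from .grid import RadialGrid

__all__ = [
    "FluidParams",
    "FUSModulation",
    "modulated_parameter",
    "solve_ifp",
    "interstitial_velocity",
]


@dataclass(frozen=True)
class FluidParams:
    """Interstitial/vascular fluid parameters on the tumor domain."""

    k_th: float = 3.1e-14  # interstitial hydraulic conductivity, m^2/(Pa s)
    Lp: float = 3.6e-11  # vessel wall hydraulic conductivity, m/(Pa s)
    S_v: float = 2.0e4  # vascular density, m^2/m^3
    p_v: float = 2.66e3  # microvascular pressure, Pa
    R_tumor: float = 3.6e-3  # tumor radius, m

    def __post_init__(self) -> None:
        if min(self.k_th, self.Lp, self.S_v, self.p_v, self.R_tumor) <= 0:
            raise ValueError("fluid parameters must be positive")

    @property
    def alpha_b(self) -> float:
        """Dimensionless leakiness ratio R sqrt(Lp Sv / k_th)."""
        return self.R_tumor * np.sqrt(self.Lp * self.S_v / self.k_th)


@dataclass(frozen=True)
class FUSModulation:
    """Steplike post-sonication enhancement of interstitial and wall transport.

    Sonication multiplies the interstitial hydraulic conductivity k_th by
    ``a_p_kth`` (default x5) and the effective vessel-wall porosity gamma by
    ``a_p_gamma`` (default x1.5) for ``persistence`` seconds (default 24 h),
    after which both revert to baseline.
    """

    a_p_kth: float = 5.0
    a_p_gamma: float = 1.5
    t_FUS: float = 0.0
    persistence: float = 24.0 * SECONDS_PER_HOUR

    def __post_init__(self) -> None:
        if self.a_p_kth <= 0 or self.a_p_gamma <= 0:
            raise ValueError("modulation multipliers must be positive")
        if self.persistence < 0:
            raise ValueError("persistence must be nonnegative")

    def active(self, t: float) -> bool:
        return self.t_FUS <= t < self.t_FUS + self.persistence

    def multiplier(self, which: str, t: float) -> float:
        if which not in ("k_th", "gamma"):
            raise ValueError("selector must be 'k_th' or 'gamma'")
        if not self.active(t):
            return 1.0
        return self.a_p_kth if which == "k_th" else self.a_p_gamma


def modulated_parameter(par0: float, mod: FUSModulation, which: str, t: float) -> float:
    """Parameter value at time t under the half-open modulation window
    [t_FUS, t_FUS + persistence); reverts exactly at the window end."""
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    return par0 * mod.multiplier(which, t)


def solve_ifp(
    params: FluidParams,
    grid: RadialGrid,
    sigma_f_plasma: float = 0.0,
    osmotic_pressure_difference: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady radial IFP field and Darcy velocity.

    Inside the tumor (r <= R_tumor): k_th lap(p) + Lp Sv (p_v - p - sigma dpi) = 0;
    outside: pure conduction; far boundary p = 0 (gauge).  Osmotic filtration
    is off by default (dpi = 0).  Returns (p, v) with v = -k_th dp/dr.
    """
    n = grid.n
    source_mask = grid.r <= params.R_tumor + 1e-12
    ls = params.Lp * params.S_v
    p_eff = params.p_v - sigma_f_plasma * osmotic_pressure_difference

    L = grid.diffusion_matrix(params.k_th)
    A = sp.lil_matrix(-L)
    rhs = np.zeros(n)
    for i in range(n):
        if source_mask[i]:
            A[i, i] += ls
            rhs[i] += ls * p_eff
    # far Dirichlet p = 0
    A[n - 1, :] = 0.0
    A[n - 1, n - 1] = 1.0
    rhs[n - 1] = 0.0
    p = spla.spsolve(A.tocsr(), rhs)
    if not np.all(np.isfinite(p)):
        raise RuntimeError("IFP solve failed to produce a finite pressure field")
    v = interstitial_velocity(p, params.k_th, grid)
    return p, v


def interstitial_velocity(p: np.ndarray, k_th: float, grid: RadialGrid) -> np.ndarray:
    """Darcy velocity v = -k_th dp/dr at the nodes (zero at the center)."""
    v = np.empty_like(p)
    v[1:-1] = -k_th * (p[2:] - p[:-2]) / (2.0 * grid.dr)
    v[0] = 0.0
    v[-1] = -k_th * (p[-1] - p[-2]) / grid.dr
    return v


def ifp_closed_form(params: FluidParams, r: np.ndarray) -> np.ndarray:
    """Classical sinh-profile solution on a tumor-only domain with p(R)=0.

    p(r)/p_v = 1 - (R/r) sinh(aB r/R) / sinh(aB), with the r -> 0 limit
    1 - aB/sinh(aB).  Serves as the analytic reference for the numerical
    solver on matched domains.
    """
    ab = params.alpha_b
    rr = np.asarray(r, dtype=float) / params.R_tumor
    out = np.empty_like(rr)
    small = rr < 1e-12
    out[~small] = 1.0 - np.sinh(ab * rr[~small]) / (rr[~small] * np.sinh(ab))
    out[small] = 1.0 - ab / np.sinh(ab)
    return params.p_v * out
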