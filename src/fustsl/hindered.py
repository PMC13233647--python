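"""Hindered transport of spherical particles through cylindrical vessel-wall pores.

Pore-scale hydrodynamic theory (Deen, AIChE J. 33:1409, 1987) gives the vessel
wall hydraulic conductivity L_p, the vascular permeability P_er and the
solute reflection coefficient sigma_f as functions of the size ratio
lambda = r_s / r_0 between the diffusing particle and the pore.  These three
numbers parameterize Starling transvascular exchange in the drug-transport
solver and drive the particle-size / pore-size sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import BOLTZMANN, WATER_VISCOSITY_310K

__all__ = [
    "ParticleSpec",
    "VesselWall",
    "HindranceResult",
    "SeriesAccuracyWarning",
    "partition_coefficient",
    "series_coefficients",
    "hindrance_factors",
    "free_diffusivity",
    "wall_transport",
]


class SeriesAccuracyWarning(UserWarning):
    """Raised when lambda is close enough to 1 that the asymptotic series degrades."""


# Bungay & Brenner centerline coefficients as tabulated by Deen (1987),
# Table 1: a_n feed the hydrodynamic series K_t, b_n the convective series K_s.
# a1, a2 (b1, b2) multiply (1-lam)^n inside the singular bracket; a3..a7
# (b3..b7) multiply lam^0..lam^4 in the regular part.
_A_COEF = (-73.0 / 60.0, 77293.0 / 50400.0, -22.5083, -5.6117, -0.3363, -1.216, 1.647)
_B_COEF = (7.0 / 60.0, -2227.0 / 50400.0, 4.0180, -3.9788, -1.9215, 4.392, 5.006)

_SERIES_WARN_LAMBDA = 0.95


@dataclass(frozen=True)
class ParticleSpec:
    """A thermosensitive-liposome formulation as a transported particle.

    r_s: particle radius (m); alpha_payload: drug molecules per carrier;
    D_l / D_f: interstitial diffusivities of the carrier and of the free drug
    (m^2/s); k_d: plasma circulation decay constant (s); t0: injection time (s).
    """

    r_s: float
    alpha_payload: float = 1.0e4
    D_l: float = 5.0e-13
    D_f: float = 2.0e-10
    k_d: float = 7.2e3
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.r_s <= 0:
            raise ValueError(f"particle radius must be positive, got {self.r_s}")
        if self.alpha_payload < 1:
            raise ValueError("payload must be >= 1 drug molecule per carrier")
        if self.D_l <= 0 or self.D_f <= 0:
            raise ValueError("diffusivities must be positive")
        if self.k_d <= 0:
            raise ValueError("plasma decay constant must be positive")


@dataclass(frozen=True)
class VesselWall:
    """Tumor vessel-wall geometry and vascular parameters.

    r_0: pore radius (m); L_vw: wall thickness (m); gamma: effective porosity
    (area fraction of wall occupied by pores); S_v: vascular density (m^2/m^3);
    p_v: microvascular pressure (Pa).
    """

    r_0: float
    L_vw: float = 5.0e-6
    gamma: float = 1.0e-4
    S_v: float = 2.0e4
    p_v: float = 2.66e3

    def __post_init__(self) -> None:
        if self.r_0 <= 0:
            raise ValueError(f"pore radius must be positive, got {self.r_0}")
        if self.L_vw <= 0:
            raise ValueError("wall thickness must be positive")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"porosity must be in (0, 1], got {self.gamma}")
        if self.S_v < 0:
            raise ValueError("vascular density must be nonnegative")


@dataclass(frozen=True)
class HindranceResult:
    lam: float
    F: float
    Kt: float
    Ks: float
    H: float
    W: float
    Lp: float
    Per: float
    sigma_f: float
    D0: float
    excluded: bool = False


def partition_coefficient(lam: float) -> float:
    """Equilibrium partition coefficient F = 1 - lambda^2 of a sphere in a pore."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"size ratio lambda must be in [0, 1], got {lam}")
    return 1.0 - lam * lam


def series_coefficients(lam: float) -> tuple[float, float]:
    """Hydrodynamic series coefficients (K_t, K_s) for centerline transport.

    Two-part asymptotic expansion: a lubrication-singular bracket scaling as
    (1-lam)^(-5/2) plus a regular polynomial in lambda.  Accurate for
    lam < ~0.95; beyond that a SeriesAccuracyWarning is emitted because the
    truncation error is amplified by the singular prefactor.
    """
    if lam < 0.0 or lam >= 1.0:
        raise ValueError(f"series defined for 0 <= lambda < 1, got {lam}")
    if lam >= _SERIES_WARN_LAMBDA:
        warnings.warn(
            f"series accuracy degrades for lambda={lam:.3f} >= {_SERIES_WARN_LAMBDA}",
            SeriesAccuracyWarning,
            stacklevel=2,
        )
    one_m = 1.0 - lam
    prefac = 2.25 * np.pi**2 * np.sqrt(2.0) * one_m ** (-2.5)

    def _eval(coef: tuple[float, ...]) -> float:
        singular = prefac * (1.0 + coef[0] * one_m + coef[1] * one_m**2)
        regular = sum(coef[2 + n] * lam**n for n in range(5))
        return singular + regular

    return _eval(_A_COEF), _eval(_B_COEF)


def hindrance_factors(lam: float) -> tuple[float, float]:
    """Diffusive (H) and convective (W) hindrance factors, both -> 1 as lam -> 0."""
    kt, ks = series_coefficients(lam)
    f = partition_coefficient(lam)
    h = 6.0 * np.pi * f / kt
    w = f * (2.0 - f) * ks / (2.0 * kt)
    return h, w


def free_diffusivity(
    r_s: float, T_emp: float = 310.0, eta: float = WATER_VISCOSITY_310K
) -> float:
    """Stokes-Einstein free-solution diffusivity D0 = kB T / (6 pi eta r_s)."""
    if r_s <= 0 or T_emp <= 0 or eta <= 0:
        raise ValueError(
            f"free_diffusivity needs positive inputs, got r_s={r_s}, T={T_emp}, eta={eta}"
        )
    return BOLTZMANN * T_emp / (6.0 * np.pi * eta * r_s)


def wall_transport(
    wall: VesselWall,
    particle: ParticleSpec,
    T_emp: float = 310.0,
    eta: float = WATER_VISCOSITY_310K,
    oxygen_mode: bool = False,
) -> HindranceResult:
    """Full vessel-wall transport coefficients for a particle/pore pair.

    L_p = gamma r_0^2 / (8 eta L_vw)        (particle-independent)
    P_er = gamma H D0 / L_vw
    sigma_f = 1 - W

    A particle at least as large as the pore is returned as fully excluded
    (P_er = 0, sigma_f = 1) rather than raising, so size sweeps can cross
    lambda = 1 gracefully.  ``oxygen_mode`` forces gamma = H = 1, modeling a
    small solute that crosses the wall unhindered.
    """
    d0 = free_diffusivity(particle.r_s, T_emp, eta)
    lp = wall.gamma * wall.r_0**2 / (8.0 * eta * wall.L_vw)
    lam = particle.r_s / wall.r_0
    if oxygen_mode:
        return HindranceResult(
            lam=lam, F=1.0, Kt=float("nan"), Ks=float("nan"), H=1.0, W=1.0,
            Lp=lp, Per=d0 / wall.L_vw, sigma_f=0.0, D0=d0,
        )
    if lam >= 1.0:
        return HindranceResult(
            lam=lam, F=0.0, Kt=float("inf"), Ks=float("inf"), H=0.0, W=0.0,
            Lp=lp, Per=0.0, sigma_f=1.0, D0=d0, excluded=True,
        )
    kt, ks = series_coefficients(lam)
    f = partition_coefficient(lam)
    h, w = hindrance_factors(lam)
    return HindranceResult(
        lam=lam, F=f, Kt=kt, Ks=ks, H=h, W=w,
        Lp=lp, Per=wall.gamma * h * d0 / wall.L_vw, sigma_f=1.0 - w, D0=d0,
    )


def hindrance_table(
    wall: VesselWall,
    particle: ParticleSpec,
    lam_grid: np.ndarray,
    T_emp: float = 310.0,
    eta: float = WATER_VISCOSITY_310K,
):
    """Tabulate (lam, F, H, W, Lp, Per, sigma_f) over a lambda grid (CSV export)."""
    import pandas as pd

    rows = []
    for lam in np.asarray(lam_grid, dtype=float):
        p = ParticleSpec(
            r_s=max(lam, 1e-4) * wall.r_0,
            alpha_payload=particle.alpha_payload,
            D_l=particle.D_l,
            D_f=particle.D_f,
            k_d=particle.k_d,
            t0=particle.t0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeriesAccuracyWarning)
            h = wall_transport(wall, p, T_emp, eta)
        rows.append(
            dict(lam=h.lam, F=h.F, H=h.H, W=h.W, Lp=h.Lp, Per=h.Per, sigma_f=h.sigma_f)
        )
    return pd.DataFrame(rows)
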