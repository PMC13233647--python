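"""Transient bio-heat transfer on the radial grid.

The energy balance rho_t c_t dT/dt = k_t lap(T) + Q_m + Q_ex is integrated
with an unconditionally stable implicit (backward Euler) scheme; thermal
properties may be evaluated from the temperature-dependent quintic fits
(property feedback, lagged one step).  The printed balance carries no
perfusion heat sink; an optional Pennes-style sink w_b*(T_body - T) is
available and off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import CELSIUS_OFFSET, T_BODY
from .grid import RadialGrid

__all__ = [
    "ThermalProperties",
    "TemperatureField",
    "temperature_dependent_properties",
    "step_bhte",
    "BioheatSolver",
]

_T_MIN, _T_MAX = 273.0, 350.0


@dataclass(frozen=True)
class ThermalProperties:
    rho_t0: float = 1050.0  # kg/m^3
    c_t0: float = 3600.0  # J/(kg K)
    k_t0: float = 0.52  # W/(m K)
    Q_m: float = 0.0  # W/m^3; negligible next to hyperthermic deposition

    def __post_init__(self) -> None:
        if min(self.rho_t0, self.c_t0, self.k_t0) <= 0 or self.Q_m < 0:
            raise ValueError("thermal properties must be positive (Q_m nonnegative)")


@dataclass
class TemperatureField:
    T: np.ndarray  # K per node
    t: float = 0.0  # s

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if np.any(self.T < _T_MIN) or np.any(self.T > _T_MAX):
            raise ValueError("temperature outside the [273, 350] K sanity band")

    @property
    def celsius(self) -> np.ndarray:
        return self.T - CELSIUS_OFFSET


# Quintic property fits; the polynomial argument is the temperature in degC
# (Kelvin magnitudes drive the printed coefficients far outside physical
# ranges).  Coefficients ordered from the linear to the quintic term.
_RHO_POLY = (-2.97434, 0.0042, 0.00293, -6.14447e-5, 3.33019e-7)
_C_POLY = (53.55552, -3.96009, 0.10084, -0.00106, 4.01666e-6)
_K_POLY = (-0.02094, 3.89971e-4, -5.47541e-7, -4.14455e-8, 2.97188e-10)


def _poly_delta(coef: tuple[float, ...], t_c: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t_c)
    for n, c in enumerate(coef, start=1):
        out += c * t_c**n
    return out


def temperature_dependent_properties(
    T, base: ThermalProperties
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rho_t, c_t, k_t) at absolute temperature T (K), scalar or array."""
    t_arr = np.asarray(T, dtype=float)
    if np.any(t_arr < _T_MIN) or np.any(t_arr > _T_MAX):
        raise ValueError("temperature outside the [273, 350] K sanity band")
    t_c = t_arr - CELSIUS_OFFSET
    rho = base.rho_t0 + _poly_delta(_RHO_POLY, t_c)
    c = base.c_t0 + _poly_delta(_C_POLY, t_c)
    k = base.k_t0 + _poly_delta(_K_POLY, t_c)
    for name, val in (("density", rho), ("specific heat", c), ("conductivity", k)):
        if np.any(np.asarray(val) <= 0):
            raise ValueError(
                f"temperature-dependent {name} became nonpositive - check units/base values"
            )
    return rho, c, k


class BioheatSolver:
    """Implicit radial conduction solver with optional property feedback.

    far_boundary: 'fixed' clamps the outermost node at T_body (default);
    'insulated' applies a zero-flux outer face (used for energy-balance
    checks and closed-box configurations).
    """

    def __init__(
        self,
        grid: RadialGrid,
        props: ThermalProperties,
        temperature_dependent: bool = True,
        far_boundary: str = "fixed",
        T_body: float = T_BODY,
        perfusion_coefficient: float = 0.0,
    ) -> None:
        if far_boundary not in ("fixed", "insulated"):
            raise ValueError("far_boundary must be 'fixed' or 'insulated'")
        self.grid = grid
        self.props = props
        self.temperature_dependent = temperature_dependent
        self.far_boundary = far_boundary
        self.T_body = T_body
        self.perfusion_coefficient = perfusion_coefficient

    def properties_at(self, T: np.ndarray):
        if self.temperature_dependent:
            return temperature_dependent_properties(T, self.props)
        n = np.ones_like(T)
        return self.props.rho_t0 * n, self.props.c_t0 * n, self.props.k_t0 * n

    def step(self, state: TemperatureField, Q_ex, dt: float) -> TemperatureField:
        if dt <= 0:
            raise ValueError(f"time step must be positive, got {dt}")
        g = self.grid
        q = np.broadcast_to(np.asarray(Q_ex, dtype=float), (g.n,))
        if isinstance(Q_ex, np.ndarray) and Q_ex.shape != (g.n,):
            raise ValueError(f"Q_ex shape {Q_ex.shape} does not match grid ({g.n},)")
        rho, c, k = self.properties_at(state.T)
        k_face = np.empty(g.n + 1)
        k_face[1:-1] = 0.5 * (k[1:] + k[:-1])
        k_face[0], k_face[-1] = k[0], k[-1]
        L = self.grid.diffusion_matrix(k_face)
        rc = rho * c
        A = sp.identity(g.n, format="csr") - dt * sp.diags(1.0 / rc) @ L
        rhs = state.T + dt * (q + self.props.Q_m) / rc
        if self.perfusion_coefficient > 0:
            A += dt * self.perfusion_coefficient * sp.diags(1.0 / rc)
            rhs += dt * self.perfusion_coefficient * self.T_body / rc
        if self.far_boundary == "fixed":
            A = A.tolil()
            A[-1, :] = 0.0
            A[-1, -1] = 1.0
            A = A.tocsr()
            rhs[-1] = self.T_body
        T_new = spla.spsolve(A, rhs)
        if not np.all(np.isfinite(T_new)):
            raise RuntimeError("bio-heat solve did not converge to finite temperatures")
        return TemperatureField(T=T_new, t=state.t + dt)


def step_bhte(
    state: TemperatureField,
    Q_ex,
    props: ThermalProperties,
    dt: float,
    grid: RadialGrid,
    temperature_dependent: bool = False,
    far_boundary: str = "fixed",
    T_body: float = T_BODY,
) -> TemperatureField:
    """One implicit step of the bio-heat equation (functional convenience form)."""
    solver = BioheatSolver(
        grid, props, temperature_dependent=temperature_dependent,
        far_boundary=far_boundary, T_body=T_body,
    )
    return solver.step(state, Q_ex, dt)
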