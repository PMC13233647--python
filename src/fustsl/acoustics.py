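"""Frequency-domain acoustics: spherical incident wave, scattered-field
Helmholtz solve on the radial geometry, and acoustic power deposition.

The incident field of the effective point source is prescribed analytically;
the Helmholtz equation is solved only for the scattered correction caused by
tissue heterogeneity (scattered-field formulation).  On the reduced 1D
geometry the radial coordinate r (distance from the tumor center) is mapped
to the source-centered coordinate s = d - r, where d = |x0| is the on-axis
source distance, so the spherically spreading incident wave is an exact
solution of the discretized operator in homogeneous media.

Loss handling follows the printed lossless-wavenumber convention by default
(absorption enters only through the power deposition Q_ex); an optional
``lossy`` mode attenuates the beam along the in-tissue path with the complex
wavenumber kappa - i alpha_t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import RadialGrid

__all__ = [
    "AcousticSource",
    "AcousticMedium",
    "AcousticField",
    "wavenumber",
    "absorption_coefficient",
    "background_pressure",
    "solve_helmholtz",
    "power_deposition",
]

MIN_NODES_PER_WAVELENGTH = 8


@dataclass(frozen=True)
class AcousticSource:
    """Effective point source: amplitude p0 (Pa) at reference distance r_ref (m)."""

    p0: float
    f: float
    r_ref: float = 1.0
    x0: tuple[float, float, float] = (0.12, 0.12, 0.12)

    def __post_init__(self) -> None:
        if self.p0 <= 0 or self.r_ref <= 0 or self.f <= 0:
            raise ValueError("source amplitude, reference distance and frequency must be positive")

    @property
    def distance(self) -> float:
        """On-axis distance from the tumor center (origin) to the source."""
        return float(np.linalg.norm(self.x0))


@dataclass(frozen=True)
class AcousticMedium:
    """Homogeneous tissue baseline: density, sound speed, absorption power law."""

    rho_t0: float = 1050.0
    c0: float = 1540.0
    alpha0: float = 11.5  # Np/m at f0; ~1 dB/cm/MHz soft-tissue absorption
    f0: float = 1.0e6
    eta_star: float = 1.0

    def __post_init__(self) -> None:
        if min(self.rho_t0, self.c0, self.alpha0, self.f0) <= 0:
            raise ValueError("medium parameters must be positive")


@dataclass(frozen=True)
class AcousticField:
    """Complex pressure decomposition on a radial grid: p1 = pb + ps."""

    grid: RadialGrid
    p1: np.ndarray
    pb: np.ndarray
    ps: np.ndarray
    kappa: float
    alpha_t: float
    residual: float = field(default=0.0)


def wavenumber(f: float, c0: float) -> float:
    """Real (lossless) wavenumber 2 pi f / c0 (rad/m)."""
    if f <= 0 or c0 <= 0:
        raise ValueError(f"frequency and sound speed must be positive, got f={f}, c0={c0}")
    return 2.0 * np.pi * f / c0


def absorption_coefficient(f: float, medium: AcousticMedium) -> float:
    """Power-law absorption alpha_t = alpha0 (f/f0)^eta_star (Np/m)."""
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    return medium.alpha0 * (f / medium.f0) ** medium.eta_star


def background_pressure(source: AcousticSource, x, c0: float = 1540.0) -> complex:
    """Spherical-wave incident pressure p_b = p0 (r_ref/r_s) exp(-i k r_s) at point x."""
    x = np.asarray(x, dtype=float)
    r_s = float(np.linalg.norm(x - np.asarray(source.x0)))
    if r_s == 0.0:
        raise ValueError("background pressure is singular at the source location")
    k = wavenumber(source.f, c0)
    return source.p0 * (source.r_ref / r_s) * np.exp(-1j * k * r_s)


def _background_on_grid(
    grid: RadialGrid, source: AcousticSource, kappa: complex, entry_radius: float
) -> np.ndarray:
    """Incident wave along the radius; in lossy mode (complex kappa) the
    attenuation accrues only over the in-tissue path from the domain edge."""
    d = source.distance
    s = d - grid.r
    if np.any(s <= 0):
        raise ValueError("source must lie outside the radial domain")
    k_re = kappa.real
    amp = source.p0 * source.r_ref / s
    phase = np.exp(-1j * k_re * s)
    atten = np.exp(kappa.imag * (entry_radius - grid.r))  # kappa.imag <= 0
    return amp * phase * atten


def solve_helmholtz(
    grid: RadialGrid,
    source: AcousticSource,
    medium: AcousticMedium,
    rho: np.ndarray | None = None,
    c: np.ndarray | None = None,
    lossy: bool = False,
) -> AcousticField:
    """Total complex pressure on the radial grid via a scattered-field solve.

    ``rho`` and ``c`` may be per-node arrays to describe tumor/host contrast;
    by default the medium is homogeneous and the returned scattered component
    is (discretization-level) zero.  The far ends of the slab carry
    first-order radiation conditions for the scattered wave.
    """
    n = grid.n
    rho_a = np.broadcast_to(np.asarray(rho if rho is not None else medium.rho_t0, float), (n,))
    c_a = np.broadcast_to(np.asarray(c if c is not None else medium.c0, float), (n,))
    omega = 2.0 * np.pi * source.f
    c_min = float(c_a.min())
    nodes_per_wavelength = (c_min / source.f) / grid.dr
    if nodes_per_wavelength < MIN_NODES_PER_WAVELENGTH:
        needed = int(np.ceil(grid.radius / (c_min / source.f / MIN_NODES_PER_WAVELENGTH))) + 1
        raise ValueError(
            f"grid under-resolves the wavelength ({nodes_per_wavelength:.1f} nodes/wavelength,"
            f" minimum {MIN_NODES_PER_WAVELENGTH}); use at least {needed} nodes"
        )

    alpha_t = absorption_coefficient(source.f, medium)
    kappa0 = wavenumber(source.f, medium.c0)
    kappa_c = kappa0 - 1j * alpha_t if lossy else complex(kappa0)
    pb = _background_on_grid(grid, source, kappa_c, grid.radius)

    # conservative operator in s = d - r with 1/rho face weights
    d = source.distance
    s_face = d - grid.faces
    rho_face = np.empty(n + 1)
    rho_face[1:-1] = 0.5 * (rho_a[1:] + rho_a[:-1])
    rho_face[0], rho_face[-1] = rho_a[0], rho_a[-1]
    h = grid.dr
    s_node = d - grid.r
    g = s_face[1:-1] ** 2 / rho_face[1:-1] / h**2  # interior faces
    inv_s2 = 1.0 / s_node**2

    main = np.zeros(n, dtype=complex)
    lower = np.zeros(n - 1, dtype=complex)
    upper = np.zeros(n - 1, dtype=complex)
    main[:-1] -= g * inv_s2[:-1]
    upper[:] = g * inv_s2[:-1]
    main[1:] -= g * inv_s2[1:]
    lower[:] = g * inv_s2[1:]
    k_node = omega / c_a - (1j * alpha_t if lossy else 0.0)
    main += k_node**2 / rho_a
    A = sp.lil_matrix(sp.diags([lower, main, upper], [-1, 0, 1], format="csr"))

    rhs = -(A @ pb)

    # radiation rows for the scattered wave: outgoing at both slab ends
    k0 = k_node[0].real
    kn = k_node[-1].real
    A[0, :] = 0.0
    A[0, 0] = -1.0 / h - 1j * k0
    A[0, 1] = 1.0 / h
    rhs[0] = 0.0
    A[n - 1, :] = 0.0
    A[n - 1, n - 1] = 1.0 / h + 1j * kn
    A[n - 1, n - 2] = -1.0 / h
    rhs[n - 1] = 0.0

    A = A.tocsr()
    ps = spla.spsolve(A, rhs)
    p1 = pb + ps
    resid = float(np.linalg.norm(A @ ps - rhs) / max(np.linalg.norm(p1), 1e-300))
    return AcousticField(
        grid=grid, p1=p1, pb=pb, ps=ps, kappa=kappa0, alpha_t=alpha_t, residual=resid
    )


def power_deposition(
    field_or_p1,
    medium: AcousticMedium,
    alpha_t: float | np.ndarray | None = None,
) -> np.ndarray:
    """Volumetric heat source Q_ex = alpha_t |p1|^2 / (rho c) (W/m^3)."""
    p1 = field_or_p1.p1 if isinstance(field_or_p1, AcousticField) else np.asarray(field_or_p1)
    if alpha_t is None:
        if not isinstance(field_or_p1, AcousticField):
            raise ValueError("alpha_t must be given when passing a raw pressure array")
        alpha_t = field_or_p1.alpha_t
    alpha_arr = np.asarray(alpha_t, dtype=float)
    if alpha_arr.ndim and alpha_arr.shape != p1.shape:
        raise ValueError(f"alpha_t shape {alpha_arr.shape} does not match field {p1.shape}")
    return alpha_arr * np.abs(p1) ** 2 / (medium.rho_t0 * medium.c0)


def acoustic_intensity(p1: np.ndarray, medium: AcousticMedium) -> np.ndarray:
    """Time-averaged intensity I = |p1|^2 / (2 rho c) (W/m^2)."""
    return np.abs(p1) ** 2 / (2.0 * medium.rho_t0 * medium.c0)
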