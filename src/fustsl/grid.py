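"""Uniform radial (spherically symmetric) finite-volume grid.

All spatial solvers in this package operate on a 1D radial reduction of the
spherical tumor-in-host geometry: node i sits at radius ``r[i]``, cell i is the
spherical shell between the half-radii ``r[i] -/+ dr/2`` (clamped to the domain).
The conservative divergence operator built here makes mass/energy bookkeeping
exact at the discrete level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


@dataclass(frozen=True)
class RadialGrid:
    """Uniform node spacing on [0, R]; node 0 at the center."""

    r: np.ndarray
    _faces: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 1 or r.size < 3:
            raise ValueError("radial grid needs at least 3 nodes")
        if r[0] != 0.0:
            raise ValueError("radial grid must start at r=0")
        dr = np.diff(r)
        if not np.allclose(dr, dr[0]):
            raise ValueError("radial grid must be uniform")
        object.__setattr__(self, "r", r)
        faces = np.concatenate(([0.0], 0.5 * (r[1:] + r[:-1]), [r[-1]]))
        object.__setattr__(self, "_faces", faces)

    @classmethod
    def uniform(cls, radius: float, n: int) -> "RadialGrid":
        if radius <= 0:
            raise ValueError(f"domain radius must be positive, got {radius}")
        return cls(np.linspace(0.0, radius, n))

    @property
    def n(self) -> int:
        return self.r.size

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def radius(self) -> float:
        return float(self.r[-1])

    @property
    def faces(self) -> np.ndarray:
        """Cell interface radii, shape (n+1,); faces[0]=0, faces[-1]=R."""
        return self._faces

    @property
    def face_areas(self) -> np.ndarray:
        return 4.0 * np.pi * self._faces**2

    @property
    def cell_volumes(self) -> np.ndarray:
        f = self._faces
        return 4.0 * np.pi / 3.0 * (f[1:] ** 3 - f[:-1] ** 3)

    def volume_average(self, values: np.ndarray, within: float | None = None) -> float:
        """Volume-weighted average of a nodal field, optionally over r <= within."""
        v = self.cell_volumes
        if within is not None:
            mask = self.r <= within + 1e-12
            return float(np.sum(values[mask] * v[mask]) / np.sum(v[mask]))
        return float(np.sum(values * v) / np.sum(v))

    def diffusion_matrix(self, coef_face: np.ndarray | float) -> sp.csr_matrix:
        """Conservative FV operator L with (L u)_i ~ (1/r^2) d/dr(coef r^2 du/dr).

        ``coef_face`` is the transport coefficient at the n+1 cell faces (a
        scalar is broadcast).  Zero-flux is imposed at the center face (exact,
        by symmetry) and at the outer face; Dirichlet conditions are applied by
        overwriting boundary rows in the calling solver.
        """
        n = self.n
        coef = np.broadcast_to(np.asarray(coef_face, dtype=float), (n + 1,)).copy()
        area = self.face_areas
        vol = self.cell_volumes
        dr = self.dr
        # conductance through interior faces 1..n-1
        g = area[1:-1] * coef[1:-1] / dr  # shape (n-1,)
        main = np.zeros(n)
        lower = np.zeros(n - 1)
        upper = np.zeros(n - 1)
        main[:-1] -= g / vol[:-1]
        upper[:] = g / vol[:-1]
        main[1:] -= g / vol[1:]
        lower[:] = g / vol[1:]
        return sp.diags([lower, main, upper], [-1, 0, 1], format="csr")

    def advection_matrix(self, v_face: np.ndarray) -> sp.csr_matrix:
        """Upwind FV operator A with (A c)_i ~ -(1/r^2) d/dr(r^2 v c).

        ``v_face`` is the radial velocity at the n+1 faces (positive =
        outward).  Upwinding selects the donor cell by the sign of the face
        velocity, which keeps the scheme positivity-preserving.
        """
        n = self.n
        v = np.broadcast_to(np.asarray(v_face, dtype=float), (n + 1,))
        area = self.face_areas
        vol = self.cell_volumes
        rows, cols, vals = [], [], []
        for j in range(1, n):  # interior faces; boundary faces carry no flux here
            flux = area[j] * v[j]
            donor = j - 1 if v[j] >= 0 else j
            # outflow from cell j-1 side / inflow to cell j side
            rows.append(j - 1)
            cols.append(donor)
            vals.append(-flux / vol[j - 1])
            rows.append(j)
            cols.append(donor)
            vals.append(flux / vol[j])
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
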