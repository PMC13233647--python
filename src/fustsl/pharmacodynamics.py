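"""Surrogate pharmacodynamics: internalized drug -> cancer-cell survival ->
tumor volume, plus the proliferation-rate calibration and the total-variance
sensitivity statistic.

The multi-population balance of the full tissue model is replaced by a
single-compartment logistic law modulated by the survival fraction S_f:

    dV/dt = k1 V (1 - V/V_K) S_f  -  k1 V (1 - S_f)

so survivors proliferate logistically and non-survivors are removed at the
proliferative tempo; untreated dynamics (S_f = 1) reduce to plain logistic
growth.  All tumor-volume outputs of this module are surrogate-PD results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ResponseParams",
    "TrajectorySet",
    "survival_fraction",
    "step_tumor_volume",
    "logistic_volume",
    "calibrate_k1",
    "total_variance",
]


@dataclass(frozen=True)
class ResponseParams:
    k1: float = 0.51  # proliferation rate constant, 1/day
    V0: float = 1.5  # initial tumor volume, mm^3
    V_K: float = 2000.0  # carrying capacity, mm^3
    kill_law: str = "exponential"
    kill_params: dict = field(default_factory=lambda: {"kappa_kill": 1.0})

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ValueError(f"proliferation rate must be positive, got {self.k1}")
        if not 0 < self.V0 < self.V_K:
            raise ValueError("initial volume must satisfy 0 < V0 < V_K")
        if self.kill_law not in ("exponential", "hill"):
            raise ValueError(f"unknown kill law {self.kill_law!r}; use 'exponential' or 'hill'")


def survival_fraction(c_int, params: ResponseParams):
    """Surviving cancer-cell fraction S_f(c_int) in (0, 1], S_f(0) = 1.

    'exponential': S_f = exp(-kappa_kill c_int)  (default surrogate)
    'hill':        S_f = 1 / (1 + (c_int/ec50)^n_hill)
    """
    c = np.asarray(c_int, dtype=float)
    if np.any(c < 0):
        raise ValueError("internalized drug concentration must be nonnegative")
    kp = params.kill_params
    if params.kill_law == "exponential":
        out = np.exp(-kp.get("kappa_kill", 1.0) * c)
    else:
        ec50 = kp.get("ec50", 1.0)
        n = kp.get("n_hill", 1.0)
        out = 1.0 / (1.0 + (c / ec50) ** n)
    return float(out) if np.ndim(c_int) == 0 else out


def _dVdt(V: float, s_f: float, params: ResponseParams) -> float:
    return params.k1 * V * (1.0 - V / params.V_K) * s_f - params.k1 * V * (1.0 - s_f)


def step_tumor_volume(V: float, S_f: float, params: ResponseParams, dt: float) -> float:
    """Advance the tumor volume one step (RK4; dt in days)."""
    if V <= 0:
        raise ValueError(f"tumor volume must be positive, got {V}")
    k1 = _dVdt(V, S_f, params)
    k2 = _dVdt(V + 0.5 * dt * k1, S_f, params)
    k3 = _dVdt(V + 0.5 * dt * k2, S_f, params)
    k4 = _dVdt(V + dt * k3, S_f, params)
    return max(V + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 1e-9)


def logistic_volume(t, k1: float, V0: float, V_K: float):
    """Closed-form logistic growth V(t) = V_K / (1 + (V_K/V0 - 1) e^{-k1 t})."""
    t = np.asarray(t, dtype=float)
    return V_K / (1.0 + (V_K / V0 - 1.0) * np.exp(-k1 * t))


def calibrate_k1(
    observed_days: np.ndarray,
    observed_volumes: np.ndarray,
    params: ResponseParams,
    bounds: tuple[float, float] = (1e-6, 5.0),
) -> float:
    """Fit the proliferation constant to an untreated growth series.

    Least-squares on the closed-form logistic solution anchored at the first
    observation; bounded scalar optimization, deterministic for fixed inputs.
    """
    t = np.asarray(observed_days, dtype=float)
    v = np.asarray(observed_volumes, dtype=float)
    if t.size < 3:
        raise ValueError("calibration needs at least 3 observations")
    if np.any(v <= 0):
        raise ValueError("observed volumes must be positive")
    t0, v0 = t[0], v[0]

    def sse(k1: float) -> float:
        model = logistic_volume(t - t0, k1, v0, params.V_K)
        return float(np.sum((model - v) ** 2))

    res = minimize_scalar(sse, bounds=bounds, method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(
            f"k1 calibration failed to converge in bracket {bounds}: {res.message}"
        )
    return float(res.x)


@dataclass(frozen=True)
class TrajectorySet:
    """Tumor-volume trajectories of the levels of one swept parameter."""

    times: np.ndarray  # days, common grid
    volumes: np.ndarray  # (n_levels, n_times), mm^3
    labels: tuple = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.atleast_2d(np.asarray(self.volumes, dtype=float))
        if v.shape[0] < 2:
            raise ValueError("variance needs at least 2 trajectories")
        if v.shape[1] != t.size:
            raise ValueError(
                f"trajectory grid mismatch: {v.shape[1]} samples vs {t.size} times"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)


def total_variance(
    tset: TrajectorySet, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Time-averaged total variance across parameter levels.

    Tot.Var = sum_i (1/T) int_window (V_i(t) - Vbar(t))^2 dt with Vbar the
    cross-level mean, trapezoidal quadrature.  Returns (tot_var, log10);
    identical trajectories give (0.0, -inf).
    """
    t = tset.times
    v = tset.volumes
    if window is not None:
        lo, hi = window
        m = (t >= lo) & (t <= hi)
        if m.sum() < 2:
            raise ValueError(f"integration window {window} contains fewer than 2 samples")
        t, v = t[m], v[:, m]
    span = t[-1] - t[0]
    vbar = v.mean(axis=0)
    dev2 = (v - vbar) ** 2
    tot = float(np.sum(np.trapezoid(dev2, t, axis=1)) / span)
    # identical levels leave only roundoff residue; snap it to the sentinel
    if tot <= 1e-24 * max(float(np.max(v**2)), 1.0):
        tot = 0.0
    log10 = np.log10(tot) if tot > 0 else float("-inf")
    return tot, float(log10)
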