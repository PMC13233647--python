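"""Temperature-triggered drug release kinetics of thermosensitive liposomes.

The release rate constant follows an empirical exponential fit to in vitro
release data, k_rel(T) = A exp(B T) with T in Kelvin, valid over the mild
hyperthermia window 37-42 degC.  Outside the fitted range the rate is clamped
to the boundary value: the steep exponential (B ~ 0.52 1/K) would otherwise
extrapolate nonphysically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import CELSIUS_OFFSET

__all__ = ["ReleaseModel", "release_rate", "formulation_library", "FORMULATION_LABELS"]

#: Ordering (fastest first) every valid library must respect at any temperature.
FORMULATION_LABELS = ("ultra-fast", "fast", "intermediate", "slow")


@dataclass(frozen=True)
class ReleaseModel:
    """k_rel(T) = A exp(B T), clamped to [T_lo, T_hi]."""

    A: float
    B: float
    T_lo: float = 37.0 + CELSIUS_OFFSET
    T_hi: float = 42.0 + CELSIUS_OFFSET
    label: str = "fast"

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("release fit constants A, B must be positive")
        if self.T_lo >= self.T_hi:
            raise ValueError("validity range must satisfy T_lo < T_hi")

    def scaled(self, multiplier: float, label: str | None = None) -> "ReleaseModel":
        """A surrogate formulation: the same exponential scaled by a constant."""
        return replace(self, A=self.A * multiplier, label=label or self.label)


#: Fitted fast-release formulation (baseline formulation of the simulator).
FAST_RELEASE = ReleaseModel(A=4.0e-73, B=0.5204, label="fast")

# Surrogate multipliers for the unfitted formulations.  They span the
# slow-to-ultra-fast spread used in the release-rate sensitivity levels
# (x0.1 ... x6 of the fast fit) and preserve the required speed ordering.
_SURROGATE_MULTIPLIERS = {"ultra-fast": 6.0, "intermediate": 0.3, "slow": 0.1}


def release_rate(T, model: ReleaseModel = FAST_RELEASE):
    """Release rate constant (1/s) at absolute temperature T (K), clamped.

    Accepts scalars or arrays.  Strictly increasing on [T_lo, T_hi] and
    continuous across the clamp boundaries.
    """
    t = np.clip(np.asarray(T, dtype=float), model.T_lo, model.T_hi)
    out = model.A * np.exp(model.B * t)
    return float(out) if np.isscalar(T) or np.ndim(T) == 0 else out


def formulation_library(label: str) -> ReleaseModel:
    """Look up a release formulation by name.

    'fast' is the fitted baseline; 'ultra-fast', 'intermediate' and 'slow' are
    surrogate rescalings of the fast fit (clearly flagged as such) until
    formulation-specific fit constants are supplied via configuration.
    """
    if label == "fast":
        return FAST_RELEASE
    if label in _SURROGATE_MULTIPLIERS:
        return FAST_RELEASE.scaled(_SURROGATE_MULTIPLIERS[label], label=label)
    raise KeyError(
        f"unknown formulation {label!r}; available: {', '.join(FORMULATION_LABELS)}"
    )


def release_table(T_celsius: np.ndarray):
    """CSV-ready table of k_rel per formulation over a temperature grid (degC)."""
    import pandas as pd

    t_k = np.asarray(T_celsius, dtype=float) + CELSIUS_OFFSET
    data = {"T_celsius": np.asarray(T_celsius, dtype=float)}
    for label in FORMULATION_LABELS:
        data[label] = release_rate(t_k, formulation_library(label))
    return pd.DataFrame(data)
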