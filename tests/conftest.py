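"""Shared fixtures.

The scenario-level fixtures are session-scoped: the coupled runs cost seconds
each and several test modules interrogate the same trajectories.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fustsl
from fustsl.scenarios import set_param

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

HOUR = 3600.0


@pytest.fixture(scope="session")
def jc_scenario():
    return fustsl.preset("jc_dromi")


@pytest.fixture(scope="session")
def jc_arms(jc_scenario):
    """All four treatment arms of the JC replication scenario."""
    return fustsl.run_arms(jc_scenario)


@pytest.fixture(scope="session")
def persistence_runs(jc_scenario):
    """Combination arm with the transport enhancement persisting 2/6/12/24 h."""
    out = {}
    for hours in (2, 6, 12, 24):
        scn = set_param(
            jc_scenario, "protocol.fus_modulation.persistence", hours * HOUR
        )
        out[hours] = fustsl.run_scenario(scn)
    return out


@pytest.fixture(scope="session")
def magnitude_runs(jc_scenario):
    """Combination arm with the enhancement multipliers scaled -50%..+50%."""
    out = {}
    for scale in (0.5, 0.75, 1.0, 1.25, 1.5):
        scn = set_param(jc_scenario, "protocol.fus_modulation.a_p_kth", 5.0 * scale)
        scn = set_param(scn, "protocol.fus_modulation.a_p_gamma", 1.5 * scale)
        out[scale] = fustsl.run_scenario(scn)
    return out


@pytest.fixture(scope="session")
def formulation_runs(jc_scenario):
    """Combination arm across the four release formulations."""
    out = {}
    for label in ("ultra-fast", "fast", "intermediate", "slow"):
        scn = fustsl.set_param(jc_scenario, "release", fustsl.formulation_library(label))
        out[label] = fustsl.run_scenario(scn)
    return out


@pytest.fixture(scope="session")
def tsl_reference(jc_scenario):
    return fustsl.run_scenario(jc_scenario, arm="tsl")


def tsl_drug_at(result, t_s: float) -> float:
    """Intratumoral drug of a TSL-only run interpolated to a matched time."""
    ds = result.drug_series
    return float(np.interp(t_s, ds["t_s"], ds["intratumoral"]))
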