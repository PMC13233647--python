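"""Protocol scheduling and multirate orchestration of the coupled solvers.

A scenario bundles geometry, tissue, particle, vessel-wall, kinetic, release
and response parameters with a treatment protocol.  ``run_scenario`` advances
three clocks:

* a day-scale outer clock (default 0.25 d) for tumor volume,
* a minute-scale drug clock from injection until the drug has cleared,
* a 9-s fine clock during sonication, when the acoustic field (solved once
  per exposure window, the source being stationary) drives the bio-heat
  equation and temperature-triggered release.

The post-sonication transport enhancement (x5 interstitial hydraulic
conductivity, x1.5 wall porosity) is applied as a step window and the IFP
field is re-solved quasi-statically at each parameter change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from itertools import product
from typing import Iterable

import numpy as np
import pandas as pd

from .acoustics import AcousticMedium, AcousticSource, power_deposition, solve_helmholtz
from .bioheat import BioheatSolver, TemperatureField, ThermalProperties
from .constants import SECONDS_PER_DAY, SECONDS_PER_HOUR, T_BODY
from .fluids import FluidParams, FUSModulation, solve_ifp
from .grid import RadialGrid
from .hindered import ParticleSpec, SeriesAccuracyWarning, VesselWall, wall_transport
from .pharmacodynamics import (
    ResponseParams,
    TrajectorySet,
    logistic_volume,
    step_tumor_volume,
    survival_fraction,
    total_variance,
)
from .release import ReleaseModel, formulation_library
from .transport import BindingKinetics, DrugState, DrugTransportSolver, intratumoral_drug

__all__ = [
    "Protocol",
    "Numerics",
    "Scenario",
    "SimulationResult",
    "run_scenario",
    "run_arms",
    "preset",
    "sweep",
    "sensitivity_report",
    "generate_fixture",
    "set_param",
    "particle_variant",
    "calibrate_source_pressure",
    "DEFAULT_SENSITIVITY_LEVELS",
    "ARMS",
]

ARMS = ("control", "fus", "tsl", "fus+tsl")

#: Baseline particle radius against which payload/diffusivity scalings are taken.
_R_S_BASELINE = 50e-9


@dataclass(frozen=True)
class Protocol:
    """Treatment schedule.  Times are seconds on the simulation clock."""

    injection_time: float = 10.0 * SECONDS_PER_DAY
    lag_to_fus: float = 0.0
    t_exp: float = 15.0 * 60.0
    f: float = 1.0e6
    source: AcousticSource = field(
        default_factory=lambda: AcousticSource(p0=5.9e3, f=1.0e6)
    )
    fus_modulation: FUSModulation = field(default_factory=FUSModulation)
    treatment_offset_days: float = 0.0

    def __post_init__(self) -> None:
        if self.t_exp < 0:
            raise ValueError("exposure duration must be nonnegative")
        if self.f <= 0:
            raise ValueError("frequency must be positive")

    @property
    def t_inject(self) -> float:
        return self.injection_time + self.treatment_offset_days * SECONDS_PER_DAY

    @property
    def t_fus(self) -> float:
        return self.t_inject + self.lag_to_fus


@dataclass(frozen=True)
class Numerics:
    """Discretization and clock settings (problem sizes, not physics)."""

    R_thermal: float = 0.04  # m, thermal domain radius (fixed body far boundary)
    n_thermal: int = 161
    R_acoustic: float = 0.01  # m, heated/insonated tissue slab radius
    nodes_per_wavelength: int = 96
    drug_domain_factor: float = 2.5  # drug domain radius / tumor radius
    n_drug: int = 81
    dt_fine: float = 9.0  # s, sonication clock
    dt_cool: float = 30.0  # s, post-sonication cooling clock
    dt_lag: float = 60.0  # s, injection-to-sonication clock
    dt_drug: float = 600.0  # s, drug clock outside treatment windows
    cooling_duration: float = 1800.0  # s
    drug_horizon: float = 2.0 * SECONDS_PER_DAY  # drug integration past injection
    dt_day: float = 0.25  # d, outer tumor-volume clock
    t_end_day: float = 20.0
    lossy_beam: bool = True  # attenuate p1 along the in-tissue path
    temperature_dependent_properties: bool = True


@dataclass(frozen=True)
class Scenario:
    medium: AcousticMedium = field(default_factory=AcousticMedium)
    thermal: ThermalProperties = field(default_factory=ThermalProperties)
    fluid: FluidParams = field(default_factory=FluidParams)
    particle: ParticleSpec = field(default_factory=lambda: ParticleSpec(r_s=50e-9))
    wall: VesselWall = field(default_factory=lambda: VesselWall(r_0=100e-9))
    kinetics: BindingKinetics = field(default_factory=BindingKinetics)
    release: ReleaseModel = field(default_factory=lambda: formulation_library("fast"))
    response: ResponseParams = field(default_factory=ResponseParams)
    protocol: Protocol = field(default_factory=Protocol)
    numerics: Numerics = field(default_factory=Numerics)
    seed: int = 0
    name: str = "default"

    def to_dict(self) -> dict:
        """Flat provenance manifest of every resolved parameter."""

        def conv(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {f.name: conv(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)


@dataclass
class SimulationResult:
    arm: str
    times_day: np.ndarray
    volumes: np.ndarray
    final_volume: float
    time_to_500_day: float | None
    peak_temperature: float  # K, maximum over space and time
    temperature_series: dict  # t_s, peak_T, mean_tumor_T, rim_T
    drug_series: dict  # t_s, intratumoral, c_int_avg, c_l_avg
    intratumoral_end_exposure: float | None
    events: list
    manifest: dict

    @property
    def peak_temperature_celsius(self) -> float:
        return self.peak_temperature - 273.15


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def volume_to_radius(V_mm3: float) -> float:
    """Tumor radius (m) of a sphere of volume V (mm^3)."""
    return (3.0 * V_mm3 * 1e-9 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _time_to_threshold(times_day, volumes, threshold=500.0):
    v = np.asarray(volumes)
    above = np.nonzero(v >= threshold)[0]
    if above.size == 0:
        return None
    i = above[0]
    if i == 0:
        return float(times_day[0])
    t0, t1 = times_day[i - 1], times_day[i]
    v0, v1 = v[i - 1], v[i]
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))


def _acoustic_grid(scn: Scenario) -> RadialGrid:
    lam = scn.medium.c0 / scn.protocol.f
    dr = lam / scn.numerics.nodes_per_wavelength
    n = max(int(np.ceil(scn.numerics.R_acoustic / dr)) + 1, 64)
    return RadialGrid.uniform(scn.numerics.R_acoustic, n)


# --------------------------------------------------------------------------
# the orchestrator
# --------------------------------------------------------------------------

def run_scenario(scn: Scenario, arm: str = "fus+tsl") -> SimulationResult:
    """Simulate one treatment arm end to end.

    Arms: 'control' (no treatment), 'fus' (sonication only), 'tsl'
    (liposomes only), 'fus+tsl' (the combination).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; choose one of {ARMS}")
    with_fus = arm in ("fus", "fus+tsl")
    with_tsl = arm in ("tsl", "fus+tsl")
    num = scn.numerics
    events: list[tuple[float, str]] = []

    prot = scn.protocol
    t_inject = prot.t_inject
    t_fus = prot.t_fus
    mod = replace(prot.fus_modulation, t_FUS=t_fus)

    # tumor geometry frozen at the treatment-time volume (quasi-static)
    v_treat = float(
        logistic_volume(
            t_inject / SECONDS_PER_DAY, scn.response.k1, scn.response.V0, scn.response.V_K
        )
    )
    r_tumor = volume_to_radius(v_treat)
    fluid = replace(scn.fluid, R_tumor=r_tumor)

    temp_series = {"t_s": [], "peak_T": [], "mean_tumor_T": [], "rim_T": []}
    drug_series = {"t_s": [], "intratumoral": [], "c_int_avg": [], "c_l_avg": []}
    peak_temperature = T_BODY
    intratumoral_end_exposure = None

    if with_fus or with_tsl:
        thermal_grid = RadialGrid.uniform(num.R_thermal, num.n_thermal)
        drug_grid = RadialGrid.uniform(
            max(num.drug_domain_factor * r_tumor, 1.5 * r_tumor), num.n_drug
        )
        particle = replace(scn.particle, t0=t_inject)  # bolus on the protocol clock
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeriesAccuracyWarning)
            hindrance = wall_transport(scn.wall, particle)
        fluid = replace(fluid, Lp=hindrance.Lp)

        heat_solver = BioheatSolver(
            thermal_grid,
            scn.thermal,
            temperature_dependent=num.temperature_dependent_properties,
        )
        solver = DrugTransportSolver(
            drug_grid, particle, scn.wall, hindrance, scn.kinetics,
            scn.release, R_tumor=r_tumor,
        )

        def ifp(kth_mult: float, gamma_mult: float):
            f_mod = replace(
                fluid, k_th=fluid.k_th * kth_mult, Lp=fluid.Lp * gamma_mult
            )
            return solve_ifp(f_mod, drug_grid)

        p_base, v_base = ifp(1.0, 1.0)
        events.append((t_inject, "ifp_solve_baseline"))
        p_mod, v_mod = (
            ifp(mod.a_p_kth, mod.a_p_gamma) if with_fus else (p_base, v_base)
        )

        # acoustic field: one frequency-domain solve per exposure window
        q_drug_mask = None
        if with_fus and prot.t_exp > 0:
            ac_grid = _acoustic_grid(scn)
            source = replace(prot.source, f=prot.f)
            field_ac = solve_helmholtz(ac_grid, source, scn.medium, lossy=num.lossy_beam)
            q_ac = power_deposition(field_ac, scn.medium)
            q_thermal = np.interp(thermal_grid.r, ac_grid.r, q_ac, right=0.0)
            events.append((t_fus, "acoustic_solve"))
        else:
            q_thermal = np.zeros(num.n_thermal)

        T_state = TemperatureField(T=np.full(num.n_thermal, T_BODY), t=t_inject)
        drug = DrugState.zeros(drug_grid, t=t_inject) if with_tsl else None

        def record_temp(state: TemperatureField):
            nonlocal peak_temperature
            tumor_mask = thermal_grid.r <= r_tumor + 1e-12
            peak = float(state.T.max())
            peak_temperature = max(peak_temperature, peak)
            temp_series["t_s"].append(state.t)
            temp_series["peak_T"].append(peak)
            temp_series["mean_tumor_T"].append(
                thermal_grid.volume_average(state.T, within=r_tumor)
            )
            temp_series["rim_T"].append(float(np.interp(r_tumor, thermal_grid.r, state.T)))

        def record_drug(state: DrugState):
            drug_series["t_s"].append(state.t)
            drug_series["intratumoral"].append(
                intratumoral_drug(state, drug_grid, r_tumor)
            )
            drug_series["c_int_avg"].append(
                drug_grid.volume_average(state.c_int, within=r_tumor)
            )
            drug_series["c_l_avg"].append(
                drug_grid.volume_average(state.c_l, within=r_tumor)
            )

        def advance_drug(t_end: float, dt: float, T_nodes, p, v, gamma_mult):
            nonlocal drug
            if drug is None:
                return
            while drug.t < t_end - 1e-9:
                step = min(dt, t_end - drug.t)
                drug = solver.step(drug, T_nodes, p, v, step, gamma_multiplier=gamma_mult)
                record_drug(drug)

        def drug_T(temp_state: TemperatureField):
            return np.interp(drug_grid.r, thermal_grid.r, temp_state.T)

        if with_tsl:
            events.append((t_inject, "injection"))
            record_drug(drug)
        record_temp(T_state)

        t_exp_end = t_fus + prot.t_exp
        t_cool_end = t_exp_end + num.cooling_duration
        t_horizon = t_inject + num.drug_horizon
        t_mod_end = t_fus + mod.persistence

        # --- lag: injection -> sonication (baseline transport, body temp)
        if with_fus and t_fus > t_inject:
            events.append((t_inject, "clock_lag"))
            advance_drug(t_fus, num.dt_lag, T_BODY, p_base, v_base, 1.0)
            T_state = TemperatureField(T=T_state.T, t=t_fus)

        if with_fus and prot.t_exp > 0:
            # --- sonication window: fine clock, modulated transport
            events.append((t_fus, "fus_on"))
            events.append((t_fus, "modulation_on"))
            events.append((t_fus, "ifp_solve_modulated"))
            events.append((t_fus, "clock_fine"))
            while T_state.t < t_exp_end - 1e-9:
                step = min(num.dt_fine, t_exp_end - T_state.t)
                T_state = heat_solver.step(T_state, q_thermal, step)
                record_temp(T_state)
                if drug is not None:
                    drug = solver.step(
                        drug, drug_T(T_state), p_mod, v_mod, step,
                        gamma_multiplier=mod.a_p_gamma,
                    )
                    record_drug(drug)
            if drug is not None and with_tsl:
                intratumoral_end_exposure = drug_series["intratumoral"][-1]
            events.append((t_exp_end, "fus_off"))

            # --- cooling: sonication off, modulation persists
            events.append((t_exp_end, "clock_cooling"))
            while T_state.t < t_cool_end - 1e-9:
                step = min(num.dt_cool, t_cool_end - T_state.t)
                T_state = heat_solver.step(T_state, 0.0, step)
                record_temp(T_state)
                if drug is not None:
                    drug = solver.step(
                        drug, drug_T(T_state), p_mod, v_mod, step,
                        gamma_multiplier=mod.a_p_gamma,
                    )
                    record_drug(drug)

            # --- post-treatment: body temperature, day-scale drug clock
            events.append((t_cool_end, "clock_post"))
            t_mod_stop = min(t_mod_end, t_horizon)
            if t_mod_stop > t_cool_end:
                advance_drug(
                    t_mod_stop, num.dt_drug, T_BODY, p_mod, v_mod, mod.a_p_gamma
                )
            if t_mod_end < t_horizon:
                events.append((t_mod_end, "modulation_revert"))
                events.append((t_mod_end, "ifp_solve_baseline_revert"))
                advance_drug(t_horizon, num.dt_drug, T_BODY, p_base, v_base, 1.0)
        else:
            # no sonication in this arm: baseline transport to the horizon
            advance_drug(t_horizon, num.dt_drug, T_BODY, p_base, v_base, 1.0)

    # ------------------------------------------------------------------
    # day-scale tumor response (surrogate PD)
    # ------------------------------------------------------------------
    if drug_series["t_s"]:
        cint_t = np.asarray(drug_series["t_s"]) / SECONDS_PER_DAY
        cint_v = np.asarray(drug_series["c_int_avg"])
    else:
        cint_t = cint_v = None

    def c_int_at(day: float) -> float:
        if cint_t is None:
            return 0.0
        if day <= cint_t[0]:
            return 0.0
        if day >= cint_t[-1]:
            return float(cint_v[-1])
        return float(np.interp(day, cint_t, cint_v))

    n_outer = int(round(num.t_end_day / num.dt_day))
    times_day = np.linspace(0.0, num.t_end_day, n_outer + 1)
    volumes = np.empty(n_outer + 1)
    volumes[0] = scn.response.V0
    for i in range(n_outer):
        s_f = survival_fraction(c_int_at(times_day[i]), scn.response)
        volumes[i + 1] = step_tumor_volume(volumes[i], s_f, scn.response, num.dt_day)

    events.sort(key=lambda e: e[0])
    return SimulationResult(
        arm=arm,
        times_day=times_day,
        volumes=volumes,
        final_volume=float(volumes[-1]),
        time_to_500_day=_time_to_threshold(times_day, volumes),
        peak_temperature=peak_temperature,
        temperature_series={k: np.asarray(v) for k, v in temp_series.items()},
        drug_series={k: np.asarray(v) for k, v in drug_series.items()},
        intratumoral_end_exposure=intratumoral_end_exposure,
        events=events,
        manifest={"scenario": scn.to_dict(), "arm": arm, "seed": scn.seed},
    )


def run_arms(scn: Scenario, arms: Iterable[str] = ARMS) -> dict[str, SimulationResult]:
    return {arm: run_scenario(scn, arm) for arm in arms}


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def _v0_for_treatment_volume(v_treat: float, k1: float, v_k: float, day: float) -> float:
    """Initial volume so that untreated logistic growth reaches v_treat at `day`."""
    g = np.exp(k1 * day)
    return v_k / (1.0 + (v_k / v_treat - 1.0) * g)

# Source amplitudes produced by calibrate_source_pressure on each preset
# (the protocol prescribes calibrating the source strength to the target
# hyperthermia temperature; values frozen here for reproducibility).
_JC_P0 = 1.2483e4     # Pa at 1 m; peak ~41.2 degC for 1 MHz / 30 min
_CWR22_P0 = 1.0912e5  # Pa at 1 m; ~42 degC after the 4-min 40-kHz exposure

# Surrogate-PD kill constant, anchored once so the JC combination arm lands on
# the reported final-volume scale; held fixed across arms and sweeps.
_JC_KAPPA_KILL = 8.6e-5


def preset(name: str) -> Scenario:
    """Built-in replication scenarios.

    'jc_dromi': murine mammary JC adenocarcinoma protocol - 1 MHz pulsed FUS
    for 15 min (configurable 15-30), no injection-to-exposure delay, treatment
    at ~200 mm^3, k1 = 0.51 1/day.

    'cwr22_hagtvet': CWR22 prostate adenocarcinoma protocol - 40 kHz exposure
    for 4 min applied 24 h post-injection (the intratumoral accumulation
    peak of the long-circulating formulation), treatment at ~144 mm^3,
    k1 = 0.38 1/day, tissue driven to ~42 degC.
    """
    if name == "jc_dromi":
        k1, v_treat = 0.51, 200.0
        response = ResponseParams(
            k1=k1,
            V0=_v0_for_treatment_volume(v_treat, k1, 2000.0, 10.0),
            V_K=2000.0,
            kill_law="exponential",
            kill_params={"kappa_kill": _JC_KAPPA_KILL},
        )
        protocol = Protocol(
            injection_time=10.0 * SECONDS_PER_DAY,
            lag_to_fus=0.0,
            t_exp=15.0 * 60.0,
            f=1.0e6,
            source=AcousticSource(p0=_JC_P0, f=1.0e6),
        )
        particle = ParticleSpec(r_s=50e-9, k_d=7.2e3)
        return Scenario(
            particle=particle, response=response, protocol=protocol, name="jc_dromi"
        )
    if name == "cwr22_hagtvet":
        k1, v_treat = 0.38, 144.0
        response = ResponseParams(
            k1=k1,
            V0=_v0_for_treatment_volume(v_treat, k1, 2000.0, 10.0),
            V_K=2000.0,
            kill_law="exponential",
            kill_params={"kappa_kill": _JC_KAPPA_KILL},
        )
        protocol = Protocol(
            injection_time=10.0 * SECONDS_PER_DAY,
            lag_to_fus=24.0 * SECONDS_PER_HOUR,
            t_exp=4.0 * 60.0,
            f=4.0e4,
            source=AcousticSource(p0=_CWR22_P0, f=4.0e4),
        )
        particle = ParticleSpec(r_s=50e-9, k_d=SECONDS_PER_DAY)
        numerics = Numerics(drug_horizon=3.0 * SECONDS_PER_DAY)
        return Scenario(
            particle=particle, response=response, protocol=protocol,
            numerics=numerics, name="cwr22_hagtvet",
        )
    raise KeyError(f"unknown preset {name!r}; available: jc_dromi, cwr22_hagtvet")


def calibrate_source_pressure(
    scn: Scenario, target_peak_celsius: float, max_iter: int = 5, tol_c: float = 0.05
) -> float:
    """Source amplitude achieving the target peak tissue temperature.

    Implements the protocol's amplitude-calibration step: repeatedly run the
    heating-only arm and rescale p0 by sqrt(dT_target/dT) (deposition is
    quadratic in the amplitude, and the conduction problem is close to linear
    over mild-hyperthermia excursions).
    """
    p0 = scn.protocol.source.p0
    target_dT = target_peak_celsius + 273.15 - T_BODY
    for _ in range(max_iter):
        trial = set_param(scn, "protocol.source.p0", p0)
        res = run_scenario(trial, arm="fus")
        dT = res.peak_temperature - T_BODY
        if dT <= 0:
            raise RuntimeError("no heating produced; cannot calibrate amplitude")
        if abs(dT - target_dT) < tol_c:
            break
        p0 *= np.sqrt(target_dT / dT)
    return float(p0)


# --------------------------------------------------------------------------
# parameter sweeps and sensitivity
# --------------------------------------------------------------------------

def set_param(scn, path: str, value):
    """Return a copy of a (nested, frozen) scenario with one field replaced.

    ``path`` is dotted, e.g. 'protocol.f' or 'protocol.fus_modulation.a_p_kth'.
    """
    head, _, rest = path.partition(".")
    if not rest:
        return replace(scn, **{head: value})
    return replace(scn, **{head: set_param(getattr(scn, head), rest, value)})


def particle_variant(
    particle: ParticleSpec, r_s: float, fixed_payload: float | None = None
) -> ParticleSpec:
    """A different-sized formulation of the same liposome chemistry.

    Payload scales with the encapsulated volume (r_s^3) and the interstitial
    carrier diffusivity with 1/r_s (Stokes-Einstein scaling of the baseline
    value), unless a fixed payload is requested to decouple loading from
    transport.
    """
    scale = r_s / _R_S_BASELINE
    payload = (
        fixed_payload if fixed_payload is not None else particle.alpha_payload * scale**3
    )
    return replace(particle, r_s=r_s, alpha_payload=max(payload, 1.0), D_l=particle.D_l / scale)


def sweep(scn: Scenario, axes: dict[str, list], arm: str = "fus+tsl") -> pd.DataFrame:
    """Cartesian parameter sweep; per-cell failures are recorded, not fatal.

    Axis keys are ``set_param`` paths, with two conveniences: 'release' accepts
    formulation labels and 'particle.r_s' applies the coupled size scalings of
    ``particle_variant``.
    """
    names = list(axes)
    rows = []
    for combo in product(*(axes[k] for k in names)):
        trial = scn
        row = dict(zip(names, combo))
        try:
            for key, val in zip(names, combo):
                if key == "release" and isinstance(val, str):
                    trial = replace(trial, release=formulation_library(val))
                elif key == "particle.r_s":
                    trial = replace(trial, particle=particle_variant(trial.particle, val))
                else:
                    trial = set_param(trial, key, val)
            res = run_scenario(trial, arm=arm)
            row.update(
                final_volume=res.final_volume,
                peak_temperature_c=res.peak_temperature_celsius,
                intratumoral_end_exposure=res.intratumoral_end_exposure,
                c_int_final=(
                    float(res.drug_series["c_int_avg"][-1])
                    if res.drug_series["t_s"].size
                    else 0.0
                ),
                time_to_500_day=res.time_to_500_day,
                error="",
            )
        except Exception as exc:  # per-cell failure: record and continue
            row.update(
                final_volume=np.nan, peak_temperature_c=np.nan,
                intratumoral_end_exposure=np.nan, c_int_final=np.nan,
                time_to_500_day=np.nan, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


#: Single-parameter variation levels (multipliers on the baseline value).
DEFAULT_SENSITIVITY_LEVELS = {
    "k_rel": (0.1, 1.0, 6.0),
    "r_s": (0.2, 1.0, 1.3),
    "k1": (1.0, 1.2, 1.4),
    "f": (1.0, 3.0, 5.0),
    "t_exp": (0.033, 1.0, 2.0),
}


def _apply_multiplier(scn: Scenario, param: str, m: float) -> Scenario:
    if param == "k_rel":
        return replace(scn, release=scn.release.scaled(m))
    if param == "r_s":
        return replace(scn, particle=particle_variant(scn.particle, scn.particle.r_s * m))
    if param == "k1":
        return set_param(scn, "response.k1", scn.response.k1 * m)
    if param == "f":
        return set_param(scn, "protocol.f", scn.protocol.f * m)
    if param == "t_exp":
        return set_param(scn, "protocol.t_exp", scn.protocol.t_exp * m)
    raise KeyError(f"unknown sensitivity parameter {param!r}")


def sensitivity_report(
    scn: Scenario,
    levels: dict[str, tuple] | None = None,
    window: tuple[float, float] = (10.0, 17.0),
    arm: str = "fus+tsl",
) -> pd.DataFrame:
    """Per-parameter time-averaged total variance of the volume trajectories.

    Each parameter is varied across its three levels with everything else at
    baseline; the statistic integrates the squared deviation from the
    cross-level mean over the treatment window (days).  Returns a DataFrame
    ranked by log10 total variance.
    """
    levels = levels or DEFAULT_SENSITIVITY_LEVELS
    rows = []
    for param, mults in levels.items():
        trajs = []
        times = None
        for m in mults:
            res = run_scenario(_apply_multiplier(scn, param, m), arm=arm)
            times = res.times_day
            trajs.append(res.volumes)
        tset = TrajectorySet(times=times, volumes=np.vstack(trajs), labels=tuple(mults))
        tot, log10 = total_variance(tset, window=window)
        rows.append(dict(parameter=param, levels=tuple(mults), tot_var=tot, log10_tot_var=log10))
    out = pd.DataFrame(rows).sort_values("log10_tot_var", ascending=False)
    return out.reset_index(drop=True)


# --------------------------------------------------------------------------
# synthetic fixtures
# --------------------------------------------------------------------------

def generate_fixture(kind: str, seed: int, **params):
    """Deterministic synthetic datasets for calibration and solver tests.

    'growth_curve': logistic tumor-volume series with multiplicative
    lognormal noise (sigma in log space); returns (days, volumes).
    'grid_case': a small radial grid with analytic pressure/temperature
    fields for discretization tests.
    """
    rng = np.random.default_rng(seed)
    if kind == "growth_curve":
        k1 = params.get("k1", 0.51)
        v0 = params.get("V0", 50.0)
        v_k = params.get("V_K", 2000.0)
        sigma = params.get("sigma", 0.05)
        n = params.get("n_points", 8)
        t_max = params.get("t_max", 10.0)
        days = np.linspace(0.0, t_max, n)
        clean = logistic_volume(days, k1, v0, v_k)
        noise = np.exp(sigma * rng.standard_normal(n)) if sigma > 0 else 1.0
        return days, clean * noise
    if kind == "grid_case":
        n = params.get("n", 41)
        radius = params.get("radius", 5e-3)
        grid = RadialGrid.uniform(radius, n)
        x = grid.r / radius
        return {
            "grid": grid,
            "pressure": params.get("p_v", 2.66e3) * (1.0 - x**2),
            "temperature": T_BODY + params.get("dT", 4.0) * (1.0 - x**2),
        }
    raise KeyError(f"unknown fixture kind {kind!r}; use 'growth_curve' or 'grid_case'")
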