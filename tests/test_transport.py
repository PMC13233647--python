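"""Four-compartment drug transport: reaction oracle, positivity, mass ledger."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fustsl.constants import T_BODY
from fustsl.grid import RadialGrid
from fustsl.hindered import ParticleSpec, VesselWall, wall_transport
from fustsl.fluids import FluidParams, solve_ifp
from fustsl.release import ReleaseModel, formulation_library, release_rate
from fustsl.transport import (
    BindingKinetics,
    DrugState,
    DrugTransportSolver,
    fold_change,
    intratumoral_drug,
    peclet_number,
    plasma_concentration,
    transvascular_flux,
)

R_TUMOR = 3.6e-3


def make_solver(grid=None, transport=True, release=None, kinetics=None, particle=None):
    grid = grid or RadialGrid.uniform(2.5 * R_TUMOR, 41)
    particle = particle or ParticleSpec(r_s=50e-9, k_d=7200.0, t0=0.0)
    wall = VesselWall(r_0=100e-9)
    return DrugTransportSolver(
        grid,
        particle,
        wall,
        wall_transport(wall, particle),
        kinetics or BindingKinetics(),
        release or formulation_library("fast"),
        R_tumor=R_TUMOR,
        transport_enabled=transport,
    )


class TestPlasmaConcentration:
    def test_bolus_normalization(self):
        assert plasma_concentration(100.0, 100.0, 7200.0) == 1.0

    def test_e_folding(self):
        assert plasma_concentration(100.0 + 7200.0, 100.0, 7200.0) == pytest.approx(
            np.exp(-1)
        )

    def test_pre_injection_zero(self):
        assert plasma_concentration(50.0, 100.0, 7200.0) == 0.0


class TestTransvascularFlux:
    wall = VesselWall(r_0=100e-9)
    h = wall_transport(wall, ParticleSpec(r_s=50e-9))

    def test_no_gradients_no_flux(self):
        q = transvascular_flux(1.0, 1.0, self.h, self.wall, self.wall.p_v, self.wall.p_v)
        assert q == pytest.approx(0.0, abs=1e-20)

    def test_pure_diffusion_term(self):
        q = transvascular_flux(1.0, 0.0, self.h, self.wall, self.wall.p_v, self.wall.p_v)
        assert q == pytest.approx(self.h.Per * self.wall.S_v)

    def test_arithmetic_composition(self):
        # Per Sv c_iv + Lp Sv dp (1-sigma) c_iv with round numbers:
        # 1e-8 * 1e4 * 1 + 2e-4 = 3e-4
        import dataclasses

        h = dataclasses.replace(self.h, Per=1e-8, Lp=2e-4 / (1e4 * 100.0 * 0.5), sigma_f=0.5)
        wall = dataclasses.replace(self.wall, S_v=1e4, p_v=100.0)
        q = transvascular_flux(1.0, 0.0, h, wall, wall.p_v, 0.0)
        assert q == pytest.approx(3e-4, rel=1e-12)


def test_quasi_steady_bound_to_free_ratio():
    # fixed point of the binding balance: c_b/c_f = k_bind / (k_off + k_int)
    kin = BindingKinetics(k_on=3.0e-4, c_rec=1.0, phi=0.3, k_off=1e-4, k_int=5e-4)
    assert kin.k_bind == pytest.approx(1e-3)
    assert kin.k_bind / (kin.k_off + kin.k_int) == pytest.approx(1.667, rel=1e-3)
    solver = make_solver(transport=False, kinetics=kin)
    state = DrugState.zeros(solver.grid)
    state.c_f[:] = 1.0
    state.c_b[:] = kin.k_bind / (kin.k_off + kin.k_int)  # the balance point
    out = solver.step(state, T_BODY, 0.0, None, 1.0)
    # at the balance point dc_b/dt = 0 while c_f is still draining
    d_cb = abs(out.c_b[0] - state.c_b[0])
    d_cf = abs(out.c_f[0] - state.c_f[0])
    assert d_cb < 0.01 * d_cf


@pytest.mark.parametrize("draw", range(20))
def test_well_mixed_matches_ode_oracle(draw):
    rng = np.random.default_rng(500 + draw)
    particle = ParticleSpec(
        r_s=50e-9, k_d=float(rng.uniform(1800, 20000)), t0=0.0,
        alpha_payload=float(rng.uniform(1e2, 1e4)),
    )
    kin = BindingKinetics(
        k_on=float(rng.uniform(1e-4, 1e-3)),
        k_off=float(rng.uniform(1e-5, 5e-4)),
        k_int=float(rng.uniform(1e-4, 1e-3)),
        phi=float(rng.uniform(0.2, 0.9)),
    )
    grid = RadialGrid.uniform(2.5 * R_TUMOR, 3)
    solver = make_solver(grid=grid, transport=False, kinetics=kin, particle=particle)
    h, wall = solver.hindrance, solver.wall
    T = float(rng.uniform(309.0, 316.0))
    p = float(rng.uniform(0.0, wall.p_v))
    krel = release_rate(T, solver.release_model)

    def rhs(t, y):
        cl, cf, cb, ci = y
        civ = plasma_concentration(t, 0.0, particle.k_d)
        qsta = h.Per * wall.S_v * (civ - cl) + h.Lp * wall.S_v * (wall.p_v - p) * (
            1 - h.sigma_f
        ) * civ
        return [
            -krel * cl + qsta,
            particle.alpha_payload * krel * cl - kin.k_bind * cf + kin.k_off * cb,
            kin.k_bind * cf - (kin.k_off + kin.k_int) * cb,
            kin.k_int * cb,
        ]

    t_end = 86400.0
    ref = solve_ivp(rhs, [0, t_end], [0, 0, 0, 0], rtol=1e-12, atol=1e-16, method="LSODA")
    state = DrugState.zeros(grid)
    for _ in range(96):
        state = solver.step(state, T, p, None, t_end / 96)
    ours = np.array([state.c_l[0], state.c_f[0], state.c_b[0], state.c_int[0]])
    expected = ref.y[:, -1]
    assert np.all(np.abs(ours - expected) <= 1e-6 * np.abs(expected) + 1e-14)


def _pde_run(n_steps=60, dt=30.0, hot=False):
    grid = RadialGrid.uniform(2.5 * R_TUMOR, 41)
    solver = make_solver(grid=grid)
    fp = FluidParams(R_tumor=R_TUMOR, Lp=solver.hindrance.Lp)
    p, v = solve_ifp(fp, grid)
    T = np.full(grid.n, 315.15 if hot else T_BODY)
    state = DrugState.zeros(grid)
    states = [state]
    for _ in range(n_steps):
        state = solver.step(state, T, p, v, dt)
        states.append(state)
    return solver, grid, states


def test_pde_positivity_and_internalized_monotonicity():
    _, _, states = _pde_run()
    prev = states[0]
    for st in states[1:]:
        for arr in (st.c_l, st.c_f, st.c_b, st.c_int):
            assert np.min(arr) >= 0.0
        assert np.all(st.c_int >= prev.c_int - 1e-15)
        prev = st


def test_mass_ledger_against_starling_source():
    # over a short early window boundary losses are negligible; the discrete
    # total drug mass must track the integrated transvascular source
    solver, grid, states = _pde_run(n_steps=10, dt=30.0)
    vols = grid.cell_volumes
    mask = solver.tumor_mask
    alpha = solver.particle.alpha_payload
    for before, after in zip(states[:-1], states[1:]):
        dm = solver.total_drug_mass(after) - solver.total_drug_mass(before)
        civ = plasma_concentration(after.t, 0.0, solver.particle.k_d)
        h, wall = solver.hindrance, solver.wall
        # source evaluated at the implicit (end-of-step) state
        q = h.Per * wall.S_v * (civ - after.c_l) + h.Lp * wall.S_v * (
            wall.p_v - solve_ifp(FluidParams(R_tumor=R_TUMOR, Lp=h.Lp), grid)[0]
        ) * (1 - h.sigma_f) * civ
        expected = 30.0 * alpha * np.sum((q * mask) * vols)
        assert dm == pytest.approx(expected, rel=5e-3)


def test_hotter_tissue_internalizes_more_drug():
    _, grid, cold = _pde_run(hot=False)
    _, _, hot = _pde_run(hot=True)
    c_cold = intratumoral_drug(cold[-1], grid, R_TUMOR)
    c_hot = intratumoral_drug(hot[-1], grid, R_TUMOR)
    assert c_hot > c_cold
    assert np.all(hot[-1].c_int >= cold[-1].c_int)


def test_no_release_keeps_downstream_compartments_empty():
    # a practically frozen formulation: only the carrier compartment evolves
    frozen = ReleaseModel(A=1e-300, B=1e-6, label="fast")
    solver = make_solver(release=frozen)
    state = DrugState.zeros(solver.grid)
    fp = FluidParams(R_tumor=R_TUMOR, Lp=solver.hindrance.Lp)
    p, v = solve_ifp(fp, solver.grid)
    for _ in range(20):
        state = solver.step(state, T_BODY, p, v, 60.0)
    assert state.c_l.max() > 0
    assert state.c_f.max() < 1e-200
    assert state.c_b.max() < 1e-200
    assert state.c_int.max() < 1e-200


class TestDiagnostics:
    def test_intratumoral_average_cases(self):
        grid = RadialGrid.uniform(2.5 * R_TUMOR, 41)
        state = DrugState.zeros(grid)
        assert intratumoral_drug(state, grid, R_TUMOR) == 0.0
        state.c_int[:] = 1.0
        assert intratumoral_drug(state, grid, R_TUMOR) == pytest.approx(1.0)

    def test_fold_change_identity(self):
        assert fold_change(3.7, 3.7) == 1.0

    def test_peclet(self):
        assert peclet_number(0.0, 5e-3, 1e-11) == 0.0
        assert peclet_number(1e-7, 5e-3, 1e-11) == pytest.approx(50.0)
        assert peclet_number(1e-7, 1e-2, 1e-11) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            peclet_number(1e-7, 5e-3, 0.0)
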