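"""Orchestration: presets, event log, determinism, sweeps, fixtures, CLI."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import fustsl
from fustsl.constants import SECONDS_PER_HOUR
from fustsl.pharmacodynamics import logistic_volume
from fustsl.scenarios import particle_variant, set_param, volume_to_radius
from conftest import tsl_drug_at


class TestPresets:
    def test_jc_protocol_values(self):
        scn = fustsl.preset("jc_dromi")
        assert scn.response.k1 == pytest.approx(0.51)
        assert scn.protocol.f == 1.0e6
        assert scn.protocol.lag_to_fus == 0.0
        # treatment begins at ~200 mm^3
        v_treat = logistic_volume(10.0, scn.response.k1, scn.response.V0, scn.response.V_K)
        assert v_treat == pytest.approx(200.0, rel=1e-6)

    def test_cwr22_protocol_values(self):
        scn = fustsl.preset("cwr22_hagtvet")
        assert scn.response.k1 == pytest.approx(0.38)
        assert scn.protocol.lag_to_fus == pytest.approx(24 * SECONDS_PER_HOUR)
        assert scn.protocol.t_exp == pytest.approx(4 * 60.0)
        v_treat = logistic_volume(10.0, scn.response.k1, scn.response.V0, scn.response.V_K)
        assert v_treat == pytest.approx(144.0, rel=1e-6)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            fustsl.preset("hela")


class TestRunScenario:
    def test_control_matches_logistic_closed_form(self, jc_scenario, jc_arms):
        res = jc_arms["control"]
        exact = logistic_volume(
            res.times_day, jc_scenario.response.k1,
            jc_scenario.response.V0, jc_scenario.response.V_K,
        )
        assert np.max(np.abs(res.volumes - exact) / exact) < 1e-3

    def test_combination_delivers_more_drug_than_tsl_alone(
        self, jc_scenario, jc_arms, tsl_reference
    ):
        combo = jc_arms["fus+tsl"]
        t_end_exposure = jc_scenario.protocol.t_fus + jc_scenario.protocol.t_exp
        tsl_matched = tsl_drug_at(tsl_reference, t_end_exposure)
        assert combo.intratumoral_end_exposure > tsl_matched

    def test_event_log_complete_and_unique(self, jc_arms):
        labels = [label for _, label in jc_arms["fus+tsl"].events]
        for expected in (
            "injection", "fus_on", "fus_off", "modulation_on",
            "ifp_solve_baseline", "ifp_solve_modulated",
            "clock_fine", "clock_cooling", "clock_post",
        ):
            assert labels.count(expected) == 1, expected
        times = [t for t, _ in jc_arms["fus+tsl"].events]
        assert times == sorted(times)

    def test_end_to_end_determinism(self, jc_scenario, jc_arms):
        again = fustsl.run_scenario(jc_scenario, arm="fus+tsl")
        ref = jc_arms["fus+tsl"]
        assert np.array_equal(again.volumes, ref.volumes)
        assert np.array_equal(
            again.drug_series["c_int_avg"], ref.drug_series["c_int_avg"]
        )
        assert np.array_equal(
            again.temperature_series["peak_T"], ref.temperature_series["peak_T"]
        )

    def test_lag_insensitivity_of_combination(self, jc_scenario, tsl_reference):
        lags = (5.0, 60.0, 120.0)
        combo_vals, tsl_vals = [], []
        for lag_min in lags:
            scn = set_param(jc_scenario, "protocol.lag_to_fus", lag_min * 60.0)
            res = fustsl.run_scenario(scn)
            combo_vals.append(res.intratumoral_end_exposure)
            tsl_vals.append(
                tsl_drug_at(tsl_reference, scn.protocol.t_fus + scn.protocol.t_exp)
            )
        combo_range = (max(combo_vals) - min(combo_vals)) / np.mean(combo_vals)
        tsl_range = (max(tsl_vals) - min(tsl_vals)) / np.mean(tsl_vals)
        assert combo_range < tsl_range

    def test_fine_clock_refinement_changes_little(self, jc_scenario, jc_arms):
        ref = jc_arms["fus+tsl"]
        fine = fustsl.run_scenario(
            set_param(jc_scenario, "numerics.dt_fine", 4.0), arm="fus+tsl"
        )
        rel_T = abs(fine.peak_temperature - ref.peak_temperature) / (
            ref.peak_temperature - 310.15
        )
        rel_drug = abs(
            fine.drug_series["c_int_avg"][-1] - ref.drug_series["c_int_avg"][-1]
        ) / ref.drug_series["c_int_avg"][-1]
        assert rel_T < 0.01
        assert rel_drug < 0.01

    def test_unknown_arm_rejected(self, jc_scenario):
        with pytest.raises(ValueError):
            fustsl.run_scenario(jc_scenario, arm="placebo")


class TestSweep:
    def test_degenerate_sweep_equals_run_scenario(self, jc_scenario, jc_arms):
        df = fustsl.sweep(jc_scenario, {"protocol.f": [1.0e6]})
        assert len(df) == 1
        assert df.loc[0, "final_volume"] == pytest.approx(
            jc_arms["fus+tsl"].final_volume
        )
        assert df.loc[0, "error"] == ""

    def test_failures_are_recorded_not_fatal(self, jc_scenario):
        df = fustsl.sweep(jc_scenario, {"protocol.f": [1.0e6, -2.0e6]})
        assert df.loc[1, "error"] != ""
        assert np.isnan(df.loc[1, "final_volume"])
        assert df.loc[0, "error"] == ""

    def test_oversized_particle_is_excluded_not_an_error(self, jc_scenario):
        df = fustsl.sweep(jc_scenario, {"particle.r_s": [150e-9]})
        assert df.loc[0, "error"] == ""
        # fully excluded particle delivers essentially nothing
        assert df.loc[0, "c_int_final"] < 1e-6


class TestHelpers:
    def test_set_param_nested(self, jc_scenario):
        scn = set_param(jc_scenario, "protocol.fus_modulation.a_p_kth", 7.5)
        assert scn.protocol.fus_modulation.a_p_kth == 7.5
        assert jc_scenario.protocol.fus_modulation.a_p_kth == 5.0

    def test_particle_variant_scalings(self, jc_scenario):
        base = jc_scenario.particle
        small = particle_variant(base, 10e-9)
        assert small.alpha_payload == pytest.approx(base.alpha_payload * (10 / 50) ** 3)
        assert small.D_l == pytest.approx(base.D_l * 5.0)
        fixed = particle_variant(base, 10e-9, fixed_payload=1e4)
        assert fixed.alpha_payload == 1e4

    def test_volume_radius_roundtrip(self):
        r = volume_to_radius(200.0)
        assert 4.0 / 3.0 * np.pi * r**3 * 1e9 == pytest.approx(200.0)


class TestFixtures:
    def test_same_seed_identical(self):
        a = fustsl.generate_fixture("growth_curve", seed=11)
        b = fustsl.generate_fixture("growth_curve", seed=11)
        assert np.array_equal(a[1], b[1])

    def test_zero_noise_exact_model_curve(self):
        days, vols = fustsl.generate_fixture(
            "growth_curve", seed=1, sigma=0.0, k1=0.4, V0=30.0, V_K=1500.0
        )
        assert np.allclose(vols, logistic_volume(days, 0.4, 30.0, 1500.0))

    def test_grid_case_fields(self):
        case = fustsl.generate_fixture("grid_case", seed=2, n=21)
        assert case["grid"].n == 21
        assert case["pressure"][0] > case["pressure"][-1]

    def test_unknown_kind(self):
        with pytest.raises(KeyError):
            fustsl.generate_fixture("survival_curve", seed=0)


class TestCLI:
    def test_tables_and_calibration_roundtrip(self, tmp_path):
        from fustsl.cli import main

        growth = tmp_path / "growth.csv"
        assert main(["fixtures", "--kind", "growth_curve", "--seed", "5",
                     "--out", str(growth)]) == 0
        assert main(["hindrance", "--out", str(tmp_path / "h.csv")]) == 0
        assert main(["release", "--out", str(tmp_path / "r.csv")]) == 0
        h = pd.read_csv(tmp_path / "h.csv")
        assert {"lam", "H", "W", "Per", "sigma_f"} <= set(h.columns)
        assert main(["calibrate", "--data", str(growth)]) == 0

    def test_simulate_writes_outputs(self, tmp_path):
        from fustsl.cli import main

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("numerics.t_end_day: 12.0\n")
        out = tmp_path / "run"
        code = main([
            "simulate", "--preset", "jc_dromi", "--config", str(cfg),
            "--arm", "control", "--out", str(out),
        ])
        assert code == 0
        vols = pd.read_csv(out / "tumor_volume.csv")
        assert vols["time_day"].iloc[-1] == pytest.approx(12.0)
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["arm"] == "control"
        assert manifest["scenario"]["response"]["k1"] == pytest.approx(0.51)
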