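"""End-to-end orchestration: determinism, sweeps, calibration, fixtures."""

import numpy as np
import pandas as pd
import pytest
import yaml

import fontansim as fs
from fontansim import scenario_runner
from fontansim.scenario_runner import (CalibrationError, CalibrationTarget,
                                       calibrate_registry, generate_fixtures,
                                       run_scenario, run_sweep)


class TestRunScenario:
    def test_repeated_run_bit_identical(self):
        cfg = fs.ScenarioConfig(vvc_enabled=True)
        a = run_scenario(cfg)
        b = run_scenario(cfg)
        assert a.config_hash == b.config_hash
        assert a.oxygen.sao2 == b.oxygen.sao2
        assert a.mean.co == b.mean.co
        np.testing.assert_array_equal(a.solution.states, b.solution.states)

    def test_loads_yaml_document(self, tmp_path):
        doc = {"scenario": {"vvc_enabled": True, "pvr_ratio": 1.2}}
        path = tmp_path / "scenario.yaml"
        path.write_text(yaml.safe_dump(doc))
        res = run_scenario(str(path))
        assert res.config.vvc_enabled
        assert res.config.pvr_ratio == 1.2

    def test_summary_fields(self, baseline_result):
        s = baseline_result.summary()
        for key in ("sao2", "svo2", "co", "net_co", "ef", "ees_over_ea",
                    "sw_over_pva"):
            assert np.isfinite(s[key]), key


class TestRunSweep:
    def test_single_cell_equals_standalone_run(self):
        table = run_sweep(None, pvr_ratios=[1.1], doses=[0.0],
                          collateral_configs=["vvc"])
        row = table.row("vvc", 1.1, 0.0)
        solo = run_scenario(fs.ScenarioConfig(pvr_ratio=1.1, vvc_enabled=True))
        assert row["sao2"] == solo.oxygen.sao2
        assert row["co"] == solo.mean.co

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_sweep(None, pvr_ratios=[], doses=[0.0])

    def test_failed_cell_recorded_not_raised(self):
        # a dose beyond the calibrated grid fails in that cell only
        table = run_sweep(None, pvr_ratios=[1.0], doses=[0.0, 99.0],
                          collateral_configs=["none"])
        bad = table.row("none", 1.0, 99.0)
        good = table.row("none", 1.0, 0.0)
        assert "ValueError" in bad["error"]
        assert good["error"] == ""
        assert np.isfinite(good["sao2"])


class TestCalibrateRegistry:
    def test_satisfied_targets_short_circuit(self):
        base = run_scenario(fs.ScenarioConfig())
        targets = [CalibrationTarget("sao2_nc", fs.ScenarioConfig(), "sao2",
                                     base.oxygen.sao2, tolerance=0.5)]
        result = calibrate_registry(
            targets, {"shunts.vvc.conductance": (0.5, 5.0)})
        assert result.n_evaluations == 0
        assert result.success
        assert result.registry == fs.default_registry()

    def test_single_parameter_recovers_perturbed_conductance(self):
        """SaO2 decreases monotonically in the VVC conductance, so a 1D
        search must recover the saturation produced by a known conductance."""
        registry = fs.default_registry()
        true_g = registry["shunts.vvc.conductance"]
        cfg = fs.ScenarioConfig(vvc_enabled=True, apc_enabled=True)
        target_sao2 = run_scenario(cfg).oxygen.sao2
        perturbed = registry.updated({"shunts.vvc.conductance": true_g * 1.6})
        result = calibrate_registry(
            [CalibrationTarget("sao2", cfg, "sao2", target_sao2, tolerance=0.1)],
            {"shunts.vvc.conductance": (true_g * 0.3, true_g * 3.0)},
            registry=perturbed)
        assert abs(result.predictions["sao2"] - target_sao2) <= 0.1

    def test_infeasible_target_reports_failure(self):
        # arterial saturation cannot exceed the pulmonary end-capillary
        # saturation while a VVC admixes venous blood
        cfg = fs.ScenarioConfig(vvc_enabled=True, apc_enabled=True)
        with pytest.raises(CalibrationError) as err:
            calibrate_registry(
                [CalibrationTarget("sao2", cfg, "sao2", 99.5, tolerance=0.5)],
                {"shunts.vvc.conductance": (0.5, 5.0)},
                max_evaluations=40)
        report = err.value.result.report()
        assert (report.residual.abs() > 0.5).any()

    def test_more_parameters_than_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_registry(
                [CalibrationTarget("x", fs.ScenarioConfig(), "sao2", 96.0)],
                {"a": (0.0, 1.0), "b": (0.0, 1.0)})


class TestFixtures:
    def test_rc_loop_fixture_consistent(self, tmp_path):
        paths = generate_fixtures("rc_loop", tmp_path)
        doc = yaml.safe_load(paths[0].read_text())
        exp = doc["expected"]
        ra = doc["edges"]["a"]["R"]
        rb = doc["edges"]["b"]["R"]
        c1 = doc["compartments"]["c1"]["C"]
        c2 = doc["compartments"]["c2"]["C"]
        rate = (1 / ra + 1 / rb) * (1 / c1 + 1 / c2)
        assert exp["decay_rate"] == pytest.approx(rate, rel=1e-12)

    def test_two_node_mixing_fixture_solves_stated_system(self, tmp_path):
        paths = generate_fixtures("two_node_mixing", tmp_path)
        doc = yaml.safe_load(paths[0].read_text())
        f = doc["inputs"]["vvc_fraction"]
        s_cap = doc["inputs"]["pulmonary_end_capillary_saturation"]
        drop = doc["inputs"]["arteriovenous_sat_drop"]
        sao2 = doc["expected"]["sao2"]
        assert sao2 == pytest.approx((1 - f) * s_cap + f * (sao2 - drop),
                                     abs=1e-9)

    def test_reference_scenarios_parse_and_run(self, tmp_path):
        paths = generate_fixtures("reference_scenarios", tmp_path)
        assert len(paths) == 4
        resolved = fs.load_config(str(paths[0]))
        assert isinstance(resolved.config, fs.ScenarioConfig)

    def test_rectangle_fixture_matches_metric_arithmetic(self, tmp_path):
        paths = generate_fixtures("rectangle_pv", tmp_path)
        df = pd.read_csv(paths[0])
        meta = yaml.safe_load(paths[1].read_text())["expected"]
        assert df.volume.max() == meta["edv"]
        assert meta["ef_percent"] == pytest.approx(100 * 70 / 120)

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_fixtures("nope", tmp_path)
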