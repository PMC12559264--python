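"""ODE right-hand side, conservation, RC oracle, limit cycle, beat averages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import fontansim as fs
from fontansim.hemodynamics import (CirculationState, CompiledModel,
                                    NumericalError, beat_averages,
                                    run_to_limit_cycle, state_derivative)
from fontansim.parameters import PatientParameters

from conftest import make_rc_loop

PATIENT = PatientParameters()


class TestStateDerivative:
    def test_equilibrium_has_zero_derivative(self, rc_loop):
        state = CirculationState(volumes={"n1": 1.5 * 10.0, "n2": 3.0 * 10.0})
        d = state_derivative(rc_loop, state, 0.0, PATIENT)
        assert d.volumes["n1"] == pytest.approx(0.0, abs=1e-12)
        assert d.volumes["n2"] == pytest.approx(0.0, abs=1e-12)

    def test_rc_loop_matches_closed_form(self, rc_loop):
        # dV1/dt = -(P1 - P2) (1/Ra + 1/Rb) with P = V/C
        state = CirculationState(volumes={"n1": 30.0, "n2": 15.0})
        p1, p2 = 30.0 / 1.5, 15.0 / 3.0
        expected = -(p1 - p2) * (1.0 / 1.0 + 1.0 / 2.0)
        d = state_derivative(rc_loop, state, 0.0, PATIENT)
        assert d.volumes["n1"] == pytest.approx(expected, rel=1e-12)
        assert d.volumes["n2"] == pytest.approx(-expected, rel=1e-12)

    @given(st.lists(st.floats(1.0, 400.0), min_size=8, max_size=8))
    @settings(max_examples=40, deadline=None)
    def test_volume_conservation_for_any_state(self, volumes):
        topo = fs.build_fontan_topology(
            fs.ScenarioConfig(vvc_enabled=True, apc_enabled=True))
        state = CirculationState(volumes=dict(zip(topo.node_names, volumes)))
        d = state_derivative(topo, state, 0.123, PATIENT)
        total = sum(d.volumes.values())
        scale = max(abs(v) for v in d.volumes.values()) + 1.0
        assert abs(total) < 1e-10 * scale

    def test_nonfinite_state_surfaced_with_name(self, fontan_topology):
        state = CirculationState(volumes={
            n: (np.nan if n == "conduit" else 50.0)
            for n in fontan_topology.node_names})
        with pytest.raises(NumericalError, match="conduit"):
            state_derivative(fontan_topology, state, 0.0, PATIENT)


class TestRCLoopTransient:
    def test_decay_matches_closed_form_within_half_percent(self):
        ra, rb, c1, c2 = 1.0, 2.0, 1.5, 3.0
        topo = make_rc_loop(ra, rb, c1, c2, p1=20.0, p2=5.0)
        model = CompiledModel(topo, PATIENT)
        y0 = model.initial_state()
        rate = (1 / ra + 1 / rb) * (1 / c1 + 1 / c2)
        t_end = 2.0 / rate
        sol = solve_ivp(model.rhs, (0, t_end), y0, method="LSODA",
                        rtol=1e-9, atol=1e-11, t_eval=np.linspace(0, t_end, 20))
        p = model.pressures(sol.y.T, sol.t)
        dp = p[:, 0] - p[:, 1]
        expected = (20.0 - 5.0) * np.exp(-rate * sol.t)
        np.testing.assert_allclose(dp, expected, rtol=5e-3)

    def test_inertial_edge_conserves_volume(self):
        topo = make_rc_loop(la=0.05)
        model = CompiledModel(topo, PATIENT)
        assert model.n_inertial == 1
        y0 = model.initial_state()
        sol = solve_ivp(model.rhs, (0, 5.0), y0, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        totals = sol.y[:2].sum(axis=0)
        np.testing.assert_allclose(totals, totals[0], rtol=1e-9)


class TestLimitCycle:
    def test_default_scenario_converges_and_conserves_volume(self, baseline_result):
        sol = baseline_result.solution
        assert sol.beats_to_convergence < 200
        assert sol.residual < 1e-4
        assert sol.volume_drift < 1e-3

    def test_beat_solution_is_periodic(self, baseline_result):
        sol = baseline_result.solution
        rel = np.abs(sol.states[-1] - sol.states[0]) / \
            np.maximum(np.abs(sol.states[0]), 1.0)
        assert rel.max() < 2e-4

    def test_no_pumping_settles_to_zero_flow_equilibrium(self, registry):
        reg = registry.updated({
            "chambers.ventricle.e_max": registry["chambers.ventricle.e_min"],
            "chambers.atrium.e_max": registry["chambers.atrium.e_min"]})
        topo = fs.build_fontan_topology(fs.ScenarioConfig(), reg)
        sol = run_to_limit_cycle(topo, PATIENT)
        flows = sol.edge_flows()
        # residual creep toward the exact equilibrium is bounded by the
        # limit-cycle tolerance; 0.02 mL/s is <0.05% of a physiologic CO
        assert max(np.abs(q).max() for q in flows.values()) < 0.02

    def test_restart_from_converged_beat_is_immediate(self, baseline_result):
        sol = baseline_result.solution
        again = run_to_limit_cycle(sol.topology, sol.model.patient,
                                   init=sol.states[-1])
        assert again.beats_to_convergence <= 2


class TestBeatAverages:
    def test_junction_flow_balance(self, baseline_result):
        mean = baseline_result.mean
        co_mls = mean.co * 1000.0 / 60.0
        imbalance = mean.junction_imbalance(baseline_result.solution.topology)
        assert max(abs(v) for v in imbalance.values()) < 1e-3 * co_mls

    def test_no_shunt_scenario_co_equals_systemic_return(self, registry):
        # without fenestration or collaterals every aortic millilitre comes
        # back through the cavae except the coronary return
        res = fs.run_scenario(fs.ScenarioConfig(fenestration_enabled=False))
        q = res.mean.edge_flows
        co = q["aortic_valve"]
        caval = q["svc_to_pa"] + q["conduit_to_pa"]
        assert caval + q["bed_coronary"] == pytest.approx(co, rel=1e-3)

    def test_apc_recirculation_makes_co_exceed_net_co(self, collateral_result,
                                                      baseline_result):
        assert collateral_result.mean.co > collateral_result.mean.net_co
        q_apc = collateral_result.mean.edge_flows["apc"]
        assert q_apc > 0
        # mass balance: the excess of CO over caval return is exactly the
        # recirculated (APC) plus shunted (VVC, fenestration, coronary) flow
        q = collateral_result.mean.edge_flows
        excess = (collateral_result.mean.co - collateral_result.mean.net_co) \
            * 1000.0 / 60.0
        assert excess == pytest.approx(
            q["apc"] + q["vvc"] + q["fenestration"] + q["bed_coronary"],
            rel=1e-3)

    def test_timeseries_export_schema(self, baseline_result, tmp_path):
        path = tmp_path / "beat.csv"
        baseline_result.solution.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert "time" in df.columns
        assert "p_aorta" in df.columns
        assert "q_aortic_valve" in df.columns
        assert len(df) == len(baseline_result.solution.time)
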