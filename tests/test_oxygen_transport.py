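"""O2 content formulas, the mixing fixed point, and its closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fontansim.oxygen_transport import (FickParameters, InfeasibleVO2Error,
                                        fick_vo2, linear_mixing_solve, o2_content,
                                        solve_saturations)
from fontansim.parameters import PatientParameters

from conftest import make_mixing_chain, mixing_mean


class TestContentFormulas:
    @pytest.mark.parametrize("sat, hb, po2, expected", [
        (97.0, 15.0, 100.0, 20.098),      # 15*1.36*0.97 + 100*0.0031
        (60.0, 15.0, 40.0, 12.364),       # 15*1.36*0.60 + 40*0.0031
        (0.0, 12.0, 0.0, 0.0),
        (100.0, 10.0, 0.0, 13.6),
    ])
    def test_printed_formula_exact(self, sat, hb, po2, expected):
        assert o2_content(sat, hb, po2) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_saturation_rejected(self):
        with pytest.raises(ValueError):
            o2_content(101.0, 15.0, 100.0)
        with pytest.raises(ValueError):
            o2_content(-0.1, 15.0, 100.0)

    @pytest.mark.parametrize("coi, cao2, cvo2, expected", [
        (3.0, 20.098, 12.364, 232.02),
        (2.0, 18.0, 18.0, 0.0),
        (0.0, 20.0, 10.0, 0.0),
    ])
    def test_fick_arithmetic_exact(self, coi, cao2, cvo2, expected):
        assert fick_vo2(coi, cao2, cvo2) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.5, 5.0), st.floats(5.0, 25.0), st.floats(0.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_fick_linear_in_extraction(self, coi, cao2, gap):
        assert fick_vo2(coi, cao2, cao2 - gap) == pytest.approx(coi * gap * 10.0)


FICK = FickParameters(hb=15.0, vo2i=125.0, pulmonary_end_capillary_saturation=98.0)
PATIENT = PatientParameters()


class TestMixingSolve:
    def test_shunt_free_sao2_equals_capillary_saturation(self, mixing_chain):
        mean = mixing_mean(vvc_fraction=0.0)
        state = solve_saturations(mean, mixing_chain, FICK, PATIENT)
        assert state.sao2 == pytest.approx(98.0, abs=1e-9)

    def test_two_node_closed_form_oracle(self, mixing_chain):
        """One VVC carrying fraction f of pulmonary venous inflow: the
        arterial saturation solves sao2 = (1-f) s_cap + f (sao2 - drop)."""
        f = 0.1
        mean = mixing_mean(vvc_fraction=f)
        state = solve_saturations(mean, mixing_chain, FICK, PATIENT)
        # independent algebraic solution of the two-equation system
        k = FICK.hb * 1.36 / 100.0
        drop_content = FICK.vo2i * PATIENT.bsa / (100.0 * 0.06 * 10.0)
        drop = (drop_content - (FICK.pao2 - FICK.pvo2) * 0.0031) / k
        sao2_expected = ((1 - f) * 98.0 - f * drop) / (1 - f)
        assert state.sao2 == pytest.approx(sao2_expected, abs=1e-6)
        assert state.svo2 == pytest.approx(sao2_expected - drop, abs=1e-6)

    def test_fixed_point_matches_direct_linear_solve(self, mixing_chain):
        for f in (0.0, 0.05, 0.18, 0.3):
            mean = mixing_mean(vvc_fraction=f)
            fp = solve_saturations(mean, mixing_chain, FICK, PATIENT)
            lin = linear_mixing_solve(mean, mixing_chain, FICK, PATIENT)
            for node in fp.node_saturations:
                assert fp.node_saturations[node] == pytest.approx(
                    lin.node_saturations[node], abs=1e-9)

    @given(st.floats(0.0, 0.35), st.integers(40, 200))
    @settings(max_examples=25, deadline=None)
    def test_fixed_point_linear_solve_equivalence_property(self, f, total):
        chain = make_mixing_chain()
        mean = mixing_mean(vvc_fraction=f, total=float(total))
        fp = solve_saturations(mean, chain, FICK, PATIENT)
        lin = linear_mixing_solve(mean, chain, FICK, PATIENT)
        assert fp.sao2 == pytest.approx(lin.sao2, abs=1e-9)
        assert fp.svo2 == pytest.approx(lin.svo2, abs=1e-9)

    def test_fick_closure_exact(self, mixing_chain):
        mean = mixing_mean(vvc_fraction=0.15)
        state = solve_saturations(mean, mixing_chain, FICK, PATIENT)
        assert state.fick_residual() < 1e-6 * state.vo2i

    def test_monotone_in_vvc_fraction(self, mixing_chain):
        sats = [solve_saturations(mixing_mean(vvc_fraction=f), mixing_chain,
                                  FICK, PATIENT).sao2
                for f in (0.0, 0.1, 0.2, 0.3)]
        assert all(a > b for a, b in zip(sats, sats[1:]))

    def test_monotone_in_vo2i(self, mixing_chain):
        mean = mixing_mean(vvc_fraction=0.1)
        svo2 = []
        for vo2i in (80.0, 125.0, 170.0):
            fick = FickParameters(hb=15.0, vo2i=vo2i,
                                  pulmonary_end_capillary_saturation=98.0)
            svo2.append(solve_saturations(mean, mixing_chain, fick, PATIENT).svo2)
        assert svo2[0] > svo2[1] > svo2[2]

    def test_infeasible_vo2_reports_maximum(self, mixing_chain):
        mean = mixing_mean(vvc_fraction=0.1, total=20.0)
        fick = FickParameters(hb=15.0, vo2i=600.0,
                              pulmonary_end_capillary_saturation=98.0)
        with pytest.raises(InfeasibleVO2Error) as err:
            solve_saturations(mean, mixing_chain, fick, PATIENT)
        vo2i_max = err.value.vo2i_max
        assert 0 < vo2i_max < 600.0
        # the reported maximum is itself (just barely) feasible
        feasible = FickParameters(hb=15.0, vo2i=vo2i_max * 0.999,
                                  pulmonary_end_capillary_saturation=98.0)
        state = solve_saturations(mean, mixing_chain, feasible, PATIENT)
        assert min(state.node_saturations.values()) >= -1e-6
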