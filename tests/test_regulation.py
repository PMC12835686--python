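"""Vessel tone: Laplace wall tension, the Carlson-Arciero tension forms, the
sigmoidal activation law, and the calibrated control fixed point."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerebroflow.calibration import calibrated_regulation, control_midpoint_pressures
from cerebroflow.regulation import (
    CompartmentRegulation,
    RegulationError,
    RegulationShape,
    RegulationState,
    active_tension_max,
    calibrate_tension_and_tone,
    passive_tension,
    regulation_rhs,
    tone_stimulus,
    total_activation,
    total_tension,
    wall_tension,
)
from cerebroflow.units import MMHG_TO_DYN_CM2


@pytest.fixture(scope="module")
def params(control_state):
    return calibrated_regulation(control_state)


@pytest.fixture(scope="module")
def control_inputs(network, control_state):
    midpoints = control_midpoint_pressures(network, control_state.nodal_pressures)
    return {
        "midpoints": midpoints,
        "shear": control_state.control_shear,
        "smeta": control_state.control_smeta,
    }


def make_params(**overrides) -> CompartmentRegulation:
    base = dict(
        cid="test", tone_class="SA", d0=0.01, cpass=100.0, cpass_exp=7.0,
        cact=300.0, cact_center=1.0, cact_width=0.5, cmyo=0.01, cshear=0.1,
        cmeta=1.0, ctone=0.0, dc=0.01, tc=300.0, pc=60.0, ac=0.5,
    )
    base.update(overrides)
    return CompartmentRegulation(**base)


class TestWallTension:
    def test_zero_transmural_pressure(self):
        assert wall_tension(9.5, 9.5, 0.01) == 0.0

    def test_small_arteriole_control_value(self):
        # midpoint of the tabulated P2/P3 pressures, tabulated diameter 148 um
        t = wall_tension((74.7 + 44.7) / 2, 9.5, 148e-4)
        assert t == pytest.approx(495.0, abs=2.0)

    def test_linear_in_diameter(self):
        assert wall_tension(60, 9.5, 0.02) == pytest.approx(2 * wall_tension(60, 9.5, 0.01))

    def test_negative_transmural_pressure_allowed(self):
        assert wall_tension(5.0, 9.5, 0.01) < 0


class TestTensionForms:
    def test_zero_activation_is_passive_only(self):
        prm = make_params()
        assert total_tension(prm.d0, 0.0, prm) == pytest.approx(passive_tension(prm.d0, prm))

    def test_active_peak_at_gaussian_center(self):
        prm = make_params(cact_center=1.2)
        assert active_tension_max(1.2 * prm.d0, prm) == pytest.approx(prm.cact)
        assert active_tension_max(1.0 * prm.d0, prm) < prm.cact

    def test_activation_out_of_bounds_rejected(self):
        with pytest.raises(RegulationError):
            total_tension(0.01, 1.5, make_params())

    def test_calibrated_control_tension_identity(self, params, control_state):
        for cid, prm in params.items():
            anc = control_state.anchors[cid]
            assert total_tension(anc["dc"], anc["ac"], prm) == pytest.approx(
                anc["tc"], rel=1e-12
            ), cid


class TestToneStimulus:
    def test_zero_inputs_zero_offset(self):
        prm = make_params(ctone=0.0)
        assert tone_stimulus(0.0, 0.0, 0.0, prm) == 0.0

    def test_monotone_in_tension(self):
        prm = make_params()
        assert tone_stimulus(200.0, 10.0, 0.1, prm) > tone_stimulus(100.0, 10.0, 0.1, prm)

    def test_shear_uses_magnitude(self):
        prm = make_params()
        assert tone_stimulus(100.0, -10.0, 0.0, prm) == tone_stimulus(100.0, 10.0, 0.0, prm)

    def test_la_class_ignores_metabolic_signal_with_warning(self):
        prm = make_params(tone_class="LA")
        with pytest.warns(UserWarning, match="ignored"):
            s = tone_stimulus(100.0, 10.0, 5.0, prm)
        assert s == tone_stimulus(100.0, 10.0, 0.0, make_params(tone_class="SA", cmeta=0.0))


class TestActivation:
    def test_logistic_values(self):
        assert total_activation(0.0) == pytest.approx(0.5)
        assert total_activation(math.log(99)) == pytest.approx(0.99)

    def test_saturating_limits(self):
        assert total_activation(-800.0) == pytest.approx(0.0)
        assert total_activation(800.0) == pytest.approx(1.0)

    @given(st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_strictly_inside_unit_interval(self, s):
        # strict bounds hold wherever float64 can resolve them
        a = total_activation(s)
        assert 0.0 < a < 1.0


class TestCalibration:
    def test_tone_offset_puts_control_on_logit(self, params, control_inputs):
        for cid, prm in params.items():
            s = tone_stimulus(
                wall_tension(control_inputs["midpoints"][cid], 9.5, prm.dc),
                control_inputs["shear"][cid],
                control_inputs["smeta"].get(cid, 0.0),
                prm,
            )
            expected = 0.0 if prm.ac == 0.5 else math.log(prm.ac / (1 - prm.ac))
            assert s == pytest.approx(expected, abs=1e-9), cid

    def test_collateral_control_stimulus_matches_logit_99(self, params, control_inputs):
        prm = params["COLam_l"]
        s = tone_stimulus(
            wall_tension(control_inputs["midpoints"]["COLam_l"], 9.5, prm.dc),
            control_inputs["shear"]["COLam_l"],
            control_inputs["smeta"]["COLam_l"],
            prm,
        )
        assert s == pytest.approx(math.log(99), abs=1e-9)

    def test_infeasible_shape_rejected(self, control_state):
        bad = RegulationShape(passive_fraction=1.5)
        with pytest.raises(RegulationError):
            calibrate_tension_and_tone(
                control_state.anchors, control_state.control_shear,
                control_state.control_smeta, bad,
            )

    def test_diameter_prefactor_identity(self, params):
        # Dc/Tc and 2/(Pc - Pic) are the same prefactor when
        # Tc = (Pc - Pic) Dc / 2; verified symbolically and per compartment
        import sympy

        dc, pc, pic = sympy.symbols("dc pc pic", positive=True)
        tc = (pc - pic) * dc / 2
        assert sympy.simplify(dc / tc - 2 / (pc - pic)) == 0
        for cid, prm in params.items():
            lhs = prm.dc / prm.tc
            rhs = 2.0 / ((prm.pc - 9.5) * MMHG_TO_DYN_CM2)
            assert lhs == pytest.approx(rhs, rel=1e-12), cid


class TestRegulationRhs:
    def make_state(self, params):
        return RegulationState(
            diameters={cid: p.dc for cid, p in params.items()},
            activations={cid: p.ac for cid, p in params.items()},
        )

    def test_control_state_is_equilibrium(self, params, control_inputs):
        state = self.make_state(params)
        d_dot, a_dot = regulation_rhs(
            state, control_inputs["midpoints"], control_inputs["shear"],
            control_inputs["smeta"], params,
        )
        for cid in params:
            assert abs(d_dot[cid]) < 1e-9 * params[cid].dc, cid
            assert abs(a_dot[cid]) < 1e-9, cid

    def test_activation_above_target_relaxes_down(self, params, control_inputs):
        state = self.make_state(params)
        state.activations["SA_ml"] = min(0.999, params["SA_ml"].ac + 0.2)
        _, a_dot = regulation_rhs(
            state, control_inputs["midpoints"], control_inputs["shear"],
            control_inputs["smeta"], params,
        )
        assert a_dot["SA_ml"] < 0

    def test_pressure_step_dilates_before_tone_responds(self, params, control_inputs):
        state = self.make_state(params)
        bumped = {k: v + 10.0 for k, v in control_inputs["midpoints"].items()}
        d_dot, _ = regulation_rhs(
            state, bumped, control_inputs["shear"], control_inputs["smeta"], params
        )
        assert d_dot["SA_ml"] > 0
        assert d_dot["LA_ml"] > 0

    def test_perturbed_diameter_is_not_equilibrium(self, params, control_inputs):
        state = self.make_state(params)
        state.diameters["SA_ml"] *= 1.01
        d_dot, _ = regulation_rhs(
            state, control_inputs["midpoints"], control_inputs["shear"],
            control_inputs["smeta"], params,
        )
        assert abs(d_dot["SA_ml"]) > 1e-6 * params["SA_ml"].dc

    def test_missing_anchor_rejected(self, params, control_inputs):
        state = self.make_state(params)
        del state.diameters["SA_ml"]
        with pytest.raises(RegulationError):
            regulation_rhs(
                state, control_inputs["midpoints"], control_inputs["shear"],
                control_inputs["smeta"], params,
            )
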