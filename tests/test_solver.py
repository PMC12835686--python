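"""Pressure solves: the steady resistive oracle against the tabulated control
pressures, the pulsatile DAE, period averaging, flows and shear."""

import numpy as np
import pytest

from cerebroflow.network import NetworkTopology, VesselCompartment, Edge, build_network
from cerebroflow.solver import (
    PressureSeries,
    SolverError,
    assemble_pressure_system,
    compartment_flows,
    oscillation_amplitude,
    period_average,
    resistive_steady_solve,
    solve_pressure_interval,
)
from cerebroflow.units import MMHG_TO_DYN_CM2

MIDDLE_CHAIN = ["P1,ml", "P2,ml", "P3,ml", "P4,ml", "P5,ml", "P6"]


@pytest.fixture(scope="module")
def control_pressures(network):
    return resistive_steady_solve(network, 99.2)


@pytest.fixture(scope="module")
def control_series(network, control_waveform):
    system = assemble_pressure_system(network, control_waveform)
    return solve_pressure_interval(system, (0.0, 2.0))


def two_resistor_chain(r1=1000.0, r2=1000.0):
    comps = {
        "X1": VesselCompartment("X1", "CAP", "shared", "none", 0.1, 1.0, 1, r1),
        "X2": VesselCompartment("X2", "CAP", "shared", "none", 0.1, 1.0, 1, r2),
    }
    edges = (Edge("Pa", "M", "X1"), Edge("M", "PV", "X2"))
    return NetworkTopology(compartments=comps, edges=edges, capacitor_nodes={})


class TestResistiveSolve:
    def test_voltage_divider_midpoint(self):
        p = resistive_steady_solve(two_resistor_chain(), 100.0, 0.0)
        assert p["M"] == pytest.approx(50.0)

    @pytest.mark.parametrize(
        "node,expected",
        [("P2,ml", 74.7), ("P2,mr", 74.7), ("P3,ml", 44.7), ("P4,ml", 16.0), ("P6", 13.7)],
    )
    def test_reproduces_tabulated_control_pressures(self, control_pressures, node, expected):
        assert control_pressures[node] == pytest.approx(expected, abs=0.1)

    def test_pressures_decrease_downstream(self, control_pressures):
        chain = ["Pa"] + MIDDLE_CHAIN + ["P6,mid", "P7", "P7,mid", "PV"]
        values = [control_pressures[n] for n in chain]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_junction_current_conservation(self, network, control_pressures):
        total_in = (99.2 - control_pressures["PICA,l1"]) * MMHG_TO_DYN_CM2 / (758 / 2)
        for node in network.junction_nodes:
            net = sum(
                (control_pressures[e.u if e.v == node else e.v] - control_pressures[node])
                * MMHG_TO_DYN_CM2
                / (network.compartments[e.compartment].resistance * e.fraction)
                for e in network.edges
                if node in (e.u, e.v)
            )
            assert abs(net) < 1e-8 * total_in


class TestPulsatileSystem:
    def test_control_network_has_18_differential_states(self, network, control_waveform):
        system = assemble_pressure_system(network, control_waveform)
        assert len(system.diff_nodes) == 18
        assert len(system.junction_nodes) == 39

    def test_occluded_network_has_17_differential_states(self, occluded_network, control_waveform):
        system = assemble_pressure_system(occluded_network, control_waveform)
        assert len(system.diff_nodes) == 17
        assert "PMCA,l" not in system.diff_nodes
        assert "P1,ml" not in system.junction_nodes

    def test_period_averages_match_resistive_oracle(self, control_series, control_pressures, network):
        avg = period_average(control_series)
        ref = resistive_steady_solve(network, control_series.pressures["Pa"].mean() * 0 + 99.2)
        for node in network.nodes:
            assert avg[node] == pytest.approx(control_pressures[node], abs=0.2), node

    def test_pressures_bounded_by_boundary_extremes(self, control_series):
        for node, p in control_series.pressures.items():
            assert np.all(p >= 9.5 - 1e-6), node
            assert np.all(p <= 121.0 + 1e-6), node

    def test_periodic_steady_state(self, control_series):
        # skip the first RC-transient milliseconds after the initial condition
        t = control_series.t
        late = t >= 1.05
        for node, p in control_series.pressures.items():
            shifted = np.interp(t[late] - 1.0, t, p)
            assert np.max(np.abs(p[late] - shifted)) < 0.05, node

    def test_vanishing_capacitance_limit_is_resistive(self, network, control_waveform):
        import copy
        import dataclasses

        comps = {
            cid: (
                dataclasses.replace(c, capacitance=c.capacitance * 1e-6)
                if c.capacitance
                else c
            )
            for cid, c in network.compartments.items()
        }
        tiny = dataclasses.replace(network, compartments=comps)
        system = assemble_pressure_system(tiny, control_waveform)
        series = solve_pressure_interval(system, (0.0, 2.0))
        # with negligible storage, the instantaneous solution tracks the
        # instantaneous resistive solve
        t_probe = series.t[-50]
        inst = resistive_steady_solve(network, float(control_waveform(t_probe)))
        i = np.argmin(np.abs(series.t - t_probe))
        for node in ("P1,ml", "P3,ml", "PMCA,l", "P6"):
            assert series.pressures[node][i] == pytest.approx(inst[node], abs=0.05)

    def test_insensitive_to_initial_condition_offset(self, network, control_waveform):
        system = assemble_pressure_system(network, control_waveform)
        base = solve_pressure_interval(system, (0.0, 2.0))
        from cerebroflow.solver import _default_initial

        shifted = {k: v + 5.0 for k, v in _default_initial(system).items()}
        off = solve_pressure_interval(system, (0.0, 2.0), initial=shifted)
        a0, a1 = period_average(base), period_average(off)
        for node in system.diff_nodes:
            assert a0[node] == pytest.approx(a1[node], abs=0.1)


class TestPeriodAverage:
    def test_constant_series(self):
        t = np.linspace(0, 2, 401)
        series = PressureSeries(t=t, pressures={"X": np.full_like(t, 7.5)}, period=1.0)
        assert period_average(series)["X"] == pytest.approx(7.5)

    def test_sinusoid_over_integer_periods(self):
        t = np.linspace(0, 2, 2001)
        series = PressureSeries(
            t=t, pressures={"X": 3.0 + 2.0 * np.sin(2 * np.pi * t)}, period=1.0
        )
        assert period_average(series)["X"] == pytest.approx(3.0, abs=1e-5)

    def test_short_series_rejected(self):
        t = np.linspace(0, 0.5, 51)
        series = PressureSeries(t=t, pressures={"X": np.ones_like(t)}, period=1.0)
        with pytest.raises(SolverError):
            period_average(series)


class TestFlows:
    def test_total_venous_flow_in_physiological_range(self, network, control_pressures):
        flows = compartment_flows(control_pressures, network)
        assert 11.0 <= flows.compartment_flows["V"] <= 13.0

    def test_small_arteriole_shear_near_tabulated_state(self, network, control_pressures):
        flows = compartment_flows(control_pressures, network)
        assert flows.shear["SA_ml"] == pytest.approx(54.0, abs=2.0)

    def test_vessel_flow_times_number_is_compartment_flow(self, network, control_pressures):
        flows = compartment_flows(control_pressures, network)
        for cid, q in flows.compartment_flows.items():
            n = network.compartments[cid].number
            assert flows.vessel_flows[cid] * n == pytest.approx(q, rel=1e-12)

    def test_zero_pressure_drop_gives_zero_flow(self, network):
        uniform = {n: 50.0 for n in network.nodes}
        flows = compartment_flows(uniform, network)
        assert all(q == 0.0 for q in flows.compartment_flows.values())


class TestComplianceEffects:
    def test_higher_distensibility_damps_all_microcirculation_nodes(
        self, control_series, control_waveform
    ):
        soft = build_network(distensibility_scale=1000.0)
        system = assemble_pressure_system(soft, control_waveform)
        series = solve_pressure_interval(system, (0.0, 2.0))
        a0 = oscillation_amplitude(control_series)
        a1 = oscillation_amplitude(series)
        for node in MIDDLE_CHAIN:
            assert a1[node] < a0[node], node

    def test_amplitude_attenuates_downstream(self, control_series):
        amp = oscillation_amplitude(control_series)
        chain = ["Pa"] + MIDDLE_CHAIN
        values = [amp[n] for n in chain]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
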