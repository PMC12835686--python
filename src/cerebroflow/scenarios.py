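"""Scenario orchestration: the two-timescale simulation algorithm.

Diameters and activations evolve on a slow timescale (seconds to minutes);
the nodal pressures respond on the cardiac timescale.  At every outer step
the resistances of the vasoactive compartments are rebuilt from the current
diameters, the pressure system is solved and period-averaged, and the
averaged pressures, flows and conducted metabolic signals drive the
diameter/activation derivatives.

For fixed resistances the pressure network is linear and time-invariant, so
its period-averaged solution equals the steady resistive solve at the
waveform mean; the default ``resistive`` inner mode uses that identity
(tested against the full DAE), while ``pulsatile`` integrates the DAE over a
short window and averages the final period.  Pulsatile quantities
(oscillation amplitudes, time dynamics) are always computed from a full DAE
solve at the final state.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .calibration import (
    ControlState,
    calibrated_regulation,
    control_midpoint_pressures,
    run_control_calibration,
    solve_average_pressures,
)
from .network import NetworkTopology, apply_occlusion, build_network
from .oxygen import OxygenParams, metabolic_signal, regional_saturations
from .regulation import RegulationShape, RegulationState, regulation_rhs
from .solver import (
    assemble_pressure_system,
    compartment_flows,
    oscillation_amplitude,
    period_average,
    solve_pressure_interval,
)
from .waveform import build_control_waveform, rescale_waveform

CONTROL_MAP = 95.67  # mmHg, clinical MAP of the control waveform


class ScenarioConfig(BaseModel):
    """Configuration of one simulation scenario; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    map_target: float = Field(default=CONTROL_MAP, gt=0)
    occlude_mca_left: bool = False
    distensibility_scale: float = Field(default=1.0, gt=0)
    m0: float = Field(default=12.0, ge=0)  # cm^3 O2/100 cm^3/min
    outer_duration: float = Field(default=200.0, gt=0)  # s
    outer_step: float = Field(default=0.25, gt=0)  # s
    inner_window: float = Field(default=2.0, gt=0)  # s
    inner_mode: Literal["resistive", "pulsatile"] = "resistive"
    record_every: int = Field(default=1, ge=1)
    waveform_period: float = Field(default=1.0, gt=0)  # s

    @model_validator(mode="after")
    def _check_windows(self):
        if self.inner_window < 2 * self.waveform_period:
            raise ValueError("inner_window must cover at least two waveform periods")
        if self.outer_step > self.outer_duration:
            raise ValueError("outer_step must not exceed outer_duration")
        return self


@dataclass
class SimulationResult:
    """Outer-time trajectories plus final pulsatile diagnostics."""

    config: dict
    t: np.ndarray
    diameters: dict[str, np.ndarray]
    activations: dict[str, np.ndarray]
    regional_flows: dict[str, np.ndarray]  # region+side -> cm^3/s
    smeta: dict[str, np.ndarray]
    terminal_saturations: dict[str, np.ndarray]  # region+side -> venous S
    nodal_pressures: dict[str, np.ndarray]  # period-averaged, all nodes
    final_amplitudes: dict[str, float]  # peak-to-trough, final DAE solve
    final_wave_averages: dict[str, float]  # period means of the final DAE solve
    final_wave_series: object | None = None  # PressureSeries if retained
    runtime_s: float = 0.0
    solver_stats: dict = field(default_factory=dict)

    def summary(self) -> dict:
        last = -1
        return {
            "config": self.config,
            "final_time_s": float(self.t[last]),
            "final_diameters_cm": {k: float(v[last]) for k, v in self.diameters.items()},
            "final_activations": {k: float(v[last]) for k, v in self.activations.items()},
            "final_regional_flows_cm3_s": {
                k: float(v[last]) for k, v in self.regional_flows.items()
            },
            "final_terminal_saturations": {
                k: float(v[last]) for k, v in self.terminal_saturations.items()
            },
            "final_smeta": {k: float(v[last]) for k, v in self.smeta.items()},
            "final_nodal_pressures_mmHg": {
                k: float(v[last]) for k, v in self.nodal_pressures.items()
            },
            "final_oscillation_amplitudes_mmHg": dict(self.final_amplitudes),
            "solver_stats": self.solver_stats,
        }


class _StepEval:
    """All quantities the regulation right-hand side needs at one state."""

    __slots__ = ("pressures", "flows", "midpoints", "smeta", "profiles", "resistances")

    def __init__(self, pressures, flows, midpoints, smeta, profiles, resistances):
        self.pressures = pressures
        self.flows = flows
        self.midpoints = midpoints
        self.smeta = smeta
        self.profiles = profiles
        self.resistances = resistances


def _prepare(config: ScenarioConfig, control: ControlState | None, shape: RegulationShape | None):
    base = build_network()
    if control is None:
        control = run_control_calibration(base, mode="resistive")
    params = calibrated_regulation(control, shape)
    network = build_network(distensibility_scale=config.distensibility_scale)
    if config.occlude_mca_left:
        network = apply_occlusion(network, "MCA_l")
    control_wave = build_control_waveform(period=config.waveform_period)
    waveform, _ = rescale_waveform(control_wave, config.map_target)
    oxy = OxygenParams(m0=config.m0)
    tracked = network.vasoactive_compartments()
    params = {cid: params[cid] for cid in tracked}
    return network, control, params, waveform, oxy, tracked


def _evaluate(network, waveform, control, oxy, state, config) -> _StepEval:
    res = {
        cid: network.compartments[cid].scaled_resistance(diameter=d)
        for cid, d in state.diameters.items()
    }
    pressures = solve_average_pressures(
        network, waveform, res, mode=config.inner_mode, inner_window=config.inner_window
    )
    flows = compartment_flows(pressures, network, resistances=res, diameters=state.diameters)
    midpoints = control_midpoint_pressures(network, pressures)
    regional = {
        key: flows.compartment_flows[f"SA_{key}"] for key in control.regional_flows
    }
    profiles = regional_saturations(network, flows, oxy, control.regional_flows)
    smeta = metabolic_signal(profiles, network, oxy)
    return _StepEval(pressures, flows, midpoints, smeta, profiles, res), regional


def run_simulation(
    config: ScenarioConfig,
    control: ControlState | None = None,
    shape: RegulationShape | None = None,
    keep_final_series: bool = False,
) -> SimulationResult:
    """Integrate the slow diameter/activation system under one scenario.

    The outer loop uses Heun's method; each stage re-solves the pressure
    system at the current resistances.  Occlusion, the MAP target and the
    distensibility scale are applied before t = 0.
    """
    t0 = time.perf_counter()
    network, control, params, waveform, oxy, tracked = _prepare(config, control, shape)
    pic = network.intracranial_pressure

    state = RegulationState(
        diameters={cid: control.anchors[cid]["dc"] for cid in tracked},
        activations={cid: control.anchors[cid]["ac"] for cid in tracked},
    )

    def rhs(st: RegulationState):
        ev, regional = _evaluate(network, waveform, control, oxy, st, config)
        shear = {cid: ev.flows.shear[cid] for cid in tracked}
        d_dot, a_dot = regulation_rhs(st, ev.midpoints, shear, ev.smeta, params, pic)
        return d_dot, a_dot, ev, regional

    def advance(st: RegulationState, d_dot, a_dot, dt) -> RegulationState:
        nd = {cid: max(st.diameters[cid] + dt * d_dot[cid], 1e-6) for cid in tracked}
        na = {cid: float(np.clip(st.activations[cid] + dt * a_dot[cid], 0.0, 1.0)) for cid in tracked}
        return RegulationState(nd, na)

    n_steps = int(round(config.outer_duration / config.outer_step))
    rec_t, rec_d, rec_a, rec_q, rec_s, rec_sat, rec_p = [], [], [], [], [], [], []

    def record(t, st, ev, regional):
        rec_t.append(t)
        rec_d.append(dict(st.diameters))
        rec_a.append(dict(st.activations))
        rec_q.append(dict(regional))
        rec_s.append(dict(ev.smeta))
        rec_sat.append({k: prof.saturations[-1] for k, prof in ev.profiles.items()})
        rec_p.append({k: float(v) for k, v in ev.pressures.items()})

    d_dot, a_dot, ev, regional = rhs(state)
    record(0.0, state, ev, regional)
    for i in range(n_steps):
        dt = config.outer_step
        predictor = advance(state, d_dot, a_dot, dt)
        d_dot2, a_dot2, ev2, regional2 = rhs(predictor)
        state = advance(
            state,
            {c: 0.5 * (d_dot[c] + d_dot2[c]) for c in tracked},
            {c: 0.5 * (a_dot[c] + a_dot2[c]) for c in tracked},
            dt,
        )
        state.validate()
        d_dot, a_dot, ev, regional = rhs(state)
        if (i + 1) % config.record_every == 0 or i == n_steps - 1:
            record((i + 1) * dt, state, ev, regional)

    # final pulsatile diagnostics at the converged resistances
    system = assemble_pressure_system(network, waveform, resistances=ev.resistances)
    series = solve_pressure_interval(system, (0.0, config.inner_window))
    amplitudes = oscillation_amplitude(series)
    wave_avg = period_average(series)

    def stack(records: list[dict]) -> dict[str, np.ndarray]:
        return {k: np.array([r[k] for r in records]) for k in records[0]}

    return SimulationResult(
        config=config.model_dump(),
        t=np.array(rec_t),
        diameters=stack(rec_d),
        activations=stack(rec_a),
        regional_flows=stack(rec_q),
        smeta=stack(rec_s),
        terminal_saturations=stack(rec_sat),
        nodal_pressures=stack(rec_p),
        final_amplitudes=amplitudes,
        final_wave_averages=wave_avg,
        final_wave_series=series if keep_final_series else None,
        runtime_s=time.perf_counter() - t0,
        solver_stats={
            "outer_steps": n_steps,
            "inner_mode": config.inner_mode,
            "control_iterations": control.iterations,
        },
    )


def autoregulation_sweep(
    map_values,
    occlude: bool = False,
    config: ScenarioConfig | None = None,
    control: ControlState | None = None,
    shape: RegulationShape | None = None,
) -> dict:
    """Steady regional flows versus MAP, as percentages of control flow.

    Each MAP point runs the scenario to its regulation steady state; per-point
    failures are recorded (NaN) and the sweep continues.  Flows are for the
    left-side middle/anterior/posterior regions, normalized by the
    control-state regional flows.
    """
    base = config or ScenarioConfig()
    if control is None:
        control = run_control_calibration(build_network(), mode="resistive")
    curves = {"map": [], "middle": [], "anterior": [], "posterior": []}
    errors: dict[float, str] = {}
    for m in map_values:
        cfg = base.model_copy(update={"map_target": float(m), "occlude_mca_left": occlude})
        try:
            res = run_simulation(cfg, control=control, shape=shape)
            curves["map"].append(float(m))
            for region, key in (("middle", "ml"), ("anterior", "al"), ("posterior", "pl")):
                pct = 100.0 * res.regional_flows[key][-1] / control.regional_flows[key]
                curves[region].append(float(pct))
        except Exception as err:  # pragma: no cover - per-point robustness
            curves["map"].append(float(m))
            for region in ("middle", "anterior", "posterior"):
                curves[region].append(float("nan"))
            errors[float(m)] = str(err)
    curves["errors"] = errors
    curves["occluded"] = occlude
    return curves


def write_results(result: SimulationResult, out_dir) -> dict[str, Path]:
    """Write summary JSON, long-format CSV time series, and a run log."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": out / "summary.json",
        "timeseries": out / "timeseries.csv",
        "log": out / "run.log",
    }
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary(), fh, indent=1, sort_keys=True)

    rows = []
    quantities = {
        "diameter_cm": result.diameters,
        "activation": result.activations,
        "flow_cm3_s": result.regional_flows,
        "smeta": result.smeta,
        "saturation": result.terminal_saturations,
        "pressure_mmHg": result.nodal_pressures,
    }
    for qty, series in quantities.items():
        for key, values in series.items():
            for t, v in zip(result.t, values):
                rows.append((float(t), key, qty, float(v)))
    pd.DataFrame(rows, columns=["time_s", "node_or_compartment", "quantity", "value"]).to_csv(
        paths["timeseries"], index=False
    )

    with open(paths["log"], "w") as fh:
        fh.write("scenario configuration:\n")
        fh.write(json.dumps(result.config, indent=1, sort_keys=True))
        fh.write(f"\nruntime_s: {result.runtime_s:.2f}\n")
        fh.write(f"solver: {json.dumps(result.solver_stats, sort_keys=True)}\n")
    return paths
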