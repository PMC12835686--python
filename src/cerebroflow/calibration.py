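"""Control (reference) state of the network.

The control state fixes everything the regulation model is anchored to: the
period-averaged nodal pressures, the vessel numbers of the microcirculation
compartments, the control midpoint pressures/tensions of the vasoactive
compartments (at fixed activation 0.5 for arterioles, 0.99 for collaterals),
the control shear stresses and conducted metabolic signals.

Vessel numbers are found by the iterative procedure: given the current
arteriole diameters, set venule diameters by fixed diameter-ratio symmetry,
update microcirculation resistances (Poiseuille scaling of the control
table), solve the pressure system and period-average, compute compartment
flows by Ohm's law and per-vessel flows from the target shear stresses
(q = pi tau D^3 / (32 mu)), and set number = compartment flow / vessel flow;
repeat until the numbers converge.  Target shears default to the values the
control table itself implies, which makes the tabulated table an exact fixed
point of the procedure.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping

from .network import (
    MICRO_REGIONS,
    SIDES,
    NetworkTopology,
    compartment_capacitance,
)
from .oxygen import OxygenParams, metabolic_signal, regional_saturations
from .regulation import (
    CompartmentRegulation,
    RegulationShape,
    calibrate_tension_and_tone,
    wall_tension,
)
from .solver import (
    FlowSolution,
    assemble_pressure_system,
    compartment_flows,
    period_average,
    resistive_steady_solve,
    solve_pressure_interval,
)
from .waveform import PressureWaveform, build_control_waveform

MICRO_CLASSES = ("LA", "SA", "CAP", "SV", "LV")
CONTROL_ACTIVATION = {"LA": 0.5, "SA": 0.5, "COLam": 0.99, "COLpm": 0.99}


class CalibrationError(RuntimeError):
    """Raised when the control-state iteration cannot complete."""


def control_midpoint_pressures(
    network: NetworkTopology, averaged_pressures: Mapping[str, float]
) -> dict[str, float]:
    """Control pressure of each tracked vasoactive compartment.

    The midpoint of the averaged pressures at the compartment's endpoints:
    (P1+P2)/2 for large arterioles, (P2+P3)/2 for small arterioles, and the
    mean of the two flanking P2 nodes for the collaterals.
    """
    out: dict[str, float] = {}
    for cid in network.vasoactive_compartments():
        u, v = network.compartment_endpoints(cid)
        try:
            out[cid] = 0.5 * (averaged_pressures[u] + averaged_pressures[v])
        except KeyError as err:
            raise CalibrationError(f"missing node {err} for compartment {cid}")
    return out


def _micro_ids(network: NetworkTopology) -> list[str]:
    out = []
    for cls in MICRO_CLASSES:
        for k in MICRO_REGIONS:
            for j in SIDES:
                cid = f"{cls}_{k}{j}"
                if cid in network.compartments and cid not in (
                    network.occluded | network.untracked
                ):
                    out.append(cid)
    return out


@dataclass
class ControlState:
    """Converged control state: anchors, numbers, pressures, flows, signals."""

    nodal_pressures: dict[str, float]
    vessel_numbers: dict[str, float]
    anchors: dict[str, dict]  # cid -> {dc, tc, pc, ac, vessel_class}
    control_shear: dict[str, float]  # signed, dyn/cm^2 (per vessel)
    control_smeta: dict[str, float]
    regional_flows: dict[str, float]  # region+side -> cm^3/s (SA compartment)
    venule_ratios: dict[str, float]  # SV/SA and LV/LA diameter ratios
    capacitances: dict[str, float]  # recomputed distensibility x volume
    target_shear: dict[str, float]
    iterations: int
    converged: bool
    mode: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ControlState":
        with open(path) as fh:
            return cls(**json.load(fh))

    def diff_table(self, network: NetworkTopology) -> str:
        """Human-readable per-field deviation from the shipped vessel table."""
        lines = ["compartment  field      table        converged    rel_dev"]
        for cid, n in sorted(self.vessel_numbers.items()):
            n0 = network.compartments[cid].number
            lines.append(
                f"{cid:12s} number  {n0:12.5g} {n:12.5g} {abs(n - n0) / n0:10.2e}"
            )
        for cid, c in sorted(self.capacitances.items()):
            c0 = network.compartments[cid].capacitance
            lines.append(
                f"{cid:12s} capac.  {c0:12.5g} {c:12.5g} {abs(c - c0) / c0:10.2e}"
            )
        return "\n".join(lines)


def _venule_ratios(network: NetworkTopology) -> dict[str, float]:
    # control SV/SA and LV/LA diameter ratios (middle region is representative;
    # ratios are identical on both sides by symmetry)
    sv = network.compartments["SV_ml"].diameter / network.compartments["SA_ml"].diameter
    lv = network.compartments["LV_ml"].diameter / network.compartments["LA_ml"].diameter
    return {"SV_over_SA": sv, "LV_over_LA": lv}


def micro_resistances(
    network: NetworkTopology,
    numbers: Mapping[str, float] | None = None,
    diameters: Mapping[str, float] | None = None,
    ratios: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Microcirculation resistances at given vessel numbers and arteriole
    diameters, with venule diameters following the symmetry ratios."""
    ratios = ratios or _venule_ratios(network)
    res: dict[str, float] = {}
    for cid in _micro_ids(network):
        comp = network.compartments[cid]
        cls = comp.vessel_class
        n = numbers[cid] if numbers and cid in numbers else comp.number
        d = None
        if diameters:
            k_j = cid.split("_")[1]
            if cls in ("LA", "SA") and cid in diameters:
                d = diameters[cid]
            elif cls == "SV" and f"SA_{k_j}" in diameters:
                d = ratios["SV_over_SA"] * diameters[f"SA_{k_j}"]
            elif cls == "LV" and f"LA_{k_j}" in diameters:
                d = ratios["LV_over_LA"] * diameters[f"LA_{k_j}"]
        res[cid] = comp.scaled_resistance(diameter=d, number=n)
    return res


def solve_average_pressures(
    network: NetworkTopology,
    waveform: PressureWaveform,
    resistances: Mapping[str, float] | None,
    mode: str = "resistive",
    inner_window: float = 2.0,
) -> dict[str, float]:
    """Period-averaged nodal pressures for the given resistances.

    ``resistive`` exploits that capacitor currents average to zero over a
    period: the averages solve the steady Kirchhoff system at the waveform
    mean.  ``pulsatile`` integrates the full pressure DAE over
    ``inner_window`` seconds and averages the final period.
    """
    if mode == "resistive":
        return resistive_steady_solve(network, waveform.time_average, resistances=resistances)
    if mode == "pulsatile":
        system = assemble_pressure_system(network, waveform, resistances=resistances)
        series = solve_pressure_interval(system, (0.0, inner_window))
        return period_average(series)
    raise CalibrationError(f"unknown pressure mode {mode!r}")


def run_control_calibration(
    network: NetworkTopology,
    waveform: PressureWaveform | None = None,
    *,
    mode: str = "resistive",
    tol: float = 1e-6,
    max_iter: int = 100,
    target_shear: Mapping[str, float] | None = None,
    initial_numbers: Mapping[str, float] | None = None,
    diameters: Mapping[str, float] | None = None,
    oxygen_params: OxygenParams | None = None,
) -> ControlState:
    """Run the control-state iteration and assemble the anchors."""
    waveform = waveform or build_control_waveform()
    oxygen_params = oxygen_params or OxygenParams()
    ratios = _venule_ratios(network)
    micro = _micro_ids(network)
    mu = next(iter(network.compartments.values())).viscosity

    def averaged(numbers):
        res = micro_resistances(network, numbers, diameters, ratios)
        return solve_average_pressures(network, waveform, res, mode=mode), res

    numbers = {cid: network.compartments[cid].number for cid in micro}
    if initial_numbers:
        numbers.update(initial_numbers)

    if target_shear is None:
        # back-computed so the shipped table is the procedure's fixed point
        table_numbers = {cid: network.compartments[cid].number for cid in micro}
        pressures, res = averaged(table_numbers)
        flows = compartment_flows(pressures, network, resistances=res)
        target_shear = {cid: abs(flows.shear[cid]) for cid in micro}

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        pressures, res = averaged(numbers)
        flows = compartment_flows(pressures, network, resistances=res)
        new_numbers = {}
        max_rel = 0.0
        for cid in micro:
            comp = network.compartments[cid]
            d = comp.diameter  # control diameters during number iteration
            q_vessel = math.pi * target_shear[cid] * d**3 / (32.0 * mu)
            if q_vessel <= 0:
                raise CalibrationError(f"{cid}: non-positive target vessel flow")
            n_new = abs(flows.compartment_flows[cid]) / q_vessel
            if not n_new > 0:
                raise CalibrationError(f"{cid}: vessel number update is non-positive")
            max_rel = max(max_rel, abs(n_new - numbers[cid]) / numbers[cid])
            new_numbers[cid] = n_new
        numbers = new_numbers
        if max_rel < tol:
            converged = True
            break
    if not converged:
        raise CalibrationError(f"vessel numbers did not converge in {max_iter} iterations")

    pressures, res = averaged(numbers)
    flows = compartment_flows(pressures, network, resistances=res)
    midpoints = control_midpoint_pressures(network, pressures)
    pic = network.intracranial_pressure

    anchors: dict[str, dict] = {}
    for cid in network.vasoactive_compartments():
        comp = network.compartments[cid]
        ac = CONTROL_ACTIVATION[comp.vessel_class]
        pc = midpoints[cid]
        anchors[cid] = {
            "dc": comp.diameter,
            "tc": wall_tension(pc, pic, comp.diameter),
            "pc": pc,
            "ac": ac,
            "vessel_class": comp.vessel_class,
        }

    regional = {
        f"{k}{j}": flows.compartment_flows[f"SA_{k}{j}"]
        for k in MICRO_REGIONS
        for j in SIDES
    }
    profiles = regional_saturations(network, flows, oxygen_params, regional)
    smeta = metabolic_signal(profiles, network, oxygen_params)

    capac = {
        cid: compartment_capacitance(c.diameter, c.length, c.distensibility)
        for cid, c in network.compartments.items()
        if c.has_capacitor
    }
    shear = {cid: flows.shear[cid] for cid in network.vasoactive_compartments()}
    return ControlState(
        nodal_pressures={k: float(v) for k, v in pressures.items()},
        vessel_numbers=numbers,
        anchors=anchors,
        control_shear=shear,
        control_smeta={cid: smeta.get(cid, 0.0) for cid in network.vasoactive_compartments()},
        regional_flows=regional,
        venule_ratios=ratios,
        capacitances=capac,
        target_shear=dict(target_shear),
        iterations=iterations,
        converged=converged,
        mode=mode,
    )


def calibrated_regulation(
    control: ControlState, shape: RegulationShape | None = None
) -> dict[str, CompartmentRegulation]:
    """Tension/tone parameters anchored to a converged control state."""
    return calibrate_tension_and_tone(
        control.anchors, control.control_shear, control.control_smeta, shape
    )
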