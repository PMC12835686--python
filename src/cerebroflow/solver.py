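"""Pressure solver for the resistor-capacitor vascular network.

At each capacitor node k, conservation of volume gives
``C_k d(P_k - Pic)/dt = inflow - outflow`` (Pic constant); at every junction
node Kirchhoff's current law gives an algebraic balance.  With fixed
resistances this is a linear index-1 DAE.  Junction pressures are eliminated
by a Schur complement on the resistive subgraph, reducing the system to an
explicit linear ODE in the capacitor-node pressures which is integrated with
a stiff solver (the RC time constants are ~1e-4 - 1e-3 s, far below the
cardiac period).

Pressures are carried in mmHg; conductances and capacitances absorb the
mmHg <-> dyn/cm^2 conversion so that flows come out in cm^3/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkTopology
from .units import MMHG_TO_DYN_CM2
from .waveform import PressureWaveform


class SolverError(RuntimeError):
    """Raised when the linear solve or time integration fails."""


def _edge_conductances(
    network: NetworkTopology, resistances: Mapping[str, float] | None
) -> list[tuple[str, str, float]]:
    """Per-edge conductance in cm^3/(s mmHg)."""
    out = []
    for e in network.edges:
        r_total = (
            resistances[e.compartment]
            if resistances is not None and e.compartment in resistances
            else network.compartments[e.compartment].resistance
        )
        r = r_total * e.fraction
        if not r > 0:
            raise SolverError(f"non-positive resistance on edge {e.u}->{e.v} ({e.compartment})")
        out.append((e.u, e.v, MMHG_TO_DYN_CM2 / r))
    return out


def _laplacian(network, resistances):
    """Internal-node Laplacian L and boundary coupling B.

    Net current into internal node i is ``-(L p)_i + (B u)_i`` with
    u = (Pa, PV).  Returns (internal node order, L, B).
    """
    internal = list(network.internal_nodes)
    index = {n: i for i, n in enumerate(internal)}
    boundary = {network.inflow_node: 0, network.outflow_node: 1}
    n = len(internal)
    L = np.zeros((n, n))
    B = np.zeros((n, 2))
    for u, v, g in _edge_conductances(network, resistances):
        for a, b in ((u, v), (v, u)):
            if a in index:
                L[index[a], index[a]] += g
                if b in index:
                    L[index[a], index[b]] -= g
                else:
                    B[index[a], boundary[b]] += g
    return internal, L, B


@dataclass
class PressureSystem:
    """Reduced linear ODE for the capacitor-node pressures.

    dp_d/dt = A p_d + F u(t), with junction recovery
    p_j = Rd p_d + Ru u(t);  u = (Pa(t), PV).
    """

    network: NetworkTopology
    boundary: PressureWaveform
    diff_nodes: list[str]
    junction_nodes: list[str]
    A: np.ndarray
    F: np.ndarray
    Rd: np.ndarray
    Ru: np.ndarray

    @property
    def outflow_pressure(self) -> float:
        return self.network.outflow_pressure

    def boundary_vector(self, t) -> np.ndarray:
        pa = np.atleast_1d(np.asarray(self.boundary(t), dtype=float))
        return np.stack([pa, np.full_like(pa, self.outflow_pressure)])

    def rhs(self, t, p_d):
        u = np.array([float(self.boundary(t)), self.outflow_pressure])
        return self.A @ p_d + self.F @ u

    def junction_pressures(self, t, p_d):
        """Recover junction pressures for states p_d (columns = samples)."""
        u = self.boundary_vector(t)
        return self.Rd @ p_d + self.Ru @ u


def assemble_pressure_system(
    network: NetworkTopology,
    boundary: PressureWaveform,
    resistances: Mapping[str, float] | None = None,
) -> PressureSystem:
    """Build the reduced capacitor-pressure ODE for the given resistances."""
    internal, L, B = _laplacian(network, resistances)
    if any(L[i, i] == 0 for i in range(len(internal))):
        bad = [n for i, n in enumerate(internal) if L[i, i] == 0]
        raise SolverError(f"nodes with no incident edges: {bad}")
    diff = [n for n in internal if n in network.capacitor_nodes]
    junc = [n for n in internal if n not in network.capacitor_nodes]
    di = [internal.index(n) for n in diff]
    ji = [internal.index(n) for n in junc]
    Ldd, Ldj = L[np.ix_(di, di)], L[np.ix_(di, ji)]
    Ljd, Ljj = L[np.ix_(ji, di)], L[np.ix_(ji, ji)]
    Bd, Bj = B[di, :], B[ji, :]

    try:
        X = np.linalg.solve(Ljj, np.hstack([Ljd, -Bj]))  # junction elimination
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise SolverError("singular junction system (disconnected network?)") from err
    Rd, Ru = -X[:, : len(di)], -X[:, len(di):]

    cap = np.array(
        [
            network.compartments[network.capacitor_nodes[n]].capacitance * MMHG_TO_DYN_CM2
            for n in diff
        ]
    )  # cm^3 per mmHg
    A = (-(Ldd + Ldj @ Rd)) / cap[:, None]
    F = (Bd - Ldj @ Ru) / cap[:, None]
    return PressureSystem(
        network=network,
        boundary=boundary,
        diff_nodes=diff,
        junction_nodes=junc,
        A=A,
        F=F,
        Rd=Rd,
        Ru=Ru,
    )


@dataclass
class PressureSeries:
    """Dense trajectory of all nodal pressures (mmHg) on a time grid."""

    t: np.ndarray
    pressures: dict[str, np.ndarray]
    period: float

    def last_period_mask(self) -> np.ndarray:
        return self.t >= self.t[-1] - self.period - 1e-12


def resistive_steady_solve(
    network: NetworkTopology,
    inflow_pressure: float,
    outflow_pressure: float | None = None,
    resistances: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Steady Kirchhoff solve with capacitor branches carrying zero current.

    This is the periodic-average oracle: over one period of a periodic steady
    state every capacitor's net current integrates to zero, so averaged nodal
    pressures satisfy the purely resistive network equations with the
    averaged inflow pressure.
    """
    if outflow_pressure is None:
        outflow_pressure = network.outflow_pressure
    internal, L, B = _laplacian(network, resistances)
    u = np.array([inflow_pressure, outflow_pressure])
    try:
        p = np.linalg.solve(L, B @ u)
    except np.linalg.LinAlgError as err:
        raise SolverError("singular resistive system (disconnected network?)") from err
    out = dict(zip(internal, p))
    out[network.inflow_node] = float(inflow_pressure)
    out[network.outflow_node] = float(outflow_pressure)
    return out


def solve_pressure_interval(
    system: PressureSystem,
    t_span: tuple[float, float] = (0.0, 2.0),
    initial: Mapping[str, float] | None = None,
    samples_per_period: int = 200,
    rtol: float = 1e-6,
    atol: float = 1e-4,
) -> PressureSeries:
    """Integrate the pressure DAE and return all nodal pressures.

    By default the initial condition is the resistive steady solution at the
    waveform's time average, which keeps the transient short (the RC time
    constants are milliseconds).
    """
    net = system.network
    if initial is None:
        initial = _default_initial(system)
    p0 = np.array([initial[n] for n in system.diff_nodes], dtype=float)
    if not np.all(np.isfinite(p0)):
        raise SolverError("non-finite initial pressures")
    period = system.boundary.period
    n_periods = (t_span[1] - t_span[0]) / period
    t_eval = np.linspace(
        t_span[0], t_span[1], max(2, int(round(samples_per_period * n_periods)) + 1)
    )
    sol = solve_ivp(
        system.rhs,
        t_span,
        p0,
        method="BDF",
        jac=lambda t, p: system.A,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover
        resid = np.abs(system.rhs(sol.t[-1], sol.y[:, -1]))
        worst = system.diff_nodes[int(np.argmax(resid))]
        raise SolverError(f"pressure integration failed: {sol.message} (max residual at {worst})")

    pressures = {n: sol.y[i] for i, n in enumerate(system.diff_nodes)}
    pj = system.junction_pressures(sol.t, sol.y)
    pressures.update({n: pj[i] for i, n in enumerate(system.junction_nodes)})
    u = system.boundary_vector(sol.t)
    pressures[net.inflow_node] = u[0]
    pressures[net.outflow_node] = u[1]
    return PressureSeries(t=sol.t, pressures=pressures, period=period)


def _default_initial(system: PressureSystem) -> dict[str, float]:
    # steady resistive solve at the mean inflow, using the resistances baked
    # into the reduced system (recovered exactly by A^-1 F u)
    u = np.array([system.boundary.time_average, system.outflow_pressure])
    p_d = np.linalg.solve(system.A, -(system.F @ u))
    return dict(zip(system.diff_nodes, p_d))


def period_average(series: PressureSeries, period: float | None = None) -> dict[str, float]:
    """Trapezoidal integral mean of each node over the final period."""
    period = series.period if period is None else period
    if series.t[-1] - series.t[0] < period - 1e-9:
        raise SolverError("series shorter than one period")
    mask = series.t >= series.t[-1] - period - 1e-12
    t = series.t[mask]
    span = t[-1] - t[0]
    return {
        n: float(np.trapezoid(p[mask], t) / span) for n, p in series.pressures.items()
    }


def oscillation_amplitude(series: PressureSeries) -> dict[str, float]:
    """Peak-to-trough amplitude of each node over the final period."""
    mask = series.last_period_mask()
    return {
        n: float(np.max(p[mask]) - np.min(p[mask])) for n, p in series.pressures.items()
    }


@dataclass
class FlowSolution:
    """Compartment and per-vessel flows with wall shear stresses."""

    compartment_flows: dict[str, float]  # cm^3/s, whole compartment
    vessel_flows: dict[str, float]  # cm^3/s per individual vessel
    shear: dict[str, float]  # dyn/cm^2, per-vessel wall shear


def compartment_flows(
    averaged_pressures: Mapping[str, float],
    network: NetworkTopology,
    resistances: Mapping[str, float] | None = None,
    diameters: Mapping[str, float] | None = None,
) -> FlowSolution:
    """Ohm's-law flows from (period-averaged) nodal pressures.

    Flow is positive in the drawn arrow direction of the network (collateral
    flows may be negative).  Shear uses the per-vessel flow and the current
    diameter: tau = 32 mu q / (pi D^3).
    """
    comp_q: dict[str, float] = {}
    vessel_q: dict[str, float] = {}
    shear: dict[str, float] = {}
    for cid in network.active_compartments():
        comp = network.compartments[cid]
        u, v = network.compartment_endpoints(cid)
        try:
            dp = averaged_pressures[u] - averaged_pressures[v]
        except KeyError as err:
            raise SolverError(f"missing node pressure {err} for compartment {cid}")
        r = (
            resistances[cid]
            if resistances is not None and cid in resistances
            else comp.resistance
        )
        q = dp * MMHG_TO_DYN_CM2 / r
        d = diameters[cid] if diameters is not None and cid in diameters else comp.diameter
        comp_q[cid] = q
        vessel_q[cid] = q / comp.number
        shear[cid] = 32.0 * comp.viscosity * vessel_q[cid] / (np.pi * d**3)
    return FlowSolution(compartment_flows=comp_q, vessel_flows=vessel_q, shear=shear)
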