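"""Smooth-muscle regulation of arteriole and collateral diameters.

Each vasoactive compartment (large arterioles LA, small arterioles SA,
leptomeningeal collaterals COL) carries two states: diameter D and activation
A (dimensionless tone in [0, 1]).  The wall tension balance drives D,

    dD/dt = (1/tau_d) (Dc/Tc) (T - T_total),    T = (Pbar - Pic) D / 2,

with total tension the sum of a passive exponential and an active Gaussian
(Carlson-Arciero form) scaled by activation:

    T_total = Cpass exp(Cpass' (D/D0 - 1)) + A Cact exp(-((D/D0 - Cact')/Cact'')^2).

Activation relaxes toward a sigmoidal function of the tone stimulus,

    dA/dt = (A_total - A)/tau_a,   A_total = 1/(1 + exp(-S_tone)),
    S_tone = Cmyo T - Cshear tau - Cmeta S_meta + Ctone''  (no metabolic
    term for the LA class),

combining the myogenic (wall tension), shear (wall shear stress) and
conducted metabolic responses.

The tension/tone scale coefficients are not free: they are calibrated per
compartment so that the control state (tabulated diameters, activation 0.5 for
arterioles and 0.99 for collaterals) is an exact equilibrium of both ODEs.
Only dimensionless shape parameters and response gains are configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit, logit

from .units import MMHG_TO_DYN_CM2

TAU_DIAMETER = 1.0  # s, diameter time constant tau_d
TAU_ACTIVATION = 60.0  # s, activation time constant tau_a


class RegulationError(ValueError):
    """Raised for invalid regulation parameters or states."""


def wall_tension(mean_pressure: float, intracranial_pressure: float, diameter: float) -> float:
    """Law-of-Laplace circumferential wall tension (dyn/cm).

    T = (Pbar - Pic) D / 2 with pressures in mmHg converted to dyn/cm^2.
    Negative transmural pressure yields negative tension.
    """
    if not diameter > 0:
        raise RegulationError(f"diameter must be positive, got {diameter!r}")
    return (mean_pressure - intracranial_pressure) * MMHG_TO_DYN_CM2 * diameter / 2.0


@dataclass(frozen=True)
class RegulationShape:
    """Dimensionless shape parameters and response gains, per tone class.

    ``passive_exponent``/``active_center``/``active_width`` set the shapes of
    the passive and active tension curves around the reference diameter;
    ``passive_fraction`` fixes the passive share of control tension, which
    determines the two tension scales from the control anchors.  The gains
    are the control-state products Cmyo*Tc, Cshear*tau_c, Cmeta*Smeta_c, i.e.
    the stimulus swing produced by an order-one relative change of each
    input.
    """

    passive_exponent: float = 7.0  # Cpass'
    active_center: float = 1.0  # Cact', peak of active tension at D = D0
    active_width: float = 0.5  # Cact''
    passive_fraction: float = 0.3
    myogenic_gain: Mapping[str, float] = field(
        default_factory=lambda: {"LA": 10.0, "SA": 10.0, "COL": 5.0}
    )
    shear_gain: Mapping[str, float] = field(
        default_factory=lambda: {"LA": 1.0, "SA": 1.0, "COL": 1.0}
    )
    metabolic_gain: Mapping[str, float] = field(
        default_factory=lambda: {"LA": 0.0, "SA": 2.0, "COL": 4.0}
    )

    def validate(self) -> None:
        if not (0.0 < self.passive_fraction < 1.0):
            raise RegulationError("passive_fraction must be in (0, 1)")
        if not (self.active_width > 0 and self.passive_exponent > 0):
            raise RegulationError("active_width and passive_exponent must be positive")
        if self.metabolic_gain.get("LA", 0.0) != 0.0:
            raise RegulationError("LA class has no metabolic term")


@dataclass(frozen=True)
class CompartmentRegulation:
    """Calibrated tension/tone parameters for one vasoactive compartment."""

    cid: str
    tone_class: str  # LA / SA / COL
    d0: float  # reference diameter, cm
    cpass: float  # dyn/cm
    cpass_exp: float
    cact: float  # dyn/cm
    cact_center: float
    cact_width: float
    cmyo: float  # (dyn/cm)^-1
    cshear: float  # (dyn/cm^2)^-1
    cmeta: float  # (signal unit)^-1
    ctone: float  # Ctone''
    dc: float  # control diameter, cm
    tc: float  # control tension, dyn/cm
    pc: float  # control midpoint pressure, mmHg
    ac: float  # control activation


def tone_class(vessel_class: str) -> str:
    return "COL" if vessel_class.startswith("COL") else vessel_class


def passive_tension(diameter: float, prm: CompartmentRegulation) -> float:
    return prm.cpass * math.exp(prm.cpass_exp * (diameter / prm.d0 - 1.0))


def active_tension_max(diameter: float, prm: CompartmentRegulation) -> float:
    z = (diameter / prm.d0 - prm.cact_center) / prm.cact_width
    return prm.cact * math.exp(-z * z)


def total_tension(diameter: float, activation: float, prm: CompartmentRegulation) -> float:
    """Passive plus activation-weighted maximal active tension (dyn/cm)."""
    if not 0.0 <= activation <= 1.0:
        raise RegulationError(f"activation must lie in [0, 1], got {activation!r}")
    return passive_tension(diameter, prm) + activation * active_tension_max(diameter, prm)


def tone_stimulus(
    tension: float,
    shear: float,
    metabolic_signal: float,
    prm: CompartmentRegulation,
) -> float:
    """Class-appropriate linear stimulus for smooth-muscle activation."""
    s = prm.cmyo * tension - prm.cshear * abs(shear) + prm.ctone
    if prm.tone_class == "LA":
        if metabolic_signal:
            warnings.warn(
                f"metabolic signal supplied for LA compartment {prm.cid}; ignored",
                stacklevel=2,
            )
        return s
    return s - prm.cmeta * metabolic_signal


def total_activation(stimulus: float):
    """Sigmoidal activation target, A_total = 1/(1 + exp(-S_tone))."""
    return expit(stimulus)


@dataclass
class RegulationState:
    """Diameters (cm) and activations of the tracked vasoactive compartments."""

    diameters: dict[str, float]
    activations: dict[str, float]

    def copy(self) -> "RegulationState":
        return RegulationState(dict(self.diameters), dict(self.activations))

    def validate(self) -> None:
        for cid, d in self.diameters.items():
            if not d > 0:
                raise RegulationError(f"{cid}: diameter must stay positive, got {d!r}")
        for cid, a in self.activations.items():
            if not 0.0 <= a <= 1.0:
                raise RegulationError(f"{cid}: activation left [0, 1]: {a!r}")


def calibrate_tension_and_tone(
    anchors: "Mapping[str, dict]",
    control_shear: Mapping[str, float],
    control_signals: Mapping[str, float],
    shape: RegulationShape | None = None,
) -> dict[str, CompartmentRegulation]:
    """Solve the tension/tone scales so the control state is a fixed point.

    ``anchors`` maps compartment id -> dict with keys dc (cm), tc (dyn/cm),
    pc (mmHg), ac, vessel_class.  For each compartment, Cpass and Cact are
    solved from T_total(Dc, Ac) = Tc given the passive fraction, and Ctone''
    from S_tone(control inputs) = logit(Ac).  The shear normalizer for the
    collateral class is its control shear magnitude or, when that is
    negligible (collaterals carry almost no control flow), a class floor of
    10 dyn/cm^2 so the gain stays finite.
    """
    shape = shape or RegulationShape()
    shape.validate()
    params: dict[str, CompartmentRegulation] = {}
    for cid, anc in anchors.items():
        cls = tone_class(anc["vessel_class"])
        dc, tc, pc, ac = anc["dc"], anc["tc"], anc["pc"], anc["ac"]
        if not (tc > 0 and dc > 0 and 0 < ac < 1):
            raise RegulationError(f"{cid}: invalid anchors dc={dc}, tc={tc}, ac={ac}")
        d0 = dc
        cpass = shape.passive_fraction * tc
        gauss = math.exp(-(((1.0 - shape.active_center) / shape.active_width) ** 2))
        cact = (1.0 - shape.passive_fraction) * tc / (ac * gauss)
        if cact <= 0 or cpass <= 0:
            raise RegulationError(f"{cid}: infeasible shape parameters")

        tau_c = abs(control_shear.get(cid, 0.0))
        tau_ref = max(tau_c, 10.0)  # dyn/cm^2 floor for near-zero control shear
        smeta_c = control_signals.get(cid, 0.0)
        cmyo = shape.myogenic_gain[cls] / tc
        cshear = shape.shear_gain[cls] / tau_ref
        gmeta = shape.metabolic_gain.get(cls, 0.0)
        cmeta = 0.0 if (cls == "LA" or smeta_c <= 0) else gmeta / smeta_c
        ctone = float(logit(ac)) - (cmyo * tc - cshear * tau_c - cmeta * smeta_c)
        params[cid] = CompartmentRegulation(
            cid=cid,
            tone_class=cls,
            d0=d0,
            cpass=cpass,
            cpass_exp=shape.passive_exponent,
            cact=cact,
            cact_center=shape.active_center,
            cact_width=shape.active_width,
            cmyo=cmyo,
            cshear=cshear,
            cmeta=cmeta,
            ctone=ctone,
            dc=dc,
            tc=tc,
            pc=pc,
            ac=ac,
        )
    return params


def regulation_rhs(
    state: RegulationState,
    midpoint_pressures: Mapping[str, float],
    shear: Mapping[str, float],
    metabolic_signals: Mapping[str, float],
    params: Mapping[str, CompartmentRegulation],
    intracranial_pressure: float = 9.5,
) -> tuple[dict[str, float], dict[str, float]]:
    """Time derivatives of diameter and activation for every tracked compartment.

    Implements dD/dt = (1/tau_d)(Dc/Tc)(T - T_total); since
    Tc = (Pc - Pic) Dc / 2, the prefactor Dc/Tc equals 2/(Pc - Pic) in
    pressure units, so the two tabulated forms of the diameter law coincide.
    """
    d_dot: dict[str, float] = {}
    a_dot: dict[str, float] = {}
    for cid, prm in params.items():
        if cid not in state.diameters:
            raise RegulationError(f"state missing tracked compartment {cid}")
        d = state.diameters[cid]
        a = state.activations[cid]
        try:
            pbar = midpoint_pressures[cid]
        except KeyError:
            raise RegulationError(f"missing midpoint pressure for {cid}")
        t_wall = wall_tension(pbar, intracranial_pressure, d)
        d_dot[cid] = (prm.dc / prm.tc) * (t_wall - total_tension(d, a, prm)) / TAU_DIAMETER
        s = tone_stimulus(t_wall, shear.get(cid, 0.0), metabolic_signals.get(cid, 0.0), prm)
        a_dot[cid] = (float(total_activation(s)) - a) / TAU_ACTIVATION
    return d_dot, a_dot
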