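"""Oxygen saturation along flow pathways and the conducted metabolic signal.

A deliberately simple convective mass balance: each tissue region consumes
oxygen at a demand rate M0 (cm^3 O2 / 100 cm^3 tissue / min) distributed over
its microcirculatory compartments by fixed extraction fractions.  Crossing
compartment k drops the blood oxygen saturation by

    dS_k = f_k * demand_region / (|Q_k| * c0),

where Q_k is the compartment flow and c0 the oxygen carrying capacity of
blood; saturation is clamped at zero.  Conduit arteries extract nothing.

Venules with low saturation generate a vasodilatory signal proportional to
(1 - S) * length which is conducted upstream with exponential attenuation
(length constant ``decay_length``) to the small arterioles and, further
attenuated across the arteriolar length, to the leptomeningeal collaterals,
which receive it from both regions they join (collateral flow can run either
way).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .network import MICRO_REGIONS, SIDES, NetworkTopology
from .solver import FlowSolution


class OxygenError(ValueError):
    """Raised for invalid oxygen-transport parameters or pathways."""


DEFAULT_EXTRACTION = {"LA": 0.10, "SA": 0.20, "CAP": 0.50, "SV": 0.15, "LV": 0.05}


@dataclass(frozen=True)
class OxygenParams:
    """Oxygen supply/demand parameters.

    ``volume_per_flow`` sets the default tissue volume of each region in
    proportion to its control regional blood flow (cm^3 tissue per cm^3/s);
    the default of 35 gives a control oxygen extraction fraction of about
    0.35 at M0 = 12.
    """

    inflow_saturation: float = 0.97
    carrying_capacity: float = 0.2  # cm^3 O2 per cm^3 blood
    m0: float = 12.0  # cm^3 O2 / 100 cm^3 tissue / min
    volume_per_flow: float = 35.0  # cm^3 per (cm^3/s) of control regional flow
    tissue_volumes: Mapping[str, float] | None = None  # region-side -> cm^3, overrides
    extraction_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXTRACTION)
    )
    decay_length: float = 1.0  # cm, conducted-response length constant
    min_flow: float = 1e-9  # cm^3/s, below which a pathway counts as unperfused

    def validate(self) -> None:
        for name in ("inflow_saturation", "carrying_capacity", "volume_per_flow", "decay_length"):
            if not getattr(self, name) > 0:
                raise OxygenError(f"{name} must be positive")
        if self.m0 < 0:
            raise OxygenError("m0 must be non-negative")
        fr = self.extraction_fractions
        if any(v < 0 for v in fr.values()) or abs(sum(fr.values()) - 1.0) > 1e-9:
            raise OxygenError("extraction fractions must be non-negative and sum to 1")


def demand_rate(params: OxygenParams, tissue_volume: float) -> float:
    """Regional oxygen consumption in cm^3 O2 / s."""
    return params.m0 / (100.0 * 60.0) * tissue_volume


@dataclass
class SaturationProfile:
    """Saturation at compartment boundaries along an ordered pathway."""

    compartments: list[str]
    positions: list[float]  # cumulative length, cm; len = n_compartments + 1
    saturations: list[float]  # at boundaries; len = n_compartments + 1
    segment_means: dict[str, float]
    clamped: bool = False
    unperfused: bool = False

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "pathway_position_cm": self.positions,
                "compartment": ["inflow"] + self.compartments,
                "saturation": self.saturations,
            }
        ).to_csv(path, index=False)


def saturation_profile(
    pathway: list[tuple[str, float, float]],
    flows: FlowSolution,
    network: NetworkTopology,
    params: OxygenParams,
    s_in: float | None = None,
) -> SaturationProfile:
    """Integrate the saturation mass balance along an ordered pathway.

    ``pathway`` is a list of (compartment id, extraction fraction, regional
    demand in cm^3 O2/s); conduit entries carry fraction 0.  A reversed
    collateral segment is handled by its flow magnitude (the caller orders
    the pathway in the actual flow direction).
    """
    params.validate()
    s = params.inflow_saturation if s_in is None else s_in
    positions = [0.0]
    saturations = [s]
    segment_means: dict[str, float] = {}
    comps: list[str] = []
    clamped = False
    unperfused = False
    for cid, fraction, demand in pathway:
        comp = network.compartments[cid]
        q = abs(flows.compartment_flows.get(cid, 0.0))
        if fraction > 0.0:
            if q <= params.min_flow:
                unperfused = True
                drop = s  # no flow: whatever enters is fully consumed
            else:
                drop = fraction * demand / (q * params.carrying_capacity)
        else:
            drop = 0.0
        s_new = s - drop
        if s_new < 0.0:
            s_new = 0.0
            clamped = True
        segment_means[cid] = 0.5 * (s + s_new)
        comps.append(cid)
        positions.append(positions[-1] + comp.length)
        saturations.append(s_new)
        s = s_new
    return SaturationProfile(
        compartments=comps,
        positions=positions,
        saturations=saturations,
        segment_means=segment_means,
        clamped=clamped,
        unperfused=unperfused,
    )


def region_tissue_volume(
    params: OxygenParams, region: str, side: str, control_regional_flow: float
) -> float:
    key = f"{region}{side}"
    if params.tissue_volumes is not None and key in params.tissue_volumes:
        return params.tissue_volumes[key]
    return params.volume_per_flow * control_regional_flow


def region_pathway(
    network: NetworkTopology, region: str, side: str, demand: float, params: OxygenParams
) -> list[tuple[str, float, float]]:
    """The standard LA->SA->CAP->SV->LV chain of one region and side."""
    fr = params.extraction_fractions
    chain = []
    for cls in ("LA", "SA", "CAP", "SV", "LV"):
        cid = f"{cls}_{region}{side}"
        if cid in network.occluded or cid in network.untracked:
            continue
        chain.append((cid, fr[cls], demand))
    return chain


def collateral_feed_pathway(
    network: NetworkTopology, side: str, demand_anterior: float, demand_middle: float,
    params: OxygenParams,
) -> list[tuple[str, float, float]]:
    """Pathway from the anterior arteries through the anterior-middle
    collaterals into the middle microcirculation (the occluded-feed route)."""
    fr = params.extraction_fractions
    return [
        (f"ICA_{side}", 0.0, 0.0),
        (f"ACA1_{side}", 0.0, 0.0),
        (f"ACA2_{side}", 0.0, 0.0),
        (f"LA_a{side}", fr["LA"], demand_anterior),
        (f"COLam_{side}", 0.0, 0.0),
        (f"SA_m{side}", fr["SA"], demand_middle),
        (f"CAP_m{side}", fr["CAP"], demand_middle),
        (f"SV_m{side}", fr["SV"], demand_middle),
        (f"LV_m{side}", fr["LV"], demand_middle),
    ]


def regional_saturations(
    network: NetworkTopology,
    flows: FlowSolution,
    params: OxygenParams,
    control_regional_flows: Mapping[str, float],
) -> dict[str, SaturationProfile]:
    """Saturation profiles for every region and side.

    Regions whose large arterioles lost their feed (occluded middle side)
    are evaluated along the collateral feed pathway instead of their own
    arteriolar chain.
    """
    params.validate()
    out: dict[str, SaturationProfile] = {}
    for k in MICRO_REGIONS:
        for j in SIDES:
            key = f"{k}{j}"
            demand = demand_rate(params, region_tissue_volume(params, k, j, control_regional_flows[key]))
            if f"LA_{k}{j}" in network.untracked:
                dem_a = demand_rate(
                    params, region_tissue_volume(params, "a", j, control_regional_flows[f"a{j}"])
                )
                path = collateral_feed_pathway(network, j, dem_a, demand, params)
            else:
                path = region_pathway(network, k, j, demand, params)
            out[key] = saturation_profile(path, flows, network, params)
    return out


def metabolic_signal(
    profiles: Mapping[str, SaturationProfile],
    network: NetworkTopology,
    params: OxygenParams,
) -> dict[str, float]:
    """Conducted vasodilatory signal at each small arteriole and collateral.

    Generated in the venules as (1 - mean saturation) * length, attenuated
    upstream by exp(-distance / decay_length).  At the arteriole-collateral
    junction the signal continues into both upstream directions, so each
    collateral receives the attenuated signals of both regions it connects.
    """
    lam = params.decay_length
    sig: dict[str, float] = {}
    sa_signal: dict[str, float] = {}
    for k in MICRO_REGIONS:
        for j in SIDES:
            prof = profiles[f"{k}{j}"]
            total = 0.0
            dist = 0.0
            # walk upstream from the small arterioles: CAP then SV then LV
            for cls in ("CAP", "SV", "LV"):
                cid = f"{cls}_{k}{j}"
                comp = network.compartments[cid]
                if cls != "CAP":
                    mean_s = prof.segment_means.get(cid, 1.0)
                    total += (1.0 - mean_s) * comp.length * math.exp(-(dist + comp.length / 2.0) / lam)
                dist += comp.length
            sa_signal[f"{k}{j}"] = total
            sig[f"SA_{k}{j}"] = total
    for j in SIDES:
        for col, other in (("COLam", "a"), ("COLpm", "p")):
            l_sa_m = network.compartments[f"SA_m{j}"].length
            l_sa_o = network.compartments[f"SA_{other}{j}"].length
            sig[f"{col}_{j}"] = sa_signal[f"m{j}"] * math.exp(-l_sa_m / lam) + sa_signal[
                f"{other}{j}"
            ] * math.exp(-l_sa_o / lam)
    return sig
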