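"""Vascular network of the cerebral circulation as a resistor-capacitor graph.

The model covers both sides of a complete Circle of Willis (ICA, BA, MCA,
ACA1/2, PCA1/2, PCoA, ACoA), the microcirculation of the middle, anterior and
posterior regions (large/small arterioles, capillaries, small/large venules),
the leptomeningeal collaterals joining the middle region to its neighbours,
and a common venous outflow (veins and venous sinuses).

Large arteries, veins and venous sinuses carry a capacitor (Windkessel
compliance); such compartments are split into halves *a* and *b*, each holding
half the compartment's length and resistance, with the capacitor at the node
between them.  Arterioles and collaterals are vasoactive: their diameters are
governed by the regulation module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

from .units import UM_TO_CM

#: compartment classes that carry a capacitor
CAPACITOR_CLASSES = frozenset(
    {"ICA", "BA", "MCA", "ACA1", "ACA2", "PCA1", "PCA2", "PCoA", "ACoA", "V", "VS"}
)
#: compartment classes under active diameter control
VASOACTIVE_CLASSES = frozenset({"LA", "SA", "COLam", "COLpm"})
#: compartments whose tabulated resistance is kept verbatim (no Poiseuille check)
TABULATED_RESISTANCE_ONLY = frozenset({"PCoA", "ACoA", "V", "VS"})

MICRO_REGIONS = ("m", "a", "p")
SIDES = ("l", "r")


class NetworkError(ValueError):
    """Raised for invalid network tables or topology operations."""


def poiseuille_resistance(
    diameter: float, length: float, number: float = 1.0, viscosity: float = 0.04
) -> float:
    """Hydraulic resistance of ``number`` identical parallel vessels.

    R = 128 L mu / (n pi D^4), CGS units (dyn s/cm^5); ``diameter`` and
    ``length`` in cm, ``viscosity`` in Poise.
    """
    for name, value in (
        ("diameter", diameter),
        ("length", length),
        ("number", number),
        ("viscosity", viscosity),
    ):
        if not value > 0:
            raise NetworkError(f"poiseuille_resistance: {name} must be positive, got {value!r}")
    return 128.0 * length * viscosity / (number * math.pi * diameter**4)


def compartment_capacitance(diameter: float, length: float, distensibility: float) -> float:
    """Capacitance (cm^5/dyn) = distensibility x cylindrical vessel volume."""
    for name, value in (
        ("diameter", diameter),
        ("length", length),
        ("distensibility", distensibility),
    ):
        if not value > 0:
            raise NetworkError(f"compartment_capacitance: {name} must be positive, got {value!r}")
    return distensibility * math.pi * (diameter / 2.0) ** 2 * length


@dataclass(frozen=True)
class VesselCompartment:
    """One lumped compartment (possibly many identical vessels in parallel)."""

    id: str
    vessel_class: str  # e.g. "ICA", "LA", "COLam"
    region: str  # middle / anterior / posterior / shared
    side: str  # l / r / none
    diameter: float  # cm
    length: float  # cm
    number: float  # parallel vessel count (>= 1)
    resistance: float  # dyn s/cm^5, whole compartment (tabulated/control value)
    viscosity: float = 0.04  # Poise
    distensibility: float | None = None  # cm^2/dyn
    capacitance: float | None = None  # cm^5/dyn
    has_capacitor: bool = False
    vasoactive: bool = False

    def scaled_resistance(self, diameter: float | None = None, number: float | None = None) -> float:
        """Resistance at a non-control diameter / vessel count.

        Scales the control (tabulated) resistance by Poiseuille's law,
        R = R_c (n_c/n) (D_c/D)^4, which keeps the control table exact while
        preserving the D^-4 dependence used by the regulation model.
        """
        d = self.diameter if diameter is None else diameter
        n = self.number if number is None else number
        if not d > 0:
            raise NetworkError(f"{self.id}: diameter must be positive, got {d!r}")
        if not n > 0:
            raise NetworkError(f"{self.id}: number must be positive, got {n!r}")
        return self.resistance * (self.number / n) * (self.diameter / d) ** 4


@dataclass(frozen=True)
class Edge:
    """A resistive element between two pressure nodes.

    ``half`` is "a"/"b" for the two halves of a capacitor compartment (each
    carrying half the compartment resistance) or None for a whole compartment.
    """

    u: str
    v: str
    compartment: str
    half: str | None = None

    @property
    def fraction(self) -> float:
        return 0.5 if self.half else 1.0


def _wiring(cid: str, vessel_class: str, region: str, side: str) -> tuple[str, str, str | None]:
    """Return (upstream node, downstream node, capacitor node) for a compartment."""
    j = side
    if vessel_class == "ICA":
        return "Pa", f"PICA,{j}2", f"PICA,{j}1"
    if vessel_class == "BA":
        return "Pa", "PBA2", "PBA1"
    if vessel_class == "MCA":
        return f"PICA,{j}2", f"P1,m{j}", f"PMCA,{j}"
    if vessel_class == "ACA1":
        return f"PICA,{j}2", f"PACA,{j}", f"PACA,{j}1"
    if vessel_class == "ACA2":
        return f"PACA,{j}", f"P1,a{j}", f"PACA,{j}2"
    if vessel_class == "PCA1":
        return "PBA2", f"PPCA,{j}", f"PPCA,{j}1"
    if vessel_class == "PCA2":
        return f"PPCA,{j}", f"P1,p{j}", f"PPCA,{j}2"
    if vessel_class == "PCoA":
        return f"PPCA,{j}", f"PICA,{j}2", f"PPCoA,{j}"
    if vessel_class == "ACoA":
        return "PACA,r", "PACA,l", "PACoA"
    if vessel_class in {"LA", "SA", "CAP", "SV", "LV"}:
        k = {"middle": "m", "anterior": "a", "posterior": "p"}[region]
        stage = {"LA": (1, 2), "SA": (2, 3), "CAP": (3, 4), "SV": (4, 5), "LV": (5, 6)}[
            vessel_class
        ]
        up = f"P{stage[0]},{k}{j}"
        down = "P6" if vessel_class == "LV" else f"P{stage[1]},{k}{j}"
        return up, down, None
    if vessel_class == "COLam":
        return f"P2,a{j}", f"P2,m{j}", None
    if vessel_class == "COLpm":
        return f"P2,p{j}", f"P2,m{j}", None
    if vessel_class == "V":
        return "P6", "P7", "P6,mid"
    if vessel_class == "VS":
        return "P7", "PV", "P7,mid"
    raise NetworkError(f"unknown vessel class for compartment {cid!r}")


@dataclass(frozen=True)
class NetworkTopology:
    """The full node/edge graph with boundary, capacitor and junction nodes."""

    compartments: Mapping[str, VesselCompartment]
    edges: tuple[Edge, ...]
    capacitor_nodes: Mapping[str, str]  # node label -> compartment id
    inflow_node: str = "Pa"
    outflow_node: str = "PV"
    outflow_pressure: float = 9.5  # mmHg, fixed venous boundary
    intracranial_pressure: float = 9.5  # mmHg, Pic
    occluded: frozenset[str] = field(default_factory=frozenset)
    untracked: frozenset[str] = field(default_factory=frozenset)

    @property
    def nodes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.u)
            seen.setdefault(e.v)
        return tuple(seen)

    @property
    def boundary_nodes(self) -> tuple[str, str]:
        return (self.inflow_node, self.outflow_node)

    @property
    def internal_nodes(self) -> tuple[str, ...]:
        b = set(self.boundary_nodes)
        return tuple(n for n in self.nodes if n not in b)

    @property
    def junction_nodes(self) -> tuple[str, ...]:
        b = set(self.boundary_nodes) | set(self.capacitor_nodes)
        return tuple(n for n in self.nodes if n not in b)

    @property
    def differential_nodes(self) -> tuple[str, ...]:
        return tuple(self.capacitor_nodes)

    def compartment_endpoints(self, cid: str) -> tuple[str, str]:
        """Outer (non-capacitor) endpoints of a compartment."""
        comp = self.compartments[cid]
        u, v, _ = _wiring(cid, comp.vessel_class, comp.region, comp.side)
        return u, v

    def active_compartments(self) -> tuple[str, ...]:
        """Compartments still present in the graph (occlusion-aware)."""
        gone = self.occluded | self.untracked
        return tuple(cid for cid in self.compartments if cid not in gone)

    def vasoactive_compartments(self) -> tuple[str, ...]:
        """Vasoactive compartments whose state is tracked (occlusion-aware)."""
        skip = self.occluded | self.untracked
        return tuple(
            cid
            for cid, c in self.compartments.items()
            if c.vasoactive and cid not in skip
        )


def load_default_table() -> dict:
    """Load the bundled control-state vessel table (JSON)."""
    with resources.files("cerebroflow").joinpath("data/control_network.json").open() as fh:
        return json.load(fh)


def _expand_rows(table: dict) -> list[VesselCompartment]:
    art_dist = float(table.get("arterial_distensibility", 4.01e-7))
    ven_factor = float(table.get("venous_distensibility_factor", 8.0))
    mu = float(table.get("viscosity_poise", 0.04))
    comps: list[VesselCompartment] = []
    for row in table["compartments"]:
        rid = row["id"]
        vessel_class = rid.split("_")[0]
        sides = SIDES if row.get("per_side") else ("none",)
        for side in sides:
            if vessel_class in {"LA", "SA", "CAP", "SV", "LV"}:
                k = rid.split("_")[1]
                cid = f"{vessel_class}_{k}{side}"
            elif side == "none":
                cid = rid
            else:
                cid = f"{rid}_{side}"
            has_cap = bool(row.get("has_capacitor", False))
            dist = None
            if has_cap:
                dist = art_dist * (ven_factor if vessel_class in {"V", "VS"} else 1.0)
            comps.append(
                VesselCompartment(
                    id=cid,
                    vessel_class=vessel_class,
                    region=row["region"],
                    side=side,
                    diameter=float(row["diameter_um"]) * UM_TO_CM,
                    length=float(row["length_cm"]),
                    number=float(row["number"]),
                    resistance=float(row["resistance"]),
                    viscosity=mu,
                    distensibility=dist,
                    capacitance=(None if row.get("capacitance") is None else float(row["capacitance"])),
                    has_capacitor=has_cap,
                    vasoactive=bool(row.get("vasoactive", False)),
                )
            )
    return comps


def _validate(comps: Iterable[VesselCompartment]) -> None:
    by_id = {c.id: c for c in comps}
    expected = set()
    for cls in ("ICA", "MCA", "ACA1", "ACA2", "PCA1", "PCA2", "PCoA"):
        expected |= {f"{cls}_l", f"{cls}_r"}
    expected |= {"BA", "ACoA", "V", "VS"}
    for cls in ("LA", "SA", "CAP", "SV", "LV"):
        for k in MICRO_REGIONS:
            for j in SIDES:
                expected.add(f"{cls}_{k}{j}")
    for cls in ("COLam", "COLpm"):
        expected |= {f"{cls}_l", f"{cls}_r"}
    missing = expected - set(by_id)
    if missing:
        raise NetworkError(f"missing compartments: {sorted(missing)}")

    for c in by_id.values():
        if c.vessel_class in TABULATED_RESISTANCE_ONLY:
            continue
        recomputed = poiseuille_resistance(c.diameter, c.length, c.number, c.viscosity)
        if c.vessel_class in CAPACITOR_CLASSES:
            if round(recomputed) != round(c.resistance):
                raise NetworkError(
                    f"{c.id}: Poiseuille resistance {recomputed:.1f} does not match "
                    f"table value {c.resistance:.0f}"
                )
        else:
            if abs(recomputed - c.resistance) > 0.02 * c.resistance:
                raise NetworkError(
                    f"{c.id}: Poiseuille resistance {recomputed:.1f} deviates more than "
                    f"2% from table value {c.resistance:.0f}"
                )
        if (c.has_capacitor) != (c.vessel_class in CAPACITOR_CLASSES):
            raise NetworkError(f"{c.id}: capacitor flag inconsistent with vessel class")
        if (c.vasoactive) != (c.vessel_class in VASOACTIVE_CLASSES):
            raise NetworkError(f"{c.id}: vasoactive flag inconsistent with vessel class")


def build_network(
    table: dict | None = None,
    *,
    distensibility_scale: float = 1.0,
    validate: bool = True,
) -> NetworkTopology:
    """Build the full symmetric topology from a vessel table.

    ``distensibility_scale`` multiplies every capacitance (used to study
    stiffer or more compliant vessels); 1.0 is the control state.
    """
    if table is None:
        table = load_default_table()
    comps = _expand_rows(table)
    if validate:
        _validate(comps)
    if not distensibility_scale > 0:
        raise NetworkError("distensibility_scale must be positive")
    if distensibility_scale != 1.0:
        comps = [
            replace(
                c,
                capacitance=(None if c.capacitance is None else c.capacitance * distensibility_scale),
                distensibility=(None if c.distensibility is None else c.distensibility * distensibility_scale),
            )
            for c in comps
        ]

    edges: list[Edge] = []
    capacitor_nodes: dict[str, str] = {}
    for c in comps:
        u, v, cap = _wiring(c.id, c.vessel_class, c.region, c.side)
        if c.has_capacitor:
            assert cap is not None
            if cap in capacitor_nodes:
                raise NetworkError(f"duplicate capacitor node label {cap!r}")
            capacitor_nodes[cap] = c.id
            edges.append(Edge(u, cap, c.id, "a"))
            edges.append(Edge(cap, v, c.id, "b"))
        else:
            edges.append(Edge(u, v, c.id, None))

    return NetworkTopology(
        compartments={c.id: c for c in comps},
        edges=tuple(edges),
        capacitor_nodes=capacitor_nodes,
        outflow_pressure=float(table.get("venous_outflow_pressure_mmhg", 9.5)),
        intracranial_pressure=float(table.get("intracranial_pressure_mmhg", 9.5)),
    )


def apply_occlusion(network: NetworkTopology, compartment_id: str = "MCA_l") -> NetworkTopology:
    """Total occlusion of a compartment by structural removal.

    Only the left middle cerebral artery is supported: both halves of MCA_l
    are removed together with nodes PMCA,l and P1,ml; the middle-left large
    arterioles lose their upstream feed and are no longer tracked (the
    middle-left microcirculation is then perfused only through the
    leptomeningeal collaterals at P2,ml).  Idempotent.
    """
    if compartment_id not in network.compartments:
        raise NetworkError(f"unknown compartment {compartment_id!r}")
    if compartment_id != "MCA_l":
        raise NetworkError("only occlusion of the left MCA (MCA_l) is supported")
    if compartment_id in network.occluded:
        return network

    removed = {"MCA_l", "LA_ml"}
    edges = tuple(e for e in network.edges if e.compartment not in removed)
    cap_nodes = {n: cid for n, cid in network.capacitor_nodes.items() if cid != "MCA_l"}
    new = NetworkTopology(
        compartments=network.compartments,
        edges=edges,
        capacitor_nodes=cap_nodes,
        inflow_node=network.inflow_node,
        outflow_node=network.outflow_node,
        outflow_pressure=network.outflow_pressure,
        intracranial_pressure=network.intracranial_pressure,
        occluded=network.occluded | {"MCA_l"},
        untracked=network.untracked | {"LA_ml"},
    )
    for gone in ("PMCA,l", "P1,ml"):
        if gone in new.nodes:  # pragma: no cover - structural guarantee
            raise NetworkError(f"occlusion failed to remove node {gone}")
    return new


def mirror_node(node: str) -> str:
    """Swap left/right in a node label (identity for shared nodes)."""
    if node.endswith(",l1") or node.endswith(",r1") or node.endswith(",l2") or node.endswith(",r2"):
        body, tail = node[:-2], node[-2:]
        swapped = {"l1": "r1", "r1": "l1", "l2": "r2", "r2": "l2"}[tail]
        return body + swapped
    if node.endswith(",l") or node.endswith(",r"):
        return node[:-1] + ("r" if node.endswith("l") else "l")
    if node.endswith("l") and "," in node:  # e.g. P1,ml
        return node[:-1] + "r"
    if node.endswith("r") and "," in node:
        return node[:-1] + "l"
    return node
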