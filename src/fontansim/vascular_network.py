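"""Circulation topology: Windkessel compartments, chambers, and shunt edges.

The total cavopulmonary connection (TCPC) Fontan layout is a single closed
loop: systemic ventricle -> aorta -> five parallel systemic beds (upper body,
abdominal organs, kidneys, lower extremities, coronary) -> caval veins ->
TCPC junction at the pulmonary arteries (the SVC directly, the IVC through an
artificial conduit) -> two parallel pulmonary branches -> pulmonary veins ->
common atrium -> ventricle.  There is no subpulmonary pump; pulmonary flow is
driven passively by the caval-to-atrial pressure gradient.

Three shunt kinds can be attached:

* ``fenestration`` — conduit to atrium, a deliberate pop-off for the Fontan
  pathway;
* ``VVC`` — venovenous collateral, systemic veins to pulmonary veins (or
  atrium), bypassing the lungs and desaturating arterial blood;
* ``APC`` — aortopulmonary collateral, systemic arteries to pulmonary
  arteries, recirculating oxygenated blood and loading the ventricle.

Every node carries a compliance, so junctions are small compartments and the
network state is the vector of compartment volumes (plus flows of any
inertial edges).  The TCPC constraint — both cavae drain to the pulmonary
artery, never directly to the atrium — is enforced structurally and checked
by :func:`validate_topology`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import networkx as nx
import yaml

from .heart_chamber import ChamberParameters, ValveParameters
from .parameters import Registry, ScenarioConfig, default_registry

__all__ = [
    "CompartmentParameters",
    "ShuntParameters",
    "Node",
    "Edge",
    "Topology",
    "TopologyError",
    "build_fontan_topology",
    "attach_shunt",
    "validate_topology",
    "topology_to_dict",
    "topology_from_dict",
]


class TopologyError(ValueError):
    """A structural rule of the circulation network was violated."""


#: node classes used for shunt endpoint rules and initial pressure guesses
NODE_CLASSES = (
    "systemic_arterial",
    "systemic_venous",
    "fontan_pathway",
    "pulmonary_arterial",
    "pulmonary_venous",
    "atrium",
    "ventricle",
)

#: allowed (source class, target class) pairs per shunt kind
_SHUNT_RULES: Mapping[str, tuple[tuple[str, str], ...]] = {
    "VVC": (("systemic_venous", "pulmonary_venous"), ("systemic_venous", "atrium")),
    "APC": (("systemic_arterial", "pulmonary_arterial"),),
    "fenestration": (("fontan_pathway", "atrium"),),
}


@dataclass(frozen=True)
class CompartmentParameters:
    """One vascular bed's lumped elements: outflow resistance R (mmHg.s/mL),
    compliance C (mL/mmHg), outflow inertance L (mmHg.s2/mL) and unstressed
    volume (mL)."""

    name: str
    resistance: float
    compliance: float
    inertance: float = 0.0
    unstressed_volume: float = 0.0

    def __post_init__(self) -> None:
        if self.resistance < 0:
            raise ValueError(f"{self.name}: resistance must be non-negative")
        if self.compliance <= 0:
            raise ValueError(f"{self.name}: compliance must be positive")
        if self.inertance < 0:
            raise ValueError(f"{self.name}: inertance must be non-negative")


@dataclass(frozen=True)
class ShuntParameters:
    """A collateral or fenestration: endpoints, conductance (mL/s/mmHg) and
    an optional orifice exponent (1 = linear conductance)."""

    kind: str
    source_node: str
    target_node: str
    conductance: float
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _SHUNT_RULES:
            raise ValueError(f"unknown shunt kind {self.kind!r}; expected one of "
                             f"{sorted(_SHUNT_RULES)}")
        if self.conductance < 0:
            raise ValueError(f"{self.kind}: conductance must be non-negative")
        if not (0 < self.exponent <= 1.0):
            raise ValueError(f"{self.kind}: orifice exponent must lie in (0, 1]")


@dataclass(frozen=True)
class Node:
    """A network node: either a Windkessel compartment or an elastance chamber."""

    name: str
    node_class: str
    compartment: Optional[CompartmentParameters] = None
    chamber: Optional[ChamberParameters] = None

    def __post_init__(self) -> None:
        if self.node_class not in NODE_CLASSES:
            raise ValueError(f"{self.name}: unknown node class {self.node_class!r}")
        if (self.compartment is None) == (self.chamber is None):
            raise ValueError(f"{self.name}: node needs exactly one of compartment/chamber")


@dataclass(frozen=True)
class Edge:
    """A directed connection carrying flow from ``source`` to ``target``.

    kind 'resistive' uses R (and a flow state when L > 0), 'valve' the
    smoothed diode law, 'shunt' the conductance law of its ShuntParameters.
    """

    name: str
    source: str
    target: str
    kind: str = "resistive"
    resistance: float = 0.0
    inertance: float = 0.0
    valve: Optional[ValveParameters] = None
    shunt: Optional[ShuntParameters] = None
    is_bed: bool = False
    is_pulmonary_capillary: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("resistive", "valve", "shunt"):
            raise ValueError(f"{self.name}: unknown edge kind {self.kind!r}")
        if self.kind == "valve" and self.valve is None:
            raise ValueError(f"{self.name}: valve edge needs ValveParameters")
        if self.kind == "shunt" and self.shunt is None:
            raise ValueError(f"{self.name}: shunt edge needs ShuntParameters")
        if self.kind == "resistive" and self.resistance < 0:
            raise ValueError(f"{self.name}: resistance must be non-negative")


@dataclass(frozen=True)
class Topology:
    """Ordered nodes and edges of one circulation network.

    Edges are stored sorted by name, so topologies built by attaching the
    same shunts in any order compare equal.
    """

    nodes: tuple[Node, ...]
    edges: tuple[Edge, ...]
    initial_pressures: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(sorted(self.edges, key=lambda e: e.name)))
        object.__setattr__(self, "initial_pressures", dict(self.initial_pressures))
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise TopologyError("duplicate node names")
        enames = [e.name for e in self.edges]
        if len(set(enames)) != len(enames):
            raise TopologyError("duplicate edge names")

    def node(self, name: str) -> Node:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def edge(self, name: str) -> Edge:
        for e in self.edges:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def shunts(self) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.kind == "shunt")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.name, node_class=n.node_class)
        for e in self.edges:
            g.add_edge(e.source, e.target, name=e.name, kind=e.kind)
        return g


def _shunt_endpoints_valid(topology_nodes: Iterable[Node], shunt: ShuntParameters) -> bool:
    classes = {n.name: n.node_class for n in topology_nodes}
    src = classes.get(shunt.source_node)
    dst = classes.get(shunt.target_node)
    return (src, dst) in _SHUNT_RULES[shunt.kind]


def attach_shunt(topology: Topology, shunt: ShuntParameters) -> Topology:
    """Return a new topology with the shunt edge added; the original is unchanged."""
    names = {n.name for n in topology.nodes}
    for endpoint in (shunt.source_node, shunt.target_node):
        if endpoint not in names:
            raise TopologyError(f"shunt {shunt.kind}: unknown endpoint {endpoint!r}")
    if not _shunt_endpoints_valid(topology.nodes, shunt):
        raise TopologyError(
            f"shunt {shunt.kind}: endpoints {shunt.source_node} -> {shunt.target_node} "
            f"violate the kind rule {_SHUNT_RULES[shunt.kind]}"
        )
    edge = Edge(
        name=shunt.kind.lower(),
        source=shunt.source_node,
        target=shunt.target_node,
        kind="shunt",
        shunt=shunt,
    )
    return replace(topology, edges=topology.edges + (edge,))


def build_fontan_topology(config: ScenarioConfig, registry: Registry | None = None) -> Topology:
    """Assemble the closed-loop TCPC Fontan network from the registry.

    Applies the scenario's resistance baselines/ratios are expected to be
    already folded into the registry aggregates (see
    :mod:`fontansim.pharmacology`); this builder only multiplies the
    scenario baselines by the configured ratios when the registry still
    carries the raw defaults.
    """
    registry = registry if registry is not None else default_registry()

    comps: dict[str, CompartmentParameters] = {}
    comp_doc = registry["compartments"]
    required = ("aorta", "svc_veins", "ivc_veins", "conduit",
                "pulmonary_arteries", "pulmonary_veins")
    for name in required:
        if name not in comp_doc:
            raise TopologyError(f"registry gap: missing compartment {name!r}")
        entry = comp_doc[name]
        comps[name] = CompartmentParameters(
            name=name,
            resistance=float(entry["R"]),
            compliance=float(entry["C"]),
            inertance=float(entry.get("L", 0.0)),
            unstressed_volume=float(entry.get("v0", 0.0)),
        )

    def chamber(name: str) -> ChamberParameters:
        entry = registry[f"chambers.{name}"]
        return ChamberParameters(
            e_max=float(entry["e_max"]),
            e_min=float(entry["e_min"]),
            v0=float(entry["v0"]),
            viscoelastic_coefficient=float(entry.get("viscoelastic_coefficient", 0.0)),
            m1=float(entry.get("m1", 1.9)),
            m2=float(entry.get("m2", 21.9)),
            tau1_fraction=float(entry.get("tau1_fraction", 0.269)),
            tau2_fraction=float(entry.get("tau2_fraction", 0.452)),
            activation_offset_fraction=float(entry.get("activation_offset_fraction", 0.0)),
        )

    def valve(name: str) -> ValveParameters:
        entry = registry[f"valves.{name}"]
        return ValveParameters(
            forward_resistance=float(entry["forward_resistance"]),
            leak_conductance=float(entry.get("leak_conductance", 0.0)),
            smoothing=float(entry.get("smoothing", 0.02)),
        )

    node_class = {
        "aorta": "systemic_arterial",
        "svc_veins": "systemic_venous",
        "ivc_veins": "systemic_venous",
        "conduit": "fontan_pathway",
        "pulmonary_arteries": "pulmonary_arterial",
        "pulmonary_veins": "pulmonary_venous",
    }
    nodes = [Node(name, node_class[name], compartment=comps[name]) for name in required]
    nodes.append(Node("atrium", "atrium", chamber=chamber("atrium")))
    nodes.append(Node("ventricle", "ventricle", chamber=chamber("ventricle")))

    svr = float(registry["svr"]) * config.svr_ratio
    pvr = float(registry["pvr"]) * config.pvr_ratio

    edges: list[Edge] = [
        Edge("mitral_valve", "atrium", "ventricle", kind="valve", valve=valve("mitral")),
        Edge("aortic_valve", "ventricle", "aorta", kind="valve", valve=valve("aortic")),
    ]

    beds = registry["beds"]
    total_fraction = sum(float(b["fraction"]) for b in beds.values())
    if abs(total_fraction - 1.0) > 1e-9:
        raise TopologyError(f"systemic bed fractions must sum to 1, got {total_fraction}")
    valid_targets = set(node_class) | {"atrium"}
    for bed_name, bed in beds.items():
        target = bed["drains_to"]
        if target not in valid_targets:
            raise TopologyError(f"registry gap: bed {bed_name!r} drains to unknown "
                                f"compartment {target!r}")
        edges.append(Edge(
            name=f"bed_{bed_name}",
            source="aorta",
            target=target,
            resistance=svr / float(bed["fraction"]) * float(bed.get("r_multiplier", 1.0)),
            is_bed=True,
        ))

    split = registry["pulmonary_split"]
    af, vf = float(split["arterial_fraction"]), float(split["venous_fraction"])
    if abs(af + vf - 1.0) > 1e-9:
        raise TopologyError("pulmonary_split fractions must sum to 1")
    edges += [
        Edge("svc_to_pa", "svc_veins", "pulmonary_arteries",
             resistance=comps["svc_veins"].resistance,
             inertance=comps["svc_veins"].inertance),
        Edge("ivc_to_conduit", "ivc_veins", "conduit",
             resistance=comps["ivc_veins"].resistance,
             inertance=comps["ivc_veins"].inertance),
        Edge("conduit_to_pa", "conduit", "pulmonary_arteries",
             resistance=comps["conduit"].resistance,
             inertance=comps["conduit"].inertance),
        # two parallel pulmonary branches between the TCPC junction and the
        # pulmonary veins; each carries half the flow so each gets twice the
        # aggregate arterial-side resistance
        Edge("right_pulmonary_branch", "pulmonary_arteries", "pulmonary_veins",
             resistance=2.0 * af * pvr, is_pulmonary_capillary=True),
        Edge("left_pulmonary_branch", "pulmonary_arteries", "pulmonary_veins",
             resistance=2.0 * af * pvr, is_pulmonary_capillary=True),
        Edge("pv_to_atrium", "pulmonary_veins", "atrium", resistance=vf * pvr),
    ]

    init_doc = registry["initial_pressures"]
    class_for_init = dict(node_class, atrium="atrium", ventricle="ventricle")
    init_key = {
        "systemic_arterial": "arterial",
        "systemic_venous": "systemic_venous",
        "fontan_pathway": "fontan_pathway",
        "pulmonary_arterial": "fontan_pathway",
        "pulmonary_venous": "pulmonary_venous",
        "atrium": "atrium",
        "ventricle": "ventricle",
    }
    initial_pressures = {
        name: float(init_doc[init_key[cls]]) for name, cls in class_for_init.items()
    }

    topology = Topology(nodes=tuple(nodes), edges=tuple(edges),
                        initial_pressures=initial_pressures)

    shunt_doc = registry["shunts"]
    enabled = []
    if config.fenestration_enabled:
        enabled.append("fenestration")
    if config.vvc_enabled:
        enabled.append("vvc")
    if config.apc_enabled:
        enabled.append("apc")
    for key in enabled:
        entry = shunt_doc[key]
        shunt = ShuntParameters(
            kind="VVC" if key == "vvc" else "APC" if key == "apc" else "fenestration",
            source_node=entry["source"],
            target_node=entry["target"],
            conductance=float(entry["conductance"]),
            exponent=float(entry.get("exponent", 1.0)),
        )
        topology = attach_shunt(topology, shunt)
    return topology


def validate_topology(topology: Topology) -> list[str]:
    """Diagnostic report: a list of violations, empty iff the topology is valid.

    Checks connectivity (every node on a directed cycle through the
    ventricle), the TCPC constraint (cavae drain to the pulmonary artery and
    never directly into the atrium), shunt endpoint rules, and parameter
    positivity.
    """
    report: list[str] = []
    g = topology.graph()

    if "ventricle" in g:
        und_ok = nx.is_weakly_connected(g) if len(g) else False
        if not und_ok:
            report.append("disconnection: network is not connected")
        else:
            for scc in nx.strongly_connected_components(g):
                if "ventricle" in scc:
                    outside = set(g) - scc
                    for name in sorted(outside):
                        report.append(
                            f"disconnection: node {name!r} is not on a directed cycle "
                            "through the ventricle"
                        )
    else:
        report.append("disconnection: no ventricle node")

    caval = {n.name for n in topology.nodes
             if n.node_class in ("systemic_venous", "fontan_pathway")}
    pa_nodes = {n.name for n in topology.nodes if n.node_class == "pulmonary_arterial"}
    reaches_pa = False
    for e in topology.edges:
        if e.source in caval and e.target in pa_nodes:
            reaches_pa = True
        if e.source in caval and e.target == "atrium":
            if not (e.kind == "shunt" and e.shunt is not None
                    and e.shunt.kind == "fenestration"):
                report.append(
                    f"TCPC breach: edge {e.name!r} connects caval node {e.source!r} "
                    "directly to the atrium"
                )
    if caval and pa_nodes and not reaches_pa:
        report.append("TCPC breach: no caval compartment drains to the pulmonary artery")

    for n in topology.nodes:
        if n.compartment is not None and n.compartment.compliance <= 0:
            report.append(f"parameter: compartment {n.name!r} has non-positive compliance")
    for e in topology.edges:
        if e.kind == "resistive" and e.resistance < 0:
            report.append(f"parameter: edge {e.name!r} has negative resistance")
        if e.kind == "shunt" and e.shunt is not None:
            if e.shunt.conductance < 0:
                report.append(f"parameter: shunt {e.name!r} has negative conductance")
            if not _shunt_endpoints_valid(topology.nodes, e.shunt):
                report.append(f"shunt rule: edge {e.name!r} has kind-inconsistent endpoints")
    return report


# -- serialization -----------------------------------------------------------

def topology_to_dict(topology: Topology) -> dict:
    def node_doc(n: Node) -> dict:
        doc: dict = {"name": n.name, "node_class": n.node_class}
        if n.compartment is not None:
            c = n.compartment
            doc["compartment"] = {
                "resistance": c.resistance, "compliance": c.compliance,
                "inertance": c.inertance, "unstressed_volume": c.unstressed_volume,
            }
        if n.chamber is not None:
            doc["chamber"] = {k: getattr(n.chamber, k)
                              for k in ChamberParameters.__dataclass_fields__}
        return doc

    def edge_doc(e: Edge) -> dict:
        doc: dict = {
            "name": e.name, "source": e.source, "target": e.target, "kind": e.kind,
            "resistance": e.resistance, "inertance": e.inertance,
            "is_bed": e.is_bed, "is_pulmonary_capillary": e.is_pulmonary_capillary,
        }
        if e.valve is not None:
            doc["valve"] = {k: getattr(e.valve, k)
                            for k in ValveParameters.__dataclass_fields__}
        if e.shunt is not None:
            doc["shunt"] = {k: getattr(e.shunt, k)
                            for k in ShuntParameters.__dataclass_fields__}
        return doc

    return {
        "nodes": [node_doc(n) for n in topology.nodes],
        "edges": [edge_doc(e) for e in topology.edges],
        "initial_pressures": dict(topology.initial_pressures),
    }


def topology_from_dict(doc: Mapping) -> Topology:
    nodes = []
    for nd in doc["nodes"]:
        comp = nd.get("compartment")
        cham = nd.get("chamber")
        nodes.append(Node(
            name=nd["name"],
            node_class=nd["node_class"],
            compartment=CompartmentParameters(name=nd["name"], **comp) if comp else None,
            chamber=ChamberParameters(**cham) if cham else None,
        ))
    edges = []
    for ed in doc["edges"]:
        edges.append(Edge(
            name=ed["name"], source=ed["source"], target=ed["target"], kind=ed["kind"],
            resistance=ed.get("resistance", 0.0), inertance=ed.get("inertance", 0.0),
            valve=ValveParameters(**ed["valve"]) if ed.get("valve") else None,
            shunt=ShuntParameters(**ed["shunt"]) if ed.get("shunt") else None,
            is_bed=ed.get("is_bed", False),
            is_pulmonary_capillary=ed.get("is_pulmonary_capillary", False),
        ))
    return Topology(nodes=tuple(nodes), edges=tuple(edges),
                    initial_pressures=doc.get("initial_pressures", {}))


def topology_to_yaml(topology: Topology) -> str:
    return yaml.safe_dump(topology_to_dict(topology), sort_keys=False)


def topology_from_yaml(text: str) -> Topology:
    return topology_from_dict(yaml.safe_load(text))
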