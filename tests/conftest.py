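"""Shared fixtures: toy circuits, the default Fontan topology, and cached
scenario runs (session-scoped so the expensive limit-cycle integrations are
shared across test modules)."""

import numpy as np
import pytest
from hypothesis import settings

import fontansim as fs

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from fontansim.hemodynamics import MeanHemodynamics
from fontansim.vascular_network import (CompartmentParameters, Edge, Node,
                                        ShuntParameters, Topology)


@pytest.fixture(scope="session")
def registry():
    return fs.default_registry()


@pytest.fixture(scope="session")
def fontan_topology(registry):
    return fs.build_fontan_topology(fs.ScenarioConfig(), registry)


@pytest.fixture(scope="session")
def fontan_topology_all_shunts(registry):
    return fs.build_fontan_topology(
        fs.ScenarioConfig(vvc_enabled=True, apc_enabled=True), registry)


def make_rc_loop(ra=1.0, rb=2.0, c1=1.5, c2=3.0, p1=20.0, p2=5.0,
                 la=0.0) -> Topology:
    """Two-compartment resistive loop with a closed-form relaxation rate."""
    nodes = (
        Node("n1", "systemic_arterial",
             compartment=CompartmentParameters("n1", resistance=0.0, compliance=c1)),
        Node("n2", "systemic_venous",
             compartment=CompartmentParameters("n2", resistance=0.0, compliance=c2)),
    )
    edges = (
        Edge("a", "n1", "n2", resistance=ra, inertance=la),
        Edge("b", "n2", "n1", resistance=rb),
    )
    return Topology(nodes=nodes, edges=edges,
                    initial_pressures={"n1": p1, "n2": p2})


@pytest.fixture
def rc_loop():
    return make_rc_loop()


def make_mixing_chain() -> Topology:
    """Open-loop style mixing fixture: one bed, one pulmonary-capillary edge,
    one venovenous shunt into the pulmonary veins."""
    def comp(name):
        return CompartmentParameters(name, resistance=0.0, compliance=1.0)

    nodes = (
        Node("aorta", "systemic_arterial", compartment=comp("aorta")),
        Node("ivc_veins", "systemic_venous", compartment=comp("ivc_veins")),
        Node("pulmonary_arteries", "pulmonary_arterial",
             compartment=comp("pulmonary_arteries")),
        Node("pulmonary_veins", "pulmonary_venous",
             compartment=comp("pulmonary_veins")),
        Node("atrium", "atrium", compartment=comp("atrium")),
        Node("ventricle", "ventricle", compartment=comp("ventricle")),
    )
    edges = (
        Edge("bed", "aorta", "ivc_veins", resistance=1.0, is_bed=True),
        Edge("ivc_to_pa", "ivc_veins", "pulmonary_arteries", resistance=1.0),
        Edge("cap", "pulmonary_arteries", "pulmonary_veins", resistance=1.0,
             is_pulmonary_capillary=True),
        Edge("vvc", "ivc_veins", "pulmonary_veins", kind="shunt",
             shunt=ShuntParameters("VVC", "ivc_veins", "pulmonary_veins", 1.0)),
        Edge("pv_to_atrium", "pulmonary_veins", "atrium", resistance=1.0),
        Edge("mitral", "atrium", "ventricle", resistance=1.0),
        Edge("aortic", "ventricle", "aorta", resistance=1.0),
    )
    return Topology(nodes=nodes, edges=edges)


def mixing_mean(vvc_fraction=0.1, total=100.0) -> MeanHemodynamics:
    """Balanced mean flows (mL/s) for the mixing chain with the VVC carrying
    the given fraction of pulmonary venous inflow."""
    q_vvc = vvc_fraction * total
    flows = {"bed": total, "ivc_to_pa": total - q_vvc, "cap": total - q_vvc,
             "vvc": q_vvc, "pv_to_atrium": total, "mitral": total,
             "aortic": total}
    return MeanHemodynamics(node_pressures={}, edge_flows=flows,
                            co=total * 0.06, net_co=total * 0.06, heart_rate=80.0)


@pytest.fixture
def mixing_chain():
    return make_mixing_chain()


# session-scoped scenario runs shared by metric, runner and acceptance tests

@pytest.fixture(scope="session")
def baseline_result():
    """No-collateral baseline (fenestration open)."""
    return fs.run_scenario(fs.ScenarioConfig())


@pytest.fixture(scope="session")
def collateral_result():
    """VVC + APC at baseline resistances."""
    return fs.run_scenario(fs.ScenarioConfig(vvc_enabled=True, apc_enabled=True))


@pytest.fixture(scope="session")
def dobutamine_result():
    """VVC + APC with dobutamine 10 ug/kg/min."""
    return fs.run_scenario(fs.ScenarioConfig(vvc_enabled=True, apc_enabled=True,
                                             dobutamine_dose=10.0))
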