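"""Topology assembly, shunt endpoint rules, validation, serialization."""

import pytest

import fontansim as fs
from fontansim.vascular_network import (ShuntParameters, Topology, TopologyError,
                                        attach_shunt, build_fontan_topology,
                                        topology_from_yaml, topology_to_yaml,
                                        validate_topology)


class TestBuildFontanTopology:
    def test_no_shunt_flags_give_shuntless_network(self, registry):
        topo = build_fontan_topology(
            fs.ScenarioConfig(fenestration_enabled=False), registry)
        assert topo.shunts == ()
        assert validate_topology(topo) == []

    def test_all_shunts_attached_with_consistent_endpoints(self, registry):
        topo = build_fontan_topology(
            fs.ScenarioConfig(vvc_enabled=True, apc_enabled=True), registry)
        kinds = {e.shunt.kind: e for e in topo.shunts}
        assert set(kinds) == {"VVC", "APC", "fenestration"}
        assert kinds["fenestration"].source == "conduit"
        assert kinds["fenestration"].target == "atrium"
        assert kinds["APC"].source == "aorta"
        assert kinds["APC"].target == "pulmonary_arteries"
        assert validate_topology(topo) == []

    def test_tcpc_constraint_holds(self, fontan_topology):
        # both cavae reach the pulmonary artery, never the atrium directly
        targets = {e.target for e in fontan_topology.edges
                   if e.source in ("svc_veins", "conduit") and e.kind != "shunt"}
        assert targets == {"pulmonary_arteries"}

    def test_registry_gap_raises_naming_the_bed(self, registry):
        broken = registry.updated(
            {"beds.upper_body.drains_to": "no_such_compartment"})
        with pytest.raises(TopologyError, match="upper_body"):
            build_fontan_topology(fs.ScenarioConfig(), broken)

    def test_closed_loop_through_ventricle(self, fontan_topology_all_shunts):
        import networkx as nx
        g = fontan_topology_all_shunts.graph()
        scc = max(nx.strongly_connected_components(g), key=len)
        assert scc == set(g.nodes)


class TestAttachShunt:
    def test_vvc_to_pulmonary_vein_accepted(self, fontan_topology):
        shunt = ShuntParameters("VVC", "ivc_veins", "pulmonary_veins", 1.0)
        topo = attach_shunt(fontan_topology, shunt)
        assert any(e.shunt == shunt for e in topo.shunts)
        # original unchanged
        assert all(e.shunt != shunt for e in fontan_topology.shunts)

    def test_vvc_to_atrium_also_valid(self, fontan_topology):
        shunt = ShuntParameters("VVC", "ivc_veins", "atrium", 1.0)
        assert attach_shunt(fontan_topology, shunt)

    def test_vvc_from_aorta_rejected(self, fontan_topology):
        with pytest.raises(TopologyError, match="VVC"):
            attach_shunt(fontan_topology,
                         ShuntParameters("VVC", "aorta", "pulmonary_veins", 1.0))

    def test_unknown_endpoint_rejected(self, fontan_topology):
        with pytest.raises(TopologyError, match="nowhere"):
            attach_shunt(fontan_topology,
                         ShuntParameters("VVC", "nowhere", "pulmonary_veins", 1.0))

    def test_zero_conductance_accepted(self, fontan_topology):
        shunt = ShuntParameters("APC", "aorta", "pulmonary_arteries", 0.0)
        topo = attach_shunt(fontan_topology, shunt)
        assert topo.edge("apc").shunt.conductance == 0.0

    def test_attachment_order_independent(self, fontan_topology):
        vvc = ShuntParameters("VVC", "ivc_veins", "pulmonary_veins", 1.0)
        apc = ShuntParameters("APC", "aorta", "pulmonary_arteries", 0.2)
        ab = attach_shunt(attach_shunt(fontan_topology, vvc), apc)
        ba = attach_shunt(attach_shunt(fontan_topology, apc), vvc)
        assert ab == ba

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            ShuntParameters("VVC", "a", "b", -1.0)


class TestValidateTopology:
    def test_builtin_topology_clean(self, fontan_topology_all_shunts):
        assert validate_topology(fontan_topology_all_shunts) == []

    def test_caval_to_atrium_edge_flagged(self, fontan_topology):
        from dataclasses import replace
        from fontansim.vascular_network import Edge
        bad = replace(fontan_topology, edges=fontan_topology.edges + (
            Edge("svc_leak", "svc_veins", "atrium", resistance=1.0),))
        report = validate_topology(bad)
        assert any("TCPC breach" in line for line in report)

    def test_nonpositive_compliance_flagged(self, rc_loop):
        with pytest.raises(ValueError, match="compliance"):
            from fontansim.vascular_network import CompartmentParameters
            CompartmentParameters("bad", resistance=0.1, compliance=0.0)

    def test_disconnected_node_flagged(self, fontan_topology):
        from dataclasses import replace
        from fontansim.vascular_network import (CompartmentParameters, Node)
        orphan = Node("orphan", "systemic_venous",
                      compartment=CompartmentParameters("orphan", 0.1, 1.0))
        bad = replace(fontan_topology, nodes=fontan_topology.nodes + (orphan,))
        report = validate_topology(bad)
        assert any("disconnection" in line for line in report)


def test_topology_yaml_roundtrip(fontan_topology_all_shunts):
    text = topology_to_yaml(fontan_topology_all_shunts)
    assert topology_from_yaml(text) == fontan_topology_all_shunts
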