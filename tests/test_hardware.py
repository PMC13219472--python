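import itertools

import numpy as np
import pytest

from chemxdl.hardware import (Capabilities, GraphError, HardwareEdge,
                              HardwareGraph, HardwareNode, MappingError,
                              derive_requirements, find_transfer_path,
                              load_graph, map_vessels, node_satisfies,
                              save_graph)
from chemxdl.synth import (random_mapping_instance, standard_graph)
from chemxdl.units import Quantity
from chemxdl.xdl_core import HardwareDecl, ReagentDecl, XDLDocument, XDLStep

FOUR_NODE = """{
  "nodes": [
    {"id": "reactor1", "class": "reactor", "max_volume": 100,
     "temp_range": [-20, 150]},
    {"id": "pump1", "class": "pump"},
    {"id": "flask1", "class": "flask", "max_volume": 250},
    {"id": "waste1", "class": "waste"}
  ],
  "edges": [
    {"source": "flask1", "target": "pump1"},
    {"source": "pump1", "target": "reactor1"},
    {"source": "reactor1", "target": "waste1"}
  ]
}"""


def test_load_graph_counts_and_roundtrip():
    graph = load_graph(FOUR_NODE)
    assert len(graph.nodes) == 4 and len(graph.edges) == 3
    again = load_graph(save_graph(graph))
    assert again == graph


def test_dangling_edge_names_the_node():
    bad = FOUR_NODE.replace('"target": "pump1"', '"target": "pump9"', 1)
    with pytest.raises(GraphError) as exc:
        load_graph(bad)
    assert "pump9" in str(exc.value)


def test_unknown_node_class_rejected():
    with pytest.raises(GraphError):
        load_graph('{"nodes": [{"id": "x", "class": "teleporter"}], "edges": []}')


def test_transfer_path_through_pump():
    graph = load_graph(FOUR_NODE)
    assert find_transfer_path(graph, "flask1", "reactor1") == \
        ["flask1", "pump1", "reactor1"]
    # interior liquid node blocks: reactor1 is not a backbone node
    assert find_transfer_path(graph, "flask1", "waste1") is None


def test_path_symmetry_on_bidirectional_graphs(rng):
    for _ in range(20):
        _, graph = random_mapping_instance(rng)
        ids = [n.id for n in graph.nodes]
        a, b = rng.choice(ids, size=2, replace=False)
        fwd = find_transfer_path(graph, str(a), str(b)) is not None
        rev = find_transfer_path(graph, str(b), str(a)) is not None
        assert fwd == rev


def _doc(steps, vessels=("reactor",)):
    return XDLDocument(
        [HardwareDecl(v, "reactor") for v in vessels],
        [ReagentDecl("water", "water", "solvent")], steps)


def test_derive_requirements_temperature_union_and_peak_volume():
    doc = _doc([
        XDLStep("Add", {"vessel": "reactor", "reagent": "water",
                        "volume": Quantity(10, "mL", "volume")}),
        XDLStep("Add", {"vessel": "reactor", "reagent": "water",
                        "volume": Quantity(15, "mL", "volume")}),
        XDLStep("HeatChill", {"vessel": "reactor",
                              "temp": Quantity(50, "°C", "temperature"),
                              "time": Quantity(5, "min", "time")}),
        XDLStep("HeatChill", {"vessel": "reactor",
                              "temp": Quantity(100, "°C", "temperature"),
                              "time": Quantity(5, "min", "time")}),
    ])
    (req,) = derive_requirements(doc)
    assert req.temp_range == (50.0, 100.0)
    assert req.stir_range is None  # no stir steps anywhere
    assert req.min_volume == pytest.approx(25.0)


def test_single_feasible_assignment():
    doc = _doc([XDLStep("HeatChill", {
        "vessel": "reactor", "temp": Quantity(100, "°C", "temperature"),
        "time": Quantity(5, "min", "time")})])
    graph = standard_graph()
    mapping = map_vessels(doc, graph)
    (req,) = derive_requirements(doc)
    assert node_satisfies(graph.node(mapping.assignment["reactor"]), req) is None


def test_pigeonhole_infeasibility_lists_vessels():
    doc = _doc([
        XDLStep("Add", {"vessel": "a", "reagent": "water",
                        "volume": Quantity(5, "mL", "volume")}),
        XDLStep("Add", {"vessel": "b", "reagent": "water",
                        "volume": Quantity(5, "mL", "volume")}),
    ], vessels=("a", "b"))
    graph = HardwareGraph(
        [HardwareNode("only", "reactor", Capabilities(max_volume=100.0)),
         HardwareNode("valve1", "valve")],
        [HardwareEdge("only", "valve1")])
    with pytest.raises(MappingError) as exc:
        map_vessels(doc, graph)
    failed = {v for v, _ in exc.value.failures}
    assert failed == {"a", "b"}


@pytest.mark.parametrize("chunk", range(4))
def test_mapping_matches_bruteforce_enumeration(chunk):
    """Feasibility (and returned-assignment validity) equals exhaustive
    enumeration over all injective vessel→node assignments."""
    for seed in range(chunk * 25, (chunk + 1) * 25):
        doc, graph = random_mapping_instance(np.random.default_rng(seed))
        reqs = derive_requirements(doc)
        liquid = sorted(graph.liquid_nodes, key=lambda n: n.id)
        brute = any(
            all(node_satisfies(n, r) is None for n, r in zip(perm, reqs))
            for perm in itertools.permutations(liquid, len(reqs))
        )
        try:
            mapping = map_vessels(doc, graph)
            assert brute, f"seed {seed}: search found mapping, oracle did not"
            assert len(set(mapping.assignment.values())) == len(reqs)
            for req in reqs:  # independent requirement re-check
                node = graph.node(mapping.assignment[req.vessel_id])
                assert node_satisfies(node, req) is None
        except MappingError:
            assert not brute, f"seed {seed}: oracle feasible, search failed"
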