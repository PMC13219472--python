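"""Hardware graphs: model, JSON I/O, transfer paths, and vessel mapping.

A hardware graph describes a physical robotic platform as
capability-annotated nodes (reactors, flasks, separators, pumps, valves,
waste) connected by tubing edges.  Abstract vessels of an XDL document
are mapped onto physical nodes by a backtracking search over the
requirements each vessel accumulates from the procedure (temperatures,
stir rates, peak volume, filtration/separation/evaporation capability).

Liquid transfers are legal only along a path whose interior nodes are
pumps or valves — the syringe-pump backbone architecture.  Multi-leg
transfers via buffer flasks are deliberately out of scope.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .xdl_core import XDLDocument

LIQUID_CLASSES = ("reactor", "flask", "separator", "rotavap", "filter", "cartridge")
NODE_CLASSES = LIQUID_CLASSES + ("pump", "valve", "waste")
_BACKBONE = ("pump", "valve")


class GraphError(ValueError):
    pass


@dataclass(frozen=True)
class Capabilities:
    """Optional capability bundle of a physical node."""

    temp_range: Optional[Tuple[float, float]] = None  # °C
    stir_range: Optional[Tuple[float, float]] = None  # rpm
    max_volume: Optional[float] = None  # mL
    can_filter: bool = False
    can_separate: bool = False
    can_evaporate: bool = False

    def __post_init__(self) -> None:
        for rng in (self.temp_range, self.stir_range):
            if rng is not None and rng[0] > rng[1]:
                raise GraphError(f"capability range {rng} has min > max")
        if self.max_volume is not None and self.max_volume <= 0:
            raise GraphError("max_volume must be positive")


@dataclass(frozen=True)
class HardwareNode:
    id: str
    node_class: str
    capabilities: Capabilities = field(default_factory=Capabilities)

    @property
    def holds_liquid(self) -> bool:
        return self.node_class in LIQUID_CLASSES


@dataclass(frozen=True)
class HardwareEdge:
    source: str
    target: str
    bidirectional: bool = True


@dataclass
class HardwareGraph:
    nodes: List[HardwareNode] = field(default_factory=list)
    edges: List[HardwareEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise GraphError("duplicate node ids in hardware graph")
        byid = set(ids)
        for e in self.edges:
            if e.source == e.target:
                raise GraphError(f"self-loop edge on '{e.source}'")
            for end in (e.source, e.target):
                if end not in byid:
                    raise GraphError(
                        f"edge {e.source}->{e.target} references unknown node '{end}'")

    def node(self, node_id: str) -> HardwareNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise GraphError(f"unknown node '{node_id}'")

    def to_networkx(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id, node_class=n.node_class)
        for e in self.edges:
            g.add_edge(e.source, e.target)
            if e.bidirectional:
                g.add_edge(e.target, e.source)
        return g

    @property
    def liquid_nodes(self) -> List[HardwareNode]:
        return [n for n in self.nodes if n.holds_liquid]


# --------------------------------------------------------------------------
# JSON I/O — top-level {"nodes": [...], "edges": [...]}


def _caps_from_json(raw: Mapping) -> Capabilities:
    def pair(key: str) -> Optional[Tuple[float, float]]:
        v = raw.get(key)
        return (float(v[0]), float(v[1])) if v is not None else None

    return Capabilities(
        temp_range=pair("temp_range"),
        stir_range=pair("stir_range"),
        max_volume=float(raw["max_volume"]) if raw.get("max_volume") is not None else None,
        can_filter=bool(raw.get("can_filter", False)),
        can_separate=bool(raw.get("can_separate", False)),
        can_evaporate=bool(raw.get("can_evaporate", False)),
    )


def load_graph(text: str) -> HardwareGraph:
    """Parse a hardware graph from its JSON source."""
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GraphError(f"malformed graph JSON: {exc}") from exc
    nodes = []
    for n in raw.get("nodes", []):
        cls = n.get("class", n.get("node_class"))
        if cls not in NODE_CLASSES:
            raise GraphError(f"unknown node class '{cls}' for node '{n.get('id')}'")
        nodes.append(HardwareNode(n["id"], cls, _caps_from_json(n)))
    edges = [
        HardwareEdge(e["source"], e["target"], bool(e.get("bidirectional", True)))
        for e in raw.get("edges", [])
    ]
    return HardwareGraph(nodes, edges)


def save_graph(graph: HardwareGraph) -> str:
    def node_json(n: HardwareNode) -> Dict:
        c = n.capabilities
        out: Dict = {"id": n.id, "class": n.node_class}
        if c.temp_range is not None:
            out["temp_range"] = list(c.temp_range)
        if c.stir_range is not None:
            out["stir_range"] = list(c.stir_range)
        if c.max_volume is not None:
            out["max_volume"] = c.max_volume
        for flag in ("can_filter", "can_separate", "can_evaporate"):
            if getattr(c, flag):
                out[flag] = True
        return out

    return json.dumps(
        {
            "nodes": [node_json(n) for n in graph.nodes],
            "edges": [
                {"source": e.source, "target": e.target,
                 "bidirectional": e.bidirectional}
                for e in graph.edges
            ],
        },
        indent=2,
    )


# --------------------------------------------------------------------------
# Transfer paths


def find_transfer_path(
    graph: HardwareGraph, src: str, dst: str
) -> Optional[List[str]]:
    """Shortest directed path from *src* to *dst* whose interior nodes are
    pumps or valves, or ``None`` when no such path exists."""
    graph.node(src), graph.node(dst)  # raise on unknown ids
    if src == dst:
        return [src]
    g = graph.to_networkx()
    # BFS expanding only through backbone nodes
    prev: Dict[str, str] = {}
    queue = deque([src])
    seen = {src}
    while queue:
        cur = queue.popleft()
        for nxt in g.successors(cur):
            if nxt in seen:
                continue
            seen.add(nxt)
            prev[nxt] = cur
            if nxt == dst:
                path = [dst]
                while path[-1] != src:
                    path.append(prev[path[-1]])
                return path[::-1]
            if g.nodes[nxt]["node_class"] in _BACKBONE:
                queue.append(nxt)
    return None


# --------------------------------------------------------------------------
# Requirements and mapping


@dataclass
class VesselRequirements:
    """Union of constraints a procedure places on one abstract vessel."""

    vessel_id: str
    vessel_class: str = "reactor"
    temp_range: Optional[Tuple[float, float]] = None  # °C needed coverage
    stir_range: Optional[Tuple[float, float]] = None  # rpm needed coverage
    min_volume: float = 0.0  # peak volume lower bound, mL
    needs_filter: bool = False
    needs_separate: bool = False
    needs_evaporate: bool = False


def derive_requirements(doc: XDLDocument) -> List[VesselRequirements]:
    """Infer per-vessel requirements from the procedure steps.

    Temperatures and stir rates are the min/max over all values requested
    in steps acting on the vessel; the peak-volume bound comes from the
    volume ledger; capability flags follow the step semantics
    (Filter/WashSolid/Dry need filtration, Separate's source needs phase
    separation, Evaporate needs reduced-pressure evaporation).
    """
    from .simulator import volume_ledger  # local import avoids a cycle
    from .xdl_core import expand_procedure

    reqs = {
        h.id: VesselRequirements(h.id, h.vessel_class) for h in doc.hardware
    }

    def widen(req: VesselRequirements, attr: str, value: float) -> None:
        cur = getattr(req, attr)
        rng = (value, value) if cur is None else (min(cur[0], value), max(cur[1], value))
        setattr(req, attr, rng)

    for step in expand_procedure(doc):
        attrs = step.attributes
        temp = step.get_quantity("temp")
        for key in ("vessel", "from_vessel", "to_vessel"):
            vid = attrs.get(key)
            if not isinstance(vid, str) or vid not in reqs:
                continue
            req = reqs[vid]
            if temp is not None and key == "vessel":
                widen(req, "temp_range", temp.to_base())
            speed = step.get_quantity("stir_speed")
            if speed is not None:
                widen(req, "stir_range", speed.to_base())
            if step.step_name in ("Filter", "WashSolid", "Dry") and key == "vessel":
                req.needs_filter = True
            if step.step_name == "Separate" and key == "from_vessel":
                req.needs_separate = True
            if step.step_name == "Evaporate" and key == "vessel":
                req.needs_evaporate = True

    ledger = volume_ledger(doc)
    for vid, entry in ledger.volumes.items():
        if vid in reqs:
            reqs[vid].min_volume = entry.peak
    return [reqs[h.id] for h in doc.hardware]


def node_satisfies(node: HardwareNode, req: VesselRequirements) -> Optional[str]:
    """Return None when *node* can host *req*, else the first failed requirement."""
    if not node.holds_liquid:
        return f"node class '{node.node_class}' cannot hold liquids"
    c = node.capabilities
    if req.temp_range is not None:
        if c.temp_range is None:
            return f"needs temperature control {req.temp_range} but node has none"
        if c.temp_range[0] > req.temp_range[0] or c.temp_range[1] < req.temp_range[1]:
            return (f"needs temperature range {req.temp_range} °C, node offers "
                    f"{c.temp_range}")
    if req.stir_range is not None:
        if c.stir_range is None:
            return f"needs stirring {req.stir_range} rpm but node cannot stir"
        if c.stir_range[0] > req.stir_range[0] or c.stir_range[1] < req.stir_range[1]:
            return f"needs stir range {req.stir_range} rpm, node offers {c.stir_range}"
    if req.min_volume > 0:
        if c.max_volume is None or c.max_volume < req.min_volume - 1e-9:
            return (f"needs capacity >= {req.min_volume:g} mL, node offers "
                    f"{c.max_volume}")
    for flag, label in (("needs_filter", "can_filter"),
                        ("needs_separate", "can_separate"),
                        ("needs_evaporate", "can_evaporate")):
        if getattr(req, flag) and not getattr(c, label):
            return f"needs capability {label}"
    return None


@dataclass
class VesselMapping:
    assignment: Dict[str, str]  # abstract vessel id -> physical node id

    def physical(self, vessel_id: str) -> Optional[str]:
        return self.assignment.get(vessel_id)


class MappingError(ValueError):
    """No feasible vessel→node assignment; lists each failure."""

    def __init__(self, failures: Sequence[Tuple[str, str]]):
        self.failures = list(failures)
        detail = "; ".join(f"{v}: {why}" for v, why in self.failures)
        super().__init__(f"no feasible vessel mapping: {detail}")


def map_vessels(
    doc: XDLDocument,
    graph: HardwareGraph,
    requirements: Optional[Sequence[VesselRequirements]] = None,
) -> VesselMapping:
    """Automatically map abstract vessels onto physical graph nodes.

    Backtracking search over vessels ordered most-constrained-first
    (fewest feasible candidate nodes), deterministic tie-break by
    lexicographic ids.  The assignment is injective and every assigned
    node satisfies the vessel's derived requirements; infeasibility
    raises :class:`MappingError` naming each unsatisfiable vessel.
    """
    reqs = list(requirements) if requirements is not None else derive_requirements(doc)
    candidates: Dict[str, List[str]] = {}
    failures: List[Tuple[str, str]] = []
    for req in reqs:
        feasible = []
        reasons = []
        for node in sorted(graph.liquid_nodes, key=lambda n: n.id):
            why = node_satisfies(node, req)
            if why is None:
                feasible.append(node.id)
            else:
                reasons.append(why)
        candidates[req.vessel_id] = feasible
        if not feasible:
            failures.append(
                (req.vessel_id, reasons[0] if reasons else "no liquid-holding nodes"))
    if failures:
        raise MappingError(failures)

    order = sorted(candidates, key=lambda v: (len(candidates[v]), v))
    assignment: Dict[str, str] = {}
    used: set = set()

    def backtrack(i: int) -> bool:
        if i == len(order):
            return True
        vid = order[i]
        for node_id in candidates[vid]:
            if node_id in used:
                continue
            assignment[vid] = node_id
            used.add(node_id)
            if backtrack(i + 1):
                return True
            used.discard(node_id)
            del assignment[vid]
        return False

    if not backtrack(0):
        raise MappingError(
            [(v, "no conflict-free assignment (too few distinct nodes)")
             for v in order])
    return VesselMapping(dict(assignment))
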