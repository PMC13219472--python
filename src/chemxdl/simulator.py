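"""Hardware-constrained, stateful simulation of an XDL procedure.

The simulator executes a mapped procedure step by step against the
capability envelope of the physical platform, checking temperature and
stir-rate ranges, vessel capacities, reagent availability and transfer
reachability.  Chemistry is deliberately not modelled — no reactions,
densities or kinetics — because the simulation validates *executability*,
not chemical outcome.  Mass-only additions are tracked as zero-volume
solids with a mass annotation.

Like the parser, the simulator continues after errors and collects all of
them, so one iteration of the repair loop receives the maximum feedback.
After an overflow the vessel is clamped at capacity so later steps remain
checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Tuple

from .hardware import HardwareGraph, HardwareNode, VesselMapping, find_transfer_path
from .units import Quantity
from .xdl_core import XDLDocument, XDLStep, expand_procedure

#: approximation used for "dropwise" additions/transfers, seconds
DEFAULT_DROPWISE_DURATION_S = 600.0

ERROR_CODES = (
    "TEMP_OUT_OF_RANGE",
    "STIR_RATE_OUT_OF_RANGE",
    "OVERFLOW",
    "UNREACHABLE_TRANSFER",
    "UNKNOWN_REAGENT",
    "INSUFFICIENT_VOLUME",
    "UNMAPPED_VESSEL",
)

_EPS = 1e-9


@dataclass
class VesselState:
    contents: List[Tuple[str, float]] = field(default_factory=list)  # (chemical, mL)
    solids: Dict[str, float] = field(default_factory=dict)  # chemical -> g
    temperature: float = 20.0  # °C, ambient start
    stir_rate: Optional[float] = None  # rpm, None = idle

    @property
    def total_volume(self) -> float:
        return sum(v for _, v in self.contents)

    def add(self, chemical: str, volume: float) -> None:
        if volume > 0:
            self.contents.append((chemical, volume))

    def remove(self, volume: float) -> float:
        """Remove up to *volume* mL proportionally across contents; returns
        the volume actually removed."""
        total = self.total_volume
        take = min(volume, total)
        if take <= 0 or total <= 0:
            return 0.0
        frac = take / total
        self.contents = [(c, v * (1 - frac)) for c, v in self.contents]
        self.contents = [(c, v) for c, v in self.contents if v > _EPS]
        return take

    def empty(self) -> float:
        total = self.total_volume
        self.contents = []
        return total


@dataclass(frozen=True)
class SimulationError:
    step_index: int
    code: str
    message: str


@dataclass
class SimulationReport:
    errors: List[SimulationError] = field(default_factory=list)
    unsupported: List[Tuple[int, str]] = field(default_factory=list)
    final_state: Dict[str, VesselState] = field(default_factory=dict)
    trace: List[Dict[str, float]] = field(default_factory=list)
    elapsed_model_time: float = 0.0  # seconds

    @property
    def passed(self) -> bool:
        return not self.errors


# --------------------------------------------------------------------------
# Volume ledger: independent pure arithmetic over the procedure


@dataclass
class VolumeEntry:
    peak: float = 0.0
    final: float = 0.0


@dataclass
class LedgerResult:
    volumes: Dict[str, VolumeEntry]
    insufficient: List[int] = field(default_factory=list)  # step indices
    total_added: float = 0.0
    total_removed: float = 0.0  # to waste / vapor


def volume_ledger(doc: XDLDocument) -> LedgerResult:
    """Pure arithmetic replay of the procedure's volume effects.

    Tracks per-vessel running, peak and final volumes over the expanded
    step sequence without any graph, state machinery or capacity checks.
    Serves as the independent cross-check of the simulator's bookkeeping
    and as the peak-volume source for requirement derivation.
    """
    cur: Dict[str, float] = {h.id: 0.0 for h in doc.hardware}
    peak: Dict[str, float] = dict(cur)
    result = LedgerResult({})

    def bump(vessel: str, delta: float) -> None:
        if vessel not in cur:
            return
        cur[vessel] = max(0.0, cur[vessel] + delta)
        peak[vessel] = max(peak[vessel], cur[vessel])

    for idx, step in enumerate(expand_procedure(doc)):
        a = step.attributes
        name = step.step_name
        if name == "Add":
            vol = step.get_quantity("volume")
            if vol is not None:
                bump(str(a.get("vessel")), vol.to_base())
                result.total_added += vol.to_base()
        elif name == "Transfer":
            src, dst = str(a.get("from_vessel")), str(a.get("to_vessel"))
            avail = cur.get(src, 0.0)
            vol = a.get("volume", "all")
            want = avail if vol == "all" or vol is None else vol.to_base()
            if want > avail + _EPS:
                result.insufficient.append(idx)
            moved = min(want, avail)
            bump(src, -moved)
            bump(dst, moved)
        elif name == "Separate":
            src, dst = str(a.get("from_vessel")), str(a.get("to_vessel"))
            sv = step.get_quantity("solvent_volume")
            if sv is not None:
                bump(src, sv.to_base())
                result.total_added += sv.to_base()
            moved = cur.get(src, 0.0)
            bump(src, -moved)
            bump(dst, moved)
        elif name in ("Evaporate", "Filter"):
            vessel = str(a.get("vessel"))
            gone = cur.get(vessel, 0.0)
            bump(vessel, -gone)
            result.total_removed += gone
        elif name == "WashSolid":
            vessel = str(a.get("vessel"))
            vol = step.get_quantity("volume")
            repeats = a.get("repeats", 1)
            repeats = repeats if isinstance(repeats, int) else 1
            if vol is not None:
                for _ in range(repeats):
                    bump(vessel, vol.to_base())
                    bump(vessel, -vol.to_base())
                    result.total_added += vol.to_base()
                    result.total_removed += vol.to_base()
        elif name == "Dissolve":
            vol = step.get_quantity("volume")
            if vol is not None:
                bump(str(a.get("vessel")), vol.to_base())
                result.total_added += vol.to_base()
    result.volumes = {
        v: VolumeEntry(peak=peak[v], final=cur[v]) for v in cur
    }
    return result


# --------------------------------------------------------------------------
# Step handlers


class _Sim:
    """Mutable simulation context shared by the step handlers."""

    def __init__(self, doc: XDLDocument, graph: HardwareGraph,
                 mapping: VesselMapping):
        self.doc = doc
        self.graph = graph
        self.mapping = mapping
        self.report = SimulationReport()
        self.states: Dict[str, VesselState] = {
            h.id: VesselState() for h in doc.hardware
        }
        self.reagent_ids = set(doc.reagent_ids)

    def error(self, idx: int, code: str, message: str) -> None:
        self.report.errors.append(SimulationError(idx, code, message))

    def node_for(self, idx: int, vessel: Optional[object]) -> Optional[HardwareNode]:
        vid = str(vessel) if vessel is not None else ""
        node_id = self.mapping.physical(vid)
        if node_id is None:
            self.error(idx, "UNMAPPED_VESSEL",
                       f"vessel '{vid}' has no physical node assignment")
            return None
        return self.graph.node(node_id)

    def check_temp(self, idx: int, step: XDLStep, node: Optional[HardwareNode]) -> None:
        temp = step.get_quantity("temp")
        if temp is None or node is None:
            return
        rng = node.capabilities.temp_range
        t = temp.to_base()
        if rng is None or not (rng[0] - _EPS <= t <= rng[1] + _EPS):
            self.error(idx, "TEMP_OUT_OF_RANGE",
                       f"{t:g} °C outside range {rng} of node '{node.id}'")

    def check_stir(self, idx: int, step: XDLStep, node: Optional[HardwareNode]) -> None:
        speed = step.get_quantity("stir_speed")
        if speed is None or node is None:
            return
        rng = node.capabilities.stir_range
        s = speed.to_base()
        if rng is None or not (rng[0] - _EPS <= s <= rng[1] + _EPS):
            self.error(idx, "STIR_RATE_OUT_OF_RANGE",
                       f"{s:g} rpm outside range {rng} of node '{node.id}'")

    def check_overflow(self, idx: int, vessel: str,
                       node: Optional[HardwareNode]) -> None:
        if node is None:
            return
        cap = node.capabilities.max_volume
        state = self.states[vessel]
        if cap is not None and state.total_volume > cap + _EPS:
            excess = state.total_volume - cap
            self.error(idx, "OVERFLOW",
                       f"vessel '{vessel}' at {state.total_volume:g} mL exceeds "
                       f"capacity {cap:g} mL of node '{node.id}'")
            state.remove(excess)  # clamp so later steps remain checkable

    def tick(self, step: XDLStep) -> None:
        t = step.get_quantity("time")
        if t is not None:
            self.report.elapsed_model_time += t.to_base()


Handler = Callable[[_Sim, XDLStep, int], None]


def _h_add(sim: _Sim, step: XDLStep, idx: int) -> None:
    a = step.attributes
    reagent = str(a.get("reagent", ""))
    if reagent not in sim.reagent_ids:
        sim.error(idx, "UNKNOWN_REAGENT", f"reagent '{reagent}' is not declared")
        return
    vessel = str(a.get("vessel", ""))
    node = sim.node_for(idx, vessel)
    if vessel not in sim.states:
        return
    vol = step.get_quantity("volume")
    mass = step.get_quantity("mass")
    if vol is not None:
        sim.states[vessel].add(reagent, vol.to_base())
        sim.check_overflow(idx, vessel, node)
    elif mass is not None:
        # mass-only addition: zero-volume solid, no 1 g/mL equivalence
        solids = sim.states[vessel].solids
        solids[reagent] = solids.get(reagent, 0.0) + mass.to_base()
    sim.tick(step)


def _h_transfer(sim: _Sim, step: XDLStep, idx: int) -> None:
    a = step.attributes
    src, dst = str(a.get("from_vessel", "")), str(a.get("to_vessel", ""))
    src_node = sim.node_for(idx, src)
    dst_node = sim.node_for(idx, dst)
    if src not in sim.states or dst not in sim.states:
        return
    if src_node is not None and dst_node is not None:
        if find_transfer_path(sim.graph, src_node.id, dst_node.id) is None:
            sim.error(idx, "UNREACHABLE_TRANSFER",
                      f"no pump/valve path from '{src_node.id}' to '{dst_node.id}'")
            return
    vol = a.get("volume", "all")
    avail = sim.states[src].total_volume
    want = avail if vol == "all" or vol is None else vol.to_base()
    if want > avail + _EPS:
        sim.error(idx, "INSUFFICIENT_VOLUME",
                  f"transfer of {want:g} mL requested but '{src}' holds {avail:g} mL")
    moved = sim.states[src].remove(min(want, avail))
    sim.states[dst].add(f"from:{src}", moved)
    sim.check_overflow(idx, dst, dst_node)
    sim.tick(step)


def _h_heatchill(sim: _Sim, step: XDLStep, idx: int) -> None:
    vessel = str(step.attributes.get("vessel", ""))
    node = sim.node_for(idx, vessel)
    sim.check_temp(idx, step, node)
    temp = step.get_quantity("temp")
    if vessel in sim.states and temp is not None:
        sim.states[vessel].temperature = temp.to_base()
    sim.tick(step)


def _h_stir(sim: _Sim, step: XDLStep, idx: int) -> None:
    vessel = str(step.attributes.get("vessel", ""))
    node = sim.node_for(idx, vessel)
    sim.check_stir(idx, step, node)
    speed = step.get_quantity("stir_speed")
    if vessel in sim.states:
        sim.states[vessel].stir_rate = speed.to_base() if speed else 250.0
    sim.tick(step)


def _h_stopstir(sim: _Sim, step: XDLStep, idx: int) -> None:
    vessel = str(step.attributes.get("vessel", ""))
    sim.node_for(idx, vessel)
    if vessel in sim.states:
        sim.states[vessel].stir_rate = None


def _h_wait(sim: _Sim, step: XDLStep, idx: int) -> None:
    sim.tick(step)


def _h_evaporate(sim: _Sim, step: XDLStep, idx: int) -> None:
    vessel = str(step.attributes.get("vessel", ""))
    node = sim.node_for(idx, vessel)
    sim.check_temp(idx, step, node)
    if vessel in sim.states:
        sim.states[vessel].empty()
    sim.tick(step)


def _h_filter(sim: _Sim, step: XDLStep, idx: int) -> None:
    vessel = str(step.attributes.get("vessel", ""))
    sim.node_for(idx, vessel)
    if vessel in sim.states:
        sim.states[vessel].empty()  # filtrate to waste; solid retained
    sim.tick(step)


def _h_washsolid(sim: _Sim, step: XDLStep, idx: int) -> None:
    a = step.attributes
    vessel = str(a.get("vessel", ""))
    node = sim.node_for(idx, vessel)
    vol = step.get_quantity("volume")
    repeats = a.get("repeats", 1)
    repeats = repeats if isinstance(repeats, int) else 1
    if vessel in sim.states and vol is not None:
        for _ in range(repeats):
            sim.states[vessel].add(str(a.get("solvent", "wash")), vol.to_base())
            sim.check_overflow(idx, vessel, node)
            sim.states[vessel].remove(vol.to_base())
    sim.tick(step)


def _h_separate(sim: _Sim, step: XDLStep, idx: int) -> None:
    a = step.attributes
    src, dst = str(a.get("from_vessel", "")), str(a.get("to_vessel", ""))
    sim.node_for(idx, src)
    dst_node = sim.node_for(idx, dst)
    if src not in sim.states or dst not in sim.states:
        return
    sv = step.get_quantity("solvent_volume")
    if sv is not None:
        sim.states[src].add(str(a.get("solvent", "solvent")), sv.to_base())
    moved = sim.states[src].empty()
    sim.states[dst].add(f"from:{src}", moved)
    sim.check_overflow(idx, dst, dst_node)
    sim.tick(step)


def _h_dissolve(sim: _Sim, step: XDLStep, idx: int) -> None:
    a = step.attributes
    vessel = str(a.get("vessel", ""))
    node = sim.node_for(idx, vessel)
    vol = step.get_quantity("volume")
    if vessel in sim.states and vol is not None:
        sim.states[vessel].add(str(a.get("solvent", "solvent")), vol.to_base())
        sim.check_overflow(idx, vessel, node)
    sim.tick(step)


def _h_passive(sim: _Sim, step: XDLStep, idx: int) -> None:
    vessel = str(step.attributes.get("vessel", ""))
    node = sim.node_for(idx, vessel)
    sim.check_temp(idx, step, node)
    sim.tick(step)


DEFAULT_HANDLERS: Dict[str, Handler] = {
    "Add": _h_add,
    "Transfer": _h_transfer,
    "HeatChill": _h_heatchill,
    "HeatChillToTemp": _h_heatchill,
    "Stir": _h_stir,
    "StartStir": _h_stir,
    "StopStir": _h_stopstir,
    "Wait": _h_wait,
    "Evaporate": _h_evaporate,
    "Filter": _h_filter,
    "WashSolid": _h_washsolid,
    "Dry": _h_passive,
    "Separate": _h_separate,
    "Dissolve": _h_dissolve,
    "Precipitate": _h_passive,
    # Repeat is expanded structurally, never handled directly
}


def register_step_handler(
    name: str, handler: Handler,
    handlers: Optional[Dict[str, Handler]] = None,
) -> Dict[str, Handler]:
    """Register a state-transition handler for a step name.

    Duplicate registration is an error; pass a copy of
    :data:`DEFAULT_HANDLERS` to extend the default set.
    """
    table = DEFAULT_HANDLERS if handlers is None else handlers
    if name in table:
        raise ValueError(f"handler for step '{name}' already registered")
    table[name] = handler
    return table


# --------------------------------------------------------------------------
# Entry point


def simulate(
    doc: XDLDocument,
    graph: HardwareGraph,
    mapping: VesselMapping,
    handlers: Optional[Mapping[str, Handler]] = None,
) -> SimulationReport:
    """Execute the procedure on the mapped hardware, collecting all errors.

    Constraint violations never raise — they are report entries — and the
    simulation continues past them so a repair iteration sees every
    problem at once.  Steps present in the document but lacking a handler
    are recorded as unsupported (roadmap harvest), not as errors.
    Deterministic: identical inputs yield identical reports.
    """
    table = dict(DEFAULT_HANDLERS if handlers is None else handlers)
    sim = _Sim(doc, graph, mapping)
    for idx, step in enumerate(expand_procedure(doc)):
        handler = table.get(step.step_name)
        if handler is None:
            sim.report.unsupported.append((idx, step.step_name))
        else:
            handler(sim, step, idx)
        sim.report.trace.append(
            {v: round(s.total_volume, 9) for v, s in sim.states.items()}
        )
    sim.report.final_state = {
        sim.mapping.physical(v) or v: state for v, state in sim.states.items()
    }
    return sim.report
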