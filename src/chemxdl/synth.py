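"""Synthetic fixtures: documents, graphs, seeded errors, scripted agents.

Real benchmark corpora (publication sets, theses, proprietary reaction
databases) are not redistributable, so every test input is generated
here: XDL documents with manifest-tracked seeded errors across all five
issue categories, random procedures for volume-ledger and vessel-mapping
oracles, hardware graphs, labelled non-executable-step templates for
clustering recovery, and a small paper-like fixture document with the
scripted agent responses that drive the end-to-end mock run.

All generators take an explicit ``numpy`` RNG (or a seed) — the global
seed policy — and their defaults encode the stated operating conditions
of the workflow rather than tunable knobs.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .hardware import Capabilities, HardwareEdge, HardwareGraph, HardwareNode
from .units import Quantity
from .xdl_core import (DEFAULT_REGISTRY, HardwareDecl, ReagentDecl,
                       XDLDocument, XDLStep, serialize_xdl)


def _rng(rng: Optional[np.random.Generator | int]) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def q(mag: float, unit: str, dim: str) -> Quantity:
    return Quantity(float(mag), unit, dim)


# --------------------------------------------------------------------------
# Hardware graphs


def standard_graph() -> HardwareGraph:
    """A small syringe-pump-backbone platform: five liquid-holding nodes
    around a valve/pump backbone plus a waste port."""
    generous = dict(temp_range=(-25.0, 180.0), stir_range=(0.0, 1500.0))
    nodes = [
        HardwareNode("reactor1", "reactor",
                     Capabilities(max_volume=500.0, **generous)),
        HardwareNode("flask1", "flask",
                     Capabilities(max_volume=250.0, temp_range=(-25.0, 100.0))),
        HardwareNode("sep1", "separator",
                     Capabilities(max_volume=500.0, can_separate=True)),
        HardwareNode("rotavap1", "rotavap",
                     Capabilities(max_volume=500.0, temp_range=(10.0, 180.0),
                                  can_evaporate=True)),
        HardwareNode("filter1", "filter",
                     Capabilities(max_volume=300.0, can_filter=True)),
        HardwareNode("pump1", "pump"),
        HardwareNode("valve1", "valve"),
        HardwareNode("waste1", "waste"),
    ]
    edges = [HardwareEdge(n.id, "valve1") for n in nodes
             if n.id not in ("valve1",)]
    return HardwareGraph(nodes, edges)


def connected_graph(vessel_ids: Sequence[str],
                    max_volume: float = 1e6) -> HardwareGraph:
    """Fully reachable graph with one generous node per abstract vessel —
    the stage for volume-ledger and conservation fixtures."""
    caps = Capabilities(temp_range=(-100.0, 300.0), stir_range=(0.0, 3000.0),
                        max_volume=max_volume, can_filter=True,
                        can_separate=True, can_evaporate=True)
    nodes = [HardwareNode(v, "reactor", caps) for v in vessel_ids]
    nodes += [HardwareNode("valve1", "valve"), HardwareNode("pump1", "pump")]
    edges = [HardwareEdge(v, "valve1") for v in vessel_ids]
    edges.append(HardwareEdge("pump1", "valve1"))
    return HardwareGraph(nodes, edges)


def identity_mapping(doc: XDLDocument):
    from .hardware import VesselMapping
    return VesselMapping({h.id: h.id for h in doc.hardware})


# --------------------------------------------------------------------------
# Valid documents


_FIXED_HARDWARE = [
    HardwareDecl("reactor", "reactor"),
    HardwareDecl("flask_a", "flask"),
    HardwareDecl("sep", "separator"),
    HardwareDecl("still", "rotavap"),
    HardwareDecl("frit", "filter"),
]
_FIXED_REAGENTS = [
    ReagentDecl("water", "water", "solvent"),
    ReagentDecl("ethanol", "ethanol", "solvent"),
    ReagentDecl("substrate_a", "benzaldehyde", "substrate"),
    ReagentDecl("acid_a", "hydrochloric acid", "acid"),
]


def _random_step(name: str, rng: np.random.Generator) -> XDLStep:
    vessels = [h.id for h in _FIXED_HARDWARE]
    reagents = [r.id for r in _FIXED_REAGENTS]
    vol = q(round(float(rng.uniform(1, 40)), 1), "mL", "volume")
    tim = q(int(rng.integers(1, 60)), "min", "time")
    temp = q(int(rng.integers(-10, 120)), "°C", "temperature")
    speed = q(int(rng.integers(100, 900)), "rpm", "rotation-rate")
    vessel = str(rng.choice(vessels))
    reagent = str(rng.choice(reagents))
    builders = {
        "Add": lambda: {"vessel": vessel, "reagent": reagent, "volume": vol},
        "Transfer": lambda: {"from_vessel": vessel,
                             "to_vessel": str(rng.choice(
                                 [v for v in vessels if v != vessel])),
                             "volume": vol},
        "HeatChill": lambda: {"vessel": vessel, "temp": temp, "time": tim},
        "HeatChillToTemp": lambda: {"vessel": vessel, "temp": temp},
        "Stir": lambda: {"vessel": vessel, "time": tim, "stir_speed": speed},
        "StartStir": lambda: {"vessel": vessel, "stir_speed": speed},
        "StopStir": lambda: {"vessel": vessel},
        "Wait": lambda: {"time": tim},
        "Evaporate": lambda: {"vessel": "still", "temp": temp, "time": tim},
        "Filter": lambda: {"vessel": "frit"},
        "WashSolid": lambda: {"vessel": "frit", "solvent": reagent,
                              "volume": vol, "repeats": int(rng.integers(1, 4))},
        "Dry": lambda: {"vessel": "frit", "time": tim},
        "Separate": lambda: {"from_vessel": "sep", "to_vessel": "reactor",
                             "solvent": reagent, "solvent_volume": vol},
        "Dissolve": lambda: {"vessel": vessel, "solvent": reagent,
                             "volume": vol},
        "Precipitate": lambda: {"vessel": vessel, "time": tim},
    }
    if name == "Repeat":
        children = [_random_step(str(rng.choice(["Add", "Stir", "Wait"])), rng)
                    for _ in range(2)]
        return XDLStep("Repeat", {"repeats": int(rng.integers(2, 4))}, children)
    return XDLStep(name, builders[name]())


def random_valid_document(
    rng: Optional[np.random.Generator | int] = None, all_steps: bool = True,
    n_steps: int = 8,
) -> XDLDocument:
    """A valid document; with ``all_steps`` every registry step appears once
    (in random order), guaranteeing vocabulary coverage."""
    rng = _rng(rng)
    names = list(DEFAULT_REGISTRY)
    if all_steps:
        order = list(rng.permutation(names))
    else:
        order = [str(rng.choice([n for n in names if n != "Repeat"]))
                 for _ in range(n_steps)]
    steps = [_random_step(str(name), rng) for name in order]
    return XDLDocument(list(_FIXED_HARDWARE), list(_FIXED_REAGENTS), steps)


# --------------------------------------------------------------------------
# Seeded-error fixtures

ERROR_CATEGORIES = ("syntax", "unit", "missing-hardware", "missing-reagent",
                    "schema")


def _error_base_document() -> XDLDocument:
    """Deterministic base with one dedicated target element per category."""
    steps = [
        XDLStep("Add", {"vessel": "reactor", "reagent": "water",
                        "volume": q(20, "mL", "volume")}),
        XDLStep("HeatChill", {"vessel": "reactor",
                              "temp": q(50, "°C", "temperature"),
                              "time": q(10, "min", "time")}),
        XDLStep("Add", {"vessel": "reactor", "reagent": "ethanol",
                        "volume": q(10, "mL", "volume")}),
        XDLStep("Stir", {"vessel": "reactor", "time": q(5, "min", "time")}),
        XDLStep("Wait", {"time": q(1, "min", "time")}),
        XDLStep("Transfer", {"from_vessel": "reactor", "to_vessel": "flask_a",
                             "volume": q(15, "mL", "volume")}),
    ]
    return XDLDocument(list(_FIXED_HARDWARE), list(_FIXED_REAGENTS), steps)


def _element_path(root: ET.Element, target: ET.Element) -> str:
    """Path in the parser's convention: 1-based index per tag among siblings."""

    def rec(parent: ET.Element, prefix: str) -> Optional[str]:
        counts: Dict[str, int] = {}
        for child in parent:
            counts[child.tag] = counts.get(child.tag, 0) + 1
            path = f"{prefix}/{child.tag}[{counts[child.tag]}]"
            if child is target:
                return path
            found = rec(child, path)
            if found:
                return found
        return None

    if target is root:
        return "/Synthesis"
    result = rec(root, "/Synthesis")
    assert result is not None
    return result


def seeded_error_fixture(
    rng: Optional[np.random.Generator | int] = None, k: Optional[int] = None,
) -> Tuple[str, List[Tuple[str, str]]]:
    """An XDL source with *k* independently seeded errors and its manifest.

    Each seeded error targets a distinct element and produces exactly one
    issue of a distinct category; the manifest lists the expected
    ``(category, element path)`` pairs.  ``k`` defaults to a random value
    in 0..5; the five mutations cover all five issue categories.
    """
    rng = _rng(rng)
    if k is None:
        k = int(rng.integers(0, 6))
    if not 0 <= k <= 5:
        raise ValueError("k must be in 0..5")
    xml_text = serialize_xdl(_error_base_document())
    root = ET.fromstring(xml_text)
    procedure = root.find("Procedure")
    reagents = root.find("Reagents")
    assert procedure is not None and reagents is not None
    steps = list(procedure)

    def mutate_unit() -> ET.Element:
        steps[1].set("temp", "300 K")
        return steps[1]

    def mutate_missing_reagent() -> ET.Element:
        steps[2].set("reagent", "undeclared_amine")
        return steps[2]

    def mutate_missing_hardware() -> ET.Element:
        steps[3].set("vessel", "reactor9")
        return steps[3]

    def mutate_schema() -> ET.Element:
        steps[4].tag = "Sonicate"
        return steps[4]

    def mutate_syntax() -> ET.Element:
        bogus = ET.SubElement(reagents, "Bogus")
        return bogus

    mutations = {
        "unit": mutate_unit,
        "missing-reagent": mutate_missing_reagent,
        "missing-hardware": mutate_missing_hardware,
        "schema": mutate_schema,
        "syntax": mutate_syntax,
    }
    chosen = [str(c) for c in rng.choice(ERROR_CATEGORIES, size=k,
                                         replace=False)]
    manifest = []
    targets = {cat: mutations[cat]() for cat in chosen}
    for cat, el in targets.items():
        manifest.append((cat, _element_path(root, el)))
    return ET.tostring(root, encoding="unicode"), sorted(manifest)


# --------------------------------------------------------------------------
# Volume / simulation fixtures


def random_volume_document(
    rng: Optional[np.random.Generator | int] = None, n_steps: int = 50,
    n_vessels: int = 4, transfers_only_after_setup: bool = True,
) -> XDLDocument:
    """A long Add/Transfer (optionally work-up) sequence for ledger tests.

    The first ``n_vessels`` steps charge each vessel; with
    ``transfers_only_after_setup`` the remainder are pure transfers
    (including occasional ``all`` and deliberate over-draws), so total
    volume after setup is conserved.  Otherwise removal steps
    (Evaporate/Filter/WashSolid/Dissolve/Separate) are mixed in.
    """
    rng = _rng(rng)
    vessels = [f"v{i}" for i in range(1, n_vessels + 1)]
    hardware = [HardwareDecl(v, "reactor") for v in vessels]
    reagents = [ReagentDecl("water", "water", "solvent"),
                ReagentDecl("ethanol", "ethanol", "solvent")]
    steps = [
        XDLStep("Add", {"vessel": v, "reagent": "water",
                        "volume": q(round(float(rng.uniform(20, 80)), 3),
                                    "mL", "volume")})
        for v in vessels
    ]
    choices = (["Transfer"] if transfers_only_after_setup
               else ["Transfer", "Add", "Evaporate", "Filter", "WashSolid",
                     "Dissolve", "Separate"])
    for _ in range(n_steps - len(steps)):
        name = str(rng.choice(choices))
        src = str(rng.choice(vessels))
        dst = str(rng.choice([v for v in vessels if v != src]))
        if name == "Transfer":
            roll = rng.random()
            if roll < 0.2:
                volume = "all"
            elif roll < 0.3:
                volume = q(round(float(rng.uniform(100, 400)), 3), "mL",
                           "volume")  # likely over-draw
            else:
                volume = q(round(float(rng.uniform(1, 30)), 3), "mL", "volume")
            steps.append(XDLStep("Transfer", {"from_vessel": src,
                                              "to_vessel": dst,
                                              "volume": volume}))
        elif name == "Add":
            steps.append(XDLStep("Add", {
                "vessel": src, "reagent": str(rng.choice(["water", "ethanol"])),
                "volume": q(round(float(rng.uniform(1, 30)), 3), "mL",
                            "volume")}))
        elif name in ("Evaporate", "Filter"):
            steps.append(XDLStep(name, {"vessel": src}))
        elif name == "WashSolid":
            steps.append(XDLStep("WashSolid", {
                "vessel": src, "solvent": "water",
                "volume": q(round(float(rng.uniform(1, 15)), 3), "mL", "volume"),
                "repeats": int(rng.integers(1, 4))}))
        elif name == "Dissolve":
            steps.append(XDLStep("Dissolve", {
                "vessel": src, "solvent": "ethanol",
                "volume": q(round(float(rng.uniform(1, 20)), 3), "mL",
                            "volume")}))
        else:  # Separate
            steps.append(XDLStep("Separate", {
                "from_vessel": src, "to_vessel": dst,
                "solvent": "ethanol",
                "solvent_volume": q(round(float(rng.uniform(1, 15)), 3), "mL",
                                    "volume")}))
    return XDLDocument(hardware, reagents, steps)


def violation_fixture(kind: str):
    """A (document, graph, mapping, expected code, expected step index)
    fixture containing exactly one hardware-constraint violation."""
    reagents = [ReagentDecl("water", "water", "solvent")]
    caps = Capabilities(temp_range=(-20.0, 150.0), stir_range=(0.0, 1000.0),
                        max_volume=50.0)
    nodes = [HardwareNode("r1", "reactor", caps),
             HardwareNode("r2", "reactor", caps),
             HardwareNode("lonely", "reactor", caps),
             HardwareNode("valve1", "valve")]
    edges = [HardwareEdge("r1", "valve1"), HardwareEdge("r2", "valve1")]
    graph = HardwareGraph(nodes, edges)
    base = [XDLStep("Add", {"vessel": "a", "reagent": "water",
                            "volume": q(10, "mL", "volume")})]
    if kind == "temperature":
        steps = base + [XDLStep("HeatChill", {
            "vessel": "a", "temp": q(160, "°C", "temperature"),
            "time": q(10, "min", "time")})]
        hardware = [HardwareDecl("a", "reactor")]
        mapping = {"a": "r1"}
        expected = ("TEMP_OUT_OF_RANGE", 1)
    elif kind == "stir":
        steps = base + [XDLStep("StartStir", {
            "vessel": "a", "stir_speed": q(1500, "rpm", "rotation-rate")})]
        hardware = [HardwareDecl("a", "reactor")]
        mapping = {"a": "r1"}
        expected = ("STIR_RATE_OUT_OF_RANGE", 1)
    elif kind == "overflow":
        steps = base + [XDLStep("Add", {"vessel": "a", "reagent": "water",
                                        "volume": q(45, "mL", "volume")})]
        hardware = [HardwareDecl("a", "reactor")]
        mapping = {"a": "r1"}
        expected = ("OVERFLOW", 1)
    elif kind == "unreachable":
        steps = base + [XDLStep("Transfer", {"from_vessel": "a",
                                             "to_vessel": "b",
                                             "volume": q(5, "mL", "volume")})]
        hardware = [HardwareDecl("a", "reactor"), HardwareDecl("b", "reactor")]
        mapping = {"a": "r1", "b": "lonely"}
        expected = ("UNREACHABLE_TRANSFER", 1)
    else:
        raise ValueError(f"unknown violation kind '{kind}'")
    from .hardware import VesselMapping
    doc = XDLDocument(hardware, reagents, steps)
    return doc, graph, VesselMapping(mapping), expected[0], expected[1]


# --------------------------------------------------------------------------
# Vessel-mapping instances


def random_mapping_instance(
    rng: Optional[np.random.Generator | int] = None,
) -> Tuple[XDLDocument, HardwareGraph]:
    """A random (document, graph) pair for the mapping-feasibility oracle:
    1–4 abstract vessels with random thermal/stir/volume demands against
    ≤ 6 liquid-holding nodes with random capability envelopes."""
    rng = _rng(rng)
    n_vessels = int(rng.integers(1, 5))
    vessels = [f"v{i}" for i in range(1, n_vessels + 1)]
    hardware = [HardwareDecl(v, "reactor") for v in vessels]
    reagents = [ReagentDecl("water", "water", "solvent")]
    steps: List[XDLStep] = []
    for v in vessels:
        steps.append(XDLStep("Add", {
            "vessel": v, "reagent": "water",
            "volume": q(round(float(rng.uniform(5, 80)), 1), "mL", "volume")}))
        if rng.random() < 0.7:
            steps.append(XDLStep("HeatChill", {
                "vessel": v,
                "temp": q(int(rng.integers(-20, 200)), "°C", "temperature"),
                "time": q(5, "min", "time")}))
        if rng.random() < 0.4:
            steps.append(XDLStep("StartStir", {
                "vessel": v,
                "stir_speed": q(int(rng.integers(100, 2000)), "rpm",
                                "rotation-rate")}))
    doc = XDLDocument(hardware, reagents, steps)

    n_nodes = int(rng.integers(1, 7))
    nodes = []
    for i in range(n_nodes):
        temp = None
        if rng.random() < 0.8:
            lo = float(rng.integers(-40, 30))
            temp = (lo, lo + float(rng.integers(50, 220)))
        stir = (0.0, float(rng.integers(300, 2500))) if rng.random() < 0.6 \
            else None
        caps = Capabilities(temp_range=temp, stir_range=stir,
                            max_volume=float(rng.integers(20, 120)))
        nodes.append(HardwareNode(f"n{i + 1}",
                                  str(rng.choice(["reactor", "flask"])), caps))
    nodes.append(HardwareNode("valve1", "valve"))
    edges = [HardwareEdge(n.id, "valve1") for n in nodes[:-1]]
    return doc, HardwareGraph(nodes, edges)


# --------------------------------------------------------------------------
# Clustering templates


_STEP_TEMPLATES = {
    "ph-adjust": ("adjust the ph of the {noun} to {n} by careful addition of "
                  "dilute {acid} monitoring with a calibrated ph meter probe"),
    "tlc": ("monitor the {noun} progress by thin layer chromatography tlc "
            "analysis on silica plates eluting with {n} percent solvent"),
    "ramp": ("heat the {noun} to {n} degrees at a controlled ramp rate of "
             "{rate} degrees per minute using gradient temperature control"),
    "sonicate": ("sonicate the {noun} suspension in an ultrasonic bath for "
                 "{n} minutes to disperse the aggregated solid particles"),
}
_NOUNS = ["mixture", "reaction", "solution", "slurry"]
_ACIDS = ["hydrochloric acid", "acetic acid", "sulfuric acid"]


def labelled_step_templates(
    rng: Optional[np.random.Generator | int] = None, per_template: int = 8,
) -> Tuple[List[str], List[str]]:
    """Non-executable step texts from 4 labelled templates with small
    perturbations; returns (texts, template labels) for clustering
    recovery against the generator labels."""
    rng = _rng(rng)
    texts, labels = [], []
    for label, template in _STEP_TEMPLATES.items():
        for _ in range(per_template):
            texts.append(template.format(
                noun=str(rng.choice(_NOUNS)),
                acid=str(rng.choice(_ACIDS)),
                n=int(rng.integers(2, 90)),
                rate=int(rng.integers(1, 10))))
            labels.append(label)
    order = rng.permutation(len(texts))
    return [texts[i] for i in order], [labels[i] for i in order]


# --------------------------------------------------------------------------
# The end-to-end paper-like fixture and its scripted agents


FIXTURE_GENERAL = (
    "General procedure A: to a stirred solution of the aryl halide in a "
    "polar aprotic solvent is added the amine, and the mixture is heated "
    "until consumption of the starting material.")

FIXTURE_PROCEDURE = (
    "A mixture of 1-fluoro-4-nitrobenzene (1.41 g, 10 mmol) and morpholine "
    "(2.61 g, 30 mmol) in DMSO (20 mL) was heated to 100 °C for 2 h "
    "following general procedure A. After cooling, water (40 mL) was added "
    "and the mixture was extracted 30 times with 20 ml ethyl acetate. The "
    "combined organic layers were concentrated under reduced pressure to "
    "give the product.")

FIXTURE_NMR = ("1H NMR (400 MHz, CDCl3): 8.11 (d, 2H), 6.82 (d, 2H), 3.85 "
               "(m, 4H), 3.36 (m, 4H).")


def fixture_paper_text() -> str:
    return (
        "Synthesis of 4-(4-nitrophenyl)morpholine\n\n"
        + FIXTURE_GENERAL + "\n\n" + FIXTURE_PROCEDURE + "\n\n"
        + "Analytical data. " + FIXTURE_NMR + "\n")


def fixture_gold_entities() -> List[str]:
    return ["1-fluoro-4-nitrobenzene", "morpholine", "dimethyl sulfoxide",
            "ethyl acetate", "water", "4-(4-nitrophenyl)morpholine"]


FIXTURE_XDL = """<Synthesis>
  <Hardware>
    <Component id="reactor" type="reactor" />
    <Component id="sep" type="separator" />
    <Component id="still" type="rotavap" />
  </Hardware>
  <Reagents>
    <Reagent id="fluoronitrobenzene" name="1-fluoro-4-nitrobenzene" role="substrate" />
    <Reagent id="morpholine" name="morpholine" role="reagent" />
    <Reagent id="dmso" name="dimethyl sulfoxide" role="solvent" />
    <Reagent id="ethyl_acetate" name="ethyl acetate" role="solvent" />
    <Reagent id="water" name="water" role="solvent" />
  </Reagents>
  <Procedure>
    <Add vessel="reactor" reagent="dmso" volume="20 mL" />
    <Add vessel="reactor" reagent="fluoronitrobenzene" mass="1.41 g" />
    <Add vessel="reactor" reagent="morpholine" mass="2.61 g" />
    <HeatChill vessel="reactor" temp="100 °C" time="2 h" />
    <Add vessel="reactor" reagent="water" volume="40 mL" />
    <Repeat repeats="3">
      <Transfer from_vessel="reactor" to_vessel="sep" volume="all" />
      <Add vessel="sep" reagent="ethyl_acetate" volume="20 mL" />
      <Separate from_vessel="sep" to_vessel="reactor" product_phase="organic" />
    </Repeat>
    <Transfer from_vessel="reactor" to_vessel="still" volume="all" />
    <Evaporate vessel="still" temp="50 °C" time="30 min" />
  </Procedure>
</Synthesis>
"""


def fixture_extraction_response() -> str:
    payload = {
        "chemicals": [
            {"name": "1-fluoro-4-nitrobenzene", "abbreviations": [],
             "synonyms": ["4-fluoronitrobenzene"]},
            {"name": "morpholine", "abbreviations": [], "synonyms": []},
            {"name": "dimethyl sulfoxide", "abbreviations": ["DMSO"],
             "synonyms": []},
            {"name": "ethyl acetate", "abbreviations": ["EtOAc"],
             "synonyms": []},
            {"name": "water", "abbreviations": [], "synonyms": []},
            {"name": "4-(4-nitrophenyl)morpholine", "abbreviations": [],
             "synonyms": ["the product"]},
        ],
        "procedures": [
            {"text": FIXTURE_GENERAL, "product": None, "language": "en"},
            {"text": FIXTURE_PROCEDURE,
             "product": "4-(4-nitrophenyl)morpholine", "language": "en"},
        ],
        "purifications": ["concentrated under reduced pressure"],
        "analytics": [{"kind": "NMR", "text": FIXTURE_NMR}],
        "notes": [],
    }
    return json.dumps(payload)


def fixture_sanitize_response() -> str:
    original = FIXTURE_PROCEDURE
    before = "extracted 30 times with 20 ml"
    after = "extracted 3 times with 20 ml"
    start = original.index(before)
    sanitized = original[:start] + after + original[start + len(before):]
    return json.dumps({
        "sanitized_text": sanitized,
        "edits": [{
            "start": start, "end": start + len(before),
            "before": before, "after": after,
            "reason": "30 extractions is implausible and inconsistent with "
                      "the reported solvent total; corrected to 3",
        }],
        "open_questions": [],
    })


def fixture_critique_response() -> str:
    return json.dumps({
        "missing_steps": [],
        "disordered_steps": [],
        "extraneous_steps": [],
        "non_executable_steps": [{
            "span": "concentrated under reduced pressure",
            "description": "pressure programme is approximated by a fixed "
                           "rotary evaporation step",
        }],
    })


def e2e_scripts() -> Dict[str, List[str]]:
    """Scripted agent responses driving the end-to-end mock run on the
    fixture document: one extraction payload, per-procedure categories,
    one sanitization with a logged 30→3 edit, one clean translation, one
    critique carrying a single non-executable harvest entry."""
    return {
        "extract": [fixture_extraction_response()],
        "classify": ["blueprint", "executable"],
        "sanitize": [fixture_sanitize_response()],
        "translate": ["Reasoning about the procedure...\n```xml\n"
                      + FIXTURE_XDL + "```\n"],
        "critique": [fixture_critique_response()],
        "refine": [""],
    }
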