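"""Data model, parser, exhaustive validator and serializer for the XDL dialect.

XDL here is an XML dialect describing a synthesis as declared hardware
(abstract vessels), reagents, and an ordered procedure of steps.  The
parser is deliberately *total*: a single pass over the source reports
every detectable problem — malformed structure, unknown steps, missing
required attributes, ill-dimensioned units, unresolved vessel or reagent
references — instead of stopping at the first, so a repair loop receives
all errors at once.

The step vocabulary is a data-driven registry (16 default steps) rather
than a fixed grammar, so a platform with a restricted instruction set can
validate against its own subset.  This is a documented compatible
dialect, not a byte-compatible clone of any proprietary schema; see
``docs/methods.md``.
"""

from __future__ import annotations

import xml.parsers.expat
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .units import DIMENSIONS, Quantity, UnitError, parse_quantity

# --------------------------------------------------------------------------
# Vocabulary

VESSEL_CLASSES = ("reactor", "separator", "rotavap", "filter", "cartridge", "flask")
REAGENT_ROLES = ("solvent", "reagent", "substrate", "catalyst", "acid", "base")

#: attribute kinds understood by the schema checker
ATTR_KINDS = (
    "vessel-ref",
    "reagent-ref",
    "free-text",
    "positive-integer",
    "volume-or-all",
) + tuple(f"quantity:{d}" for d in DIMENSIONS)


@dataclass(frozen=True)
class StepSchema:
    """Declared shape of one step: its name and typed attributes."""

    step_name: str
    required_attrs: Tuple[Tuple[str, str], ...] = ()
    optional_attrs: Tuple[Tuple[str, str], ...] = ()
    allows_children: bool = False

    def __post_init__(self) -> None:
        names = [a for a, _ in self.required_attrs + self.optional_attrs]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate attribute names in schema {self.step_name}")
        for _, kind in self.required_attrs + self.optional_attrs:
            if kind not in ATTR_KINDS:
                raise ValueError(f"unknown attribute kind '{kind}'")

    @property
    def attr_kinds(self) -> Dict[str, str]:
        return dict(self.required_attrs + self.optional_attrs)


def _s(name: str, req: Sequence[Tuple[str, str]], opt: Sequence[Tuple[str, str]] = (),
       children: bool = False) -> StepSchema:
    return StepSchema(name, tuple(req), tuple(opt), children)


#: the default 16-step vocabulary, covering addition, transfer, heating,
#: stirring, waiting, work-up (evaporate/filter/wash/dry/separate),
#: dissolution, precipitation and repetition.
DEFAULT_REGISTRY: Dict[str, StepSchema] = {
    s.step_name: s
    for s in [
        _s("Add", [("vessel", "vessel-ref"), ("reagent", "reagent-ref")],
           [("volume", "quantity:volume"), ("mass", "quantity:mass"),
            ("amount", "quantity:amount"), ("time", "quantity:time")]),
        _s("Transfer", [("from_vessel", "vessel-ref"), ("to_vessel", "vessel-ref")],
           [("volume", "volume-or-all"), ("time", "quantity:time")]),
        _s("HeatChill", [("vessel", "vessel-ref"), ("temp", "quantity:temperature"),
                         ("time", "quantity:time")]),
        _s("HeatChillToTemp", [("vessel", "vessel-ref"),
                               ("temp", "quantity:temperature")]),
        _s("Stir", [("vessel", "vessel-ref"), ("time", "quantity:time")],
           [("stir_speed", "quantity:rotation-rate")]),
        _s("StartStir", [("vessel", "vessel-ref")],
           [("stir_speed", "quantity:rotation-rate")]),
        _s("StopStir", [("vessel", "vessel-ref")]),
        _s("Wait", [("time", "quantity:time")]),
        _s("Evaporate", [("vessel", "vessel-ref")],
           [("temp", "quantity:temperature"), ("pressure", "quantity:pressure"),
            ("time", "quantity:time")]),
        _s("Filter", [("vessel", "vessel-ref")]),
        _s("WashSolid", [("vessel", "vessel-ref"), ("solvent", "reagent-ref"),
                         ("volume", "quantity:volume")],
           [("repeats", "positive-integer")]),
        _s("Dry", [("vessel", "vessel-ref")],
           [("time", "quantity:time"), ("temp", "quantity:temperature")]),
        _s("Separate", [("from_vessel", "vessel-ref"), ("to_vessel", "vessel-ref")],
           [("solvent", "reagent-ref"), ("solvent_volume", "quantity:volume"),
            ("product_phase", "free-text")]),
        _s("Dissolve", [("vessel", "vessel-ref"), ("solvent", "reagent-ref"),
                        ("volume", "quantity:volume")]),
        _s("Precipitate", [("vessel", "vessel-ref")],
           [("time", "quantity:time"), ("temp", "quantity:temperature")]),
        _s("Repeat", [("repeats", "positive-integer")], children=True),
    ]
}


# --------------------------------------------------------------------------
# Document model

AttrValue = Union[str, int, Quantity]


@dataclass(frozen=True)
class ReagentDecl:
    id: str
    name: str
    role: Optional[str] = None
    molecular_info: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class HardwareDecl:
    id: str
    vessel_class: str = "reactor"


@dataclass
class XDLStep:
    step_name: str
    attributes: Dict[str, AttrValue] = field(default_factory=dict)
    children: List["XDLStep"] = field(default_factory=list)
    source_line: Optional[int] = field(default=None, compare=False)

    def get_quantity(self, name: str) -> Optional[Quantity]:
        value = self.attributes.get(name)
        return value if isinstance(value, Quantity) else None


@dataclass
class XDLDocument:
    hardware: List[HardwareDecl] = field(default_factory=list)
    reagents: List[ReagentDecl] = field(default_factory=list)
    procedure: List[XDLStep] = field(default_factory=list)
    metadata: Dict[str, str] = field(default_factory=dict)

    @property
    def vessel_ids(self) -> List[str]:
        return [h.id for h in self.hardware]

    @property
    def reagent_ids(self) -> List[str]:
        return [r.id for r in self.reagents]


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    category: str  # syntax | unit | missing-hardware | missing-reagent | schema
    severity: str  # error | warning
    location: str  # element path, e.g. /Synthesis/Procedure/Add[2]
    message: str
    line: Optional[int] = None

    def __str__(self) -> str:
        where = self.location + (f" (line {self.line})" if self.line else "")
        return f"[{self.severity}/{self.category}] {self.code} at {where}: {self.message}"


class XDLError(ValueError):
    """Raised only for unusable calls (empty input, serializing invalid docs)."""

    def __init__(self, message: str, issues: Sequence[ValidationIssue] = ()):
        super().__init__(message)
        self.issues = list(issues)


# --------------------------------------------------------------------------
# Raw XML tree with line numbers (expat keeps us stdlib-only)


class _RawElement:
    __slots__ = ("tag", "attrs", "children", "line", "text_lines")

    def __init__(self, tag: str, attrs: Dict[str, str], line: int):
        self.tag = tag
        self.attrs = attrs
        self.children: List["_RawElement"] = []
        self.line = line
        self.text_lines: List[int] = []  # lines with stray non-whitespace text


def _parse_raw(text: str) -> _RawElement:
    parser = xml.parsers.expat.ParserCreate()
    root: List[_RawElement] = []
    stack: List[_RawElement] = []

    def start(tag: str, attrs: Dict[str, str]) -> None:
        el = _RawElement(tag, dict(attrs), parser.CurrentLineNumber)
        (stack[-1].children if stack else root).append(el)
        stack.append(el)

    def end(_tag: str) -> None:
        stack.pop()

    def chars(data: str) -> None:
        if data.strip() and stack:
            stack[-1].text_lines.append(parser.CurrentLineNumber)

    parser.StartElementHandler = start
    parser.EndElementHandler = end
    parser.CharacterDataHandler = chars
    parser.Parse(text, True)
    return root[0]


def _child_path(parent_path: str, tag: str, ordinal: int) -> str:
    return f"{parent_path}/{tag}[{ordinal}]"


class _IssueSink:
    def __init__(self) -> None:
        self.issues: List[ValidationIssue] = []

    def add(self, code: str, category: str, location: str, message: str,
            line: Optional[int] = None, severity: str = "error") -> None:
        self.issues.append(
            ValidationIssue(code, category, severity, location, message, line)
        )


# --------------------------------------------------------------------------
# Shared attribute checking (used by parse and by validate)


def _check_attr_value(
    value: AttrValue, kind: str, doc: XDLDocument, path: str, attr: str,
    sink: _IssueSink, line: Optional[int],
) -> Optional[AttrValue]:
    """Check (and for string inputs, coerce) one attribute value.

    Returns the coerced value, or None when an issue was recorded.
    """
    if kind == "free-text":
        return str(value)
    if kind == "vessel-ref":
        ref = str(value)
        if ref not in doc.vessel_ids:
            sink.add("MISSING_HARDWARE_REF", "missing-hardware", path,
                     f"step attribute {attr}='{ref}' references an undeclared vessel",
                     line)
            return None
        return ref
    if kind == "reagent-ref":
        ref = str(value)
        if ref not in doc.reagent_ids:
            sink.add("MISSING_REAGENT_REF", "missing-reagent", path,
                     f"step attribute {attr}='{ref}' references an undeclared reagent",
                     line)
            return None
        return ref
    if kind == "positive-integer":
        if isinstance(value, bool) or isinstance(value, Quantity):
            sink.add("BAD_INT", "schema", path,
                     f"attribute {attr} must be a positive integer", line)
            return None
        try:
            ivalue = int(str(value))
        except ValueError:
            sink.add("BAD_INT", "schema", path,
                     f"attribute {attr}='{value}' is not an integer", line)
            return None
        if ivalue <= 0:
            sink.add("BAD_INT", "schema", path,
                     f"attribute {attr}={ivalue} must be positive", line)
            return None
        return ivalue
    if kind == "volume-or-all":
        if isinstance(value, str) and value.strip().lower() == "all":
            return "all"
        kind = "quantity:volume"
    # quantity:<dimension>
    dimension = kind.split(":", 1)[1]
    if isinstance(value, Quantity):
        if value.dimension != dimension:
            sink.add("BAD_UNIT", "unit", path,
                     f"attribute {attr} has dimension {value.dimension}, "
                     f"expected {dimension}", line)
            return None
        return value
    try:
        return parse_quantity(str(value), dimension)
    except UnitError as exc:
        sink.add("BAD_UNIT", "unit", path,
                 f"attribute {attr}: {exc}", line)
        return None


def _check_step(
    step_name: str, raw_attrs: Mapping[str, AttrValue], schema: StepSchema,
    doc: XDLDocument, path: str, sink: _IssueSink, line: Optional[int],
) -> Dict[str, AttrValue]:
    """Check all attributes of one step against its schema; returns coerced attrs."""
    kinds = schema.attr_kinds
    coerced: Dict[str, AttrValue] = {}
    for attr, _kind in schema.required_attrs:
        if attr not in raw_attrs:
            sink.add("MISSING_ATTR", "schema", path,
                     f"step {step_name} is missing required attribute '{attr}'", line)
    for attr, value in raw_attrs.items():
        if attr not in kinds:
            sink.add("UNEXPECTED_ATTR", "schema", path,
                     f"step {step_name} has unknown attribute '{attr}'", line)
            continue
        out = _check_attr_value(value, kinds[attr], doc, path, attr, sink, line)
        if out is not None:
            coerced[attr] = out
    return coerced


# --------------------------------------------------------------------------
# Parsing


def parse_xdl(
    text: str, registry: Optional[Mapping[str, StepSchema]] = None
) -> Tuple[Optional[XDLDocument], List[ValidationIssue]]:
    """Parse XDL source, reporting *all* detectable issues in one pass.

    Returns ``(document, issues)``.  Content problems never raise — they
    become :class:`ValidationIssue` entries with source locations — and an
    empty issue list guarantees a fully valid document.  A document is
    still returned (possibly partial) whenever the XML itself is
    well-formed; only an empty input raises.
    """
    if not (text and text.strip()):
        raise XDLError("empty XDL input")
    registry = DEFAULT_REGISTRY if registry is None else registry
    sink = _IssueSink()
    try:
        root = _parse_raw(text)
    except xml.parsers.expat.ExpatError as exc:
        sink.add("XML_MALFORMED", "syntax", "/",
                 xml.parsers.expat.errors.messages[exc.code], exc.lineno)
        return None, sink.issues

    if root.tag != "Synthesis":
        sink.add("BAD_ROOT", "syntax", f"/{root.tag}[1]",
                 f"root element must be <Synthesis>, found <{root.tag}>", root.line)
        return None, sink.issues

    doc = XDLDocument()
    base = "/Synthesis"
    sections: Dict[str, List[_RawElement]] = {}
    tag_counts: Dict[str, int] = {}
    for child in root.children:
        tag_counts[child.tag] = tag_counts.get(child.tag, 0) + 1
        path = _child_path(base, child.tag, tag_counts[child.tag])
        if child.tag in ("Hardware", "Reagents", "Procedure", "Metadata"):
            sections.setdefault(child.tag, []).append(child)
        else:
            sink.add("UNEXPECTED_ELEMENT", "syntax", path,
                     f"unexpected element <{child.tag}> under <Synthesis>", child.line)
    if root.text_lines:
        sink.add("UNEXPECTED_TEXT", "syntax", base,
                 "stray text content under <Synthesis>", root.text_lines[0])

    # ---- declarations (parsed before the procedure so references resolve)
    for section in sections.get("Hardware", []):
        spath = _child_path(base, "Hardware", 1)
        counts: Dict[str, int] = {}
        for el in section.children:
            counts[el.tag] = counts.get(el.tag, 0) + 1
            path = _child_path(spath, el.tag, counts[el.tag])
            if el.tag != "Component":
                sink.add("UNEXPECTED_ELEMENT", "syntax", path,
                         f"unexpected element <{el.tag}> under <Hardware>", el.line)
                continue
            hid = el.attrs.get("id", "")
            if not hid:
                sink.add("MISSING_NAME", "schema", path,
                         "hardware component missing 'id'", el.line)
                continue
            vclass = el.attrs.get("type", "reactor")
            if vclass not in VESSEL_CLASSES:
                sink.add("BAD_VESSEL_CLASS", "schema", path,
                         f"unknown vessel class '{vclass}' for '{hid}'", el.line)
                continue
            if hid in doc.vessel_ids:
                sink.add("DUPLICATE_ID", "schema", path,
                         f"duplicate hardware id '{hid}' (first declaration wins)",
                         el.line)
                continue
            doc.hardware.append(HardwareDecl(hid, vclass))

    for section in sections.get("Reagents", []):
        spath = _child_path(base, "Reagents", 1)
        counts = {}
        for el in section.children:
            counts[el.tag] = counts.get(el.tag, 0) + 1
            path = _child_path(spath, el.tag, counts[el.tag])
            if el.tag != "Reagent":
                sink.add("UNEXPECTED_ELEMENT", "syntax", path,
                         f"unexpected element <{el.tag}> under <Reagents>", el.line)
                continue
            rid = el.attrs.get("id", "")
            if not rid:
                sink.add("MISSING_NAME", "schema", path,
                         "reagent missing 'id'", el.line)
                continue
            role = el.attrs.get("role")
            if role is not None and role not in REAGENT_ROLES:
                sink.add("BAD_ROLE", "schema", path,
                         f"unknown reagent role '{role}' for '{rid}'", el.line)
                role = None
            if rid in doc.reagent_ids:
                sink.add("DUPLICATE_ID", "schema", path,
                         f"duplicate reagent id '{rid}' (first declaration wins)",
                         el.line)
                continue
            info = {k: v for k, v in el.attrs.items()
                    if k in ("iupac_name", "molar_mass", "boiling_point")}
            doc.reagents.append(
                ReagentDecl(rid, el.attrs.get("name", rid), role, info))

    for section in sections.get("Metadata", []):
        doc.metadata.update(section.attrs)

    # ---- procedure
    def build_steps(parent: _RawElement, parent_path: str,
                    depth: int) -> List[XDLStep]:
        steps: List[XDLStep] = []
        counts: Dict[str, int] = {}
        for el in parent.children:
            counts[el.tag] = counts.get(el.tag, 0) + 1
            path = _child_path(parent_path, el.tag, counts[el.tag])
            schema = registry.get(el.tag)
            if schema is None:
                sink.add("UNKNOWN_STEP", "schema", path,
                         f"unknown step <{el.tag}>", el.line)
                continue
            if el.text_lines:
                sink.add("UNEXPECTED_TEXT", "syntax", path,
                         f"stray text content in <{el.tag}>", el.text_lines[0])
            attrs = _check_step(el.tag, el.attrs, schema, doc, path, sink, el.line)
            children: List[XDLStep] = []
            if el.children:
                if schema.allows_children:
                    children = build_steps(el, path, depth + 1)
                else:
                    sink.add("CHILDREN_NOT_ALLOWED", "schema", path,
                             f"step <{el.tag}> does not take child steps", el.line)
            steps.append(XDLStep(el.tag, attrs, children, el.line))
        return steps

    proc_sections = sections.get("Procedure", [])
    for section in proc_sections:
        doc.procedure.extend(build_steps(section, _child_path(base, "Procedure", 1), 0))
    if not doc.procedure:
        line = proc_sections[0].line if proc_sections else root.line
        sink.add("EMPTY_PROCEDURE", "schema", _child_path(base, "Procedure", 1),
                 "procedure contains no steps", line)
    return doc, sink.issues


# --------------------------------------------------------------------------
# Validation of in-memory documents


def validate_document(
    doc: XDLDocument, registry: Optional[Mapping[str, StepSchema]] = None
) -> List[ValidationIssue]:
    """Validate an in-memory document against a step registry.

    Returns every schema, unit and reference issue found; an empty list
    means the document is valid.  Idempotent: validating a document that
    already validated cleanly returns ``[]`` again.  Issues carry
    element-path locations only (no line numbers) because an in-memory
    document has no source text.
    """
    registry = DEFAULT_REGISTRY if registry is None else registry
    sink = _IssueSink()
    base = "/Synthesis"

    seen: set = set()
    for i, h in enumerate(doc.hardware, 1):
        path = _child_path(_child_path(base, "Hardware", 1), "Component", i)
        if h.vessel_class not in VESSEL_CLASSES:
            sink.add("BAD_VESSEL_CLASS", "schema", path,
                     f"unknown vessel class '{h.vessel_class}'")
        if h.id in seen:
            sink.add("DUPLICATE_ID", "schema", path, f"duplicate hardware id '{h.id}'")
        seen.add(h.id)
    seen = set()
    for i, r in enumerate(doc.reagents, 1):
        path = _child_path(_child_path(base, "Reagents", 1), "Reagent", i)
        if not r.name:
            sink.add("MISSING_NAME", "schema", path, f"reagent '{r.id}' has no name")
        if r.role is not None and r.role not in REAGENT_ROLES:
            sink.add("BAD_ROLE", "schema", path, f"unknown reagent role '{r.role}'")
        if r.id in seen:
            sink.add("DUPLICATE_ID", "schema", path, f"duplicate reagent id '{r.id}'")
        seen.add(r.id)

    def walk(steps: Sequence[XDLStep], parent_path: str) -> None:
        counts: Dict[str, int] = {}
        for step in steps:
            counts[step.step_name] = counts.get(step.step_name, 0) + 1
            path = _child_path(parent_path, step.step_name, counts[step.step_name])
            schema = registry.get(step.step_name)
            if schema is None:
                sink.add("UNKNOWN_STEP", "schema", path,
                         f"unknown step <{step.step_name}>")
                continue
            _check_step(step.step_name, step.attributes, schema, doc, path, sink, None)
            if step.children:
                if schema.allows_children:
                    walk(step.children, path)
                else:
                    sink.add("CHILDREN_NOT_ALLOWED", "schema", path,
                             f"step <{step.step_name}> does not take child steps")

    walk(doc.procedure, _child_path(base, "Procedure", 1))
    if not doc.procedure:
        sink.add("EMPTY_PROCEDURE", "schema", _child_path(base, "Procedure", 1),
                 "procedure contains no steps")
    return sink.issues


# --------------------------------------------------------------------------
# Serialization


def _attr_to_text(value: AttrValue) -> str:
    if isinstance(value, Quantity):
        return str(value)
    return str(value)


def _quote(value: str) -> str:
    return (value.replace("&", "&amp;").replace("<", "&lt;")
            .replace('"', "&quot;"))


def _step_lines(step: XDLStep, registry: Mapping[str, StepSchema],
                indent: int) -> List[str]:
    schema = registry[step.step_name]
    order = [a for a, _ in schema.required_attrs + schema.optional_attrs]
    extras = sorted(set(step.attributes) - set(order))
    attrs = "".join(
        f' {a}="{_quote(_attr_to_text(step.attributes[a]))}"'
        for a in order + extras if a in step.attributes
    )
    pad = "  " * indent
    if step.children:
        lines = [f"{pad}<{step.step_name}{attrs}>"]
        for child in step.children:
            lines.extend(_step_lines(child, registry, indent + 1))
        lines.append(f"{pad}</{step.step_name}>")
        return lines
    return [f"{pad}<{step.step_name}{attrs} />"]


def serialize_xdl(
    doc: XDLDocument, registry: Optional[Mapping[str, StepSchema]] = None
) -> str:
    """Serialize a *valid* document to XDL source with stable attribute order.

    ``parse_xdl(serialize_xdl(doc))`` reproduces *doc* with zero issues.
    An invalid document is refused with its validation issues attached.
    """
    registry = DEFAULT_REGISTRY if registry is None else registry
    issues = validate_document(doc, registry)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise XDLError(
            f"cannot serialize invalid document ({len(errors)} issues)", errors)
    lines = ["<Synthesis>"]
    lines.append("  <Hardware>")
    for h in doc.hardware:
        lines.append(f'    <Component id="{_quote(h.id)}" type="{h.vessel_class}" />')
    lines.append("  </Hardware>")
    lines.append("  <Reagents>")
    for r in doc.reagents:
        attrs = f' id="{_quote(r.id)}" name="{_quote(r.name)}"'
        if r.role:
            attrs += f' role="{r.role}"'
        for key in ("iupac_name", "molar_mass", "boiling_point"):
            if key in r.molecular_info:
                attrs += f' {key}="{_quote(str(r.molecular_info[key]))}"'
        lines.append(f"    <Reagent{attrs} />")
    lines.append("  </Reagents>")
    if doc.metadata:
        attrs = "".join(f' {k}="{_quote(str(v))}"' for k, v in sorted(doc.metadata.items()))
        lines.append(f"  <Metadata{attrs} />")
    lines.append("  <Procedure>")
    for step in doc.procedure:
        lines.extend(_step_lines(step, registry, 2))
    lines.append("  </Procedure>")
    lines.append("</Synthesis>")
    return "\n".join(lines) + "\n"


def expand_procedure(doc: XDLDocument) -> List[XDLStep]:
    """Flatten the procedure, expanding ``Repeat`` blocks in order.

    The returned list defines the step indexing used by the simulator and
    the volume ledger.
    """
    out: List[XDLStep] = []

    def rec(steps: Sequence[XDLStep]) -> None:
        for step in steps:
            if step.step_name == "Repeat":
                repeats = step.attributes.get("repeats", 1)
                count = repeats if isinstance(repeats, int) else 1
                for _ in range(count):
                    rec(step.children)
            else:
                out.append(step)

    rec(doc.procedure)
    return out
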