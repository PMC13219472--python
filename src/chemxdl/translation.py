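"""Translation of sanitized procedures into validated XDL.

The central loop: a translation agent drafts XDL from the sanitized
procedure (with retrieval-augmented few-shot pairs from the validated-XDL
store), and the draft passes through three validation stages —

1. **validity**: exhaustive parse + schema/unit/reference checking;
2. **discrepancy**: an LLM-as-a-judge critique comparing procedure and
   XDL (missing, disordered, extraneous, non-executable steps);
3. **simulation**: automatic vessel mapping onto the hardware graph and
   hardware-constrained execution simulation.

Failures at any stage become structured feedback for the next iteration;
the loop stops at the first fully clean pass or after a hard maximum of
iterations (default 6).  A later stage only runs once every earlier stage
is clean, and a discrepancy report blocks only when it contains missing
or disordered steps — non-executable entries are harvested for the
roadmap and, when an approximating step exists, do not block.

Valid results are persisted to the validated-XDL store and the labbook,
keyed by content hash so re-runs are idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from string import Template
from typing import Dict, List, Optional, Sequence, Tuple, Union

import json

from .config import WorkflowConfig
from .extraction import _strip_fences
from .hardware import HardwareGraph, MappingError, map_vessels
from .memory import (Labbook, LabbookEntry, VectorStore, retrievable_xdl,
                     seed_xdl_store)
from .providers import (CompletionProvider, CompletionRequest, SchemaError)
from .sanitization import SanitizedProcedure
from .simulator import SimulationError, simulate
from .xdl_core import (DEFAULT_REGISTRY, StepSchema, ValidationIssue,
                       XDLDocument, parse_xdl)


def load_prompt(name: str) -> Template:
    text = resources.files("chemxdl.data.prompts").joinpath(f"{name}.txt").read_text()
    return Template(text)


# --------------------------------------------------------------------------
# Context


@dataclass
class TranslationContext:
    procedure: SanitizedProcedure
    few_shot: List[Tuple[str, str]] = field(default_factory=list)  # (proc, xdl)
    registry: Dict[str, StepSchema] = field(default_factory=lambda: dict(DEFAULT_REGISTRY))
    ambiguity_notes: List[str] = field(default_factory=list)
    snippets: List[str] = field(default_factory=list)


def build_context(
    proc: SanitizedProcedure,
    store: Optional[VectorStore],
    registry: Optional[Dict[str, StepSchema]] = None,
    k: int = 5,
    snippet_k: int = 2,
    no_xdl_db: bool = False,
) -> TranslationContext:
    """Assemble the translation context: top-k validated few-shot pairs by
    whole-procedure cosine similarity, ambiguity notes, document snippets
    and the (possibly platform-restricted) step registry."""
    ctx = TranslationContext(
        proc, registry=dict(registry) if registry else dict(DEFAULT_REGISTRY))
    ctx.ambiguity_notes = [
        f"'{a.fragment}': {a.explanation}" for a in proc.applied_ambiguities]
    if store is not None:
        if not no_xdl_db and store.records("xdl-db"):
            hits = store.query(proc.sanitized_text, "xdl-db", k,
                               where=retrievable_xdl)
            ctx.few_shot = [(r.text, str(r.metadata["xdl"])) for r, _ in hits]
        if store.records("doc-db"):
            ctx.snippets = [r.text for r, _ in
                            store.query(proc.sanitized_text, "doc-db", snippet_k)]
    return ctx


def _registry_doc(registry: Dict[str, StepSchema]) -> str:
    lines = []
    for name in sorted(registry):
        schema = registry[name]
        req = ", ".join(f"{a}:{k}" for a, k in schema.required_attrs)
        opt = ", ".join(f"{a}:{k}" for a, k in schema.optional_attrs)
        lines.append(f"- {name}(required: {req or 'none'}; optional: {opt or 'none'})")
    return "\n".join(lines)


def render_translate_prompt(ctx: TranslationContext) -> str:
    few_shot = "\n\n".join(
        f"PROCEDURE:\n{p}\nXDL:\n{x}" for p, x in ctx.few_shot) or "(none)"
    return load_prompt("translate").substitute(
        registry=_registry_doc(ctx.registry),
        few_shot=few_shot,
        ambiguities="\n".join(f"- {n}" for n in ctx.ambiguity_notes) or "(none)",
        snippets="\n---\n".join(ctx.snippets) or "(none)",
        procedure=ctx.procedure.sanitized_text,
    )


_FENCE_RE = re.compile(r"```(?:xml|xdl)?\s*\n(.*?)```", re.DOTALL)


def extract_xdl_block(text: str) -> Optional[str]:
    matches = _FENCE_RE.findall(text)
    return matches[-1].strip() + "\n" if matches else None


def translate(ctx: TranslationContext, llm: CompletionProvider) -> str:
    """Produce the first draft; the full response's fenced block is the XDL."""
    response = llm.complete(
        CompletionRequest("translate", render_translate_prompt(ctx)))
    return response.text


# --------------------------------------------------------------------------
# Critique


@dataclass
class DiscrepancyReport:
    missing_steps: List[Tuple[str, str]] = field(default_factory=list)
    disordered_steps: List[str] = field(default_factory=list)
    extraneous_steps: List[str] = field(default_factory=list)
    non_executable_steps: List[Tuple[str, str]] = field(default_factory=list)
    low_confidence: bool = False

    @property
    def blocking(self) -> bool:
        """Missing or disordered steps block; extraneous steps only warn and
        non-executable steps are harvested for the roadmap."""
        return bool(self.missing_steps or self.disordered_steps)

    @property
    def empty(self) -> bool:
        return not (self.missing_steps or self.disordered_steps
                    or self.extraneous_steps or self.non_executable_steps)

    def summary(self) -> str:
        parts = []
        for span, desc in self.missing_steps:
            parts.append(f"missing step: '{span}' — {desc}")
        for item in self.disordered_steps:
            parts.append(f"disordered step: {item}")
        for item in self.extraneous_steps:
            parts.append(f"extraneous step (warning): {item}")
        for span, desc in self.non_executable_steps:
            parts.append(f"non-executable step: '{span}' — {desc}")
        return "\n".join(parts) or "no discrepancies"


def _validate_critique(text: str) -> DiscrepancyReport:
    try:
        raw = json.loads(_strip_fences(text))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"critique payload is not JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError("critique payload must be a JSON object")

    def pairs(key: str) -> List[Tuple[str, str]]:
        out = []
        for item in raw.get(key, []):
            if not isinstance(item, dict) or "span" not in item:
                raise SchemaError(f"entries of {key} need span/description")
            out.append((str(item["span"]), str(item.get("description", ""))))
        return out

    return DiscrepancyReport(
        missing_steps=pairs("missing_steps"),
        disordered_steps=[str(x) for x in raw.get("disordered_steps", [])],
        extraneous_steps=[str(x) for x in raw.get("extraneous_steps", [])],
        non_executable_steps=pairs("non_executable_steps"),
    )


def critique(proc: SanitizedProcedure, xdl_text: str,
             llm: CompletionProvider, max_retries: int = 2) -> DiscrepancyReport:
    """LLM-as-a-judge discrepancy check between procedure and XDL.

    Schema-invalid provider output is re-asked; persistent failure yields
    an empty report flagged low-confidence rather than an exception.
    """
    prompt = load_prompt("critique").substitute(
        procedure=proc.sanitized_text, xdl=xdl_text)
    response = llm.complete(CompletionRequest(
        "critique", prompt, _validate_critique, max_retries))
    if not response.ok or response.payload is None:
        return DiscrepancyReport(low_confidence=True)
    return response.payload


# --------------------------------------------------------------------------
# Feedback and refinement


@dataclass
class FeedbackItem:
    stage: str  # validity | discrepancy | simulation
    payload: Union[List[ValidationIssue], DiscrepancyReport,
                   List[SimulationError], str]

    def render(self) -> str:
        if self.stage == "validity":
            assert isinstance(self.payload, list)
            return "\n".join(str(i) for i in self.payload)
        if self.stage == "discrepancy":
            assert isinstance(self.payload, DiscrepancyReport)
            return self.payload.summary()
        if isinstance(self.payload, str):
            return self.payload
        return "\n".join(
            f"step {e.step_index}: {e.code}: {e.message}" for e in self.payload)


def refine(draft: str, feedback: Sequence[FeedbackItem],
           ctx: TranslationContext, llm: CompletionProvider) -> str:
    """One repair turn: errors with locations are presented and the agent
    must map them to lines before emitting the corrected document."""
    if not feedback:
        raise ValueError("refine requires non-empty feedback")
    rendered = "\n".join(
        f"[stage: {item.stage}]\n{item.render()}" for item in feedback)
    prompt = load_prompt("refine").substitute(
        registry=_registry_doc(ctx.registry), feedback=rendered, draft=draft,
        procedure=ctx.procedure.sanitized_text)
    return llm.complete(CompletionRequest("refine", prompt)).text


# --------------------------------------------------------------------------
# The pipeline


NO_XDL_BLOCK = ValidationIssue(
    "NO_XDL_BLOCK", "syntax", "error", "/",
    "response contains no fenced XDL block")


@dataclass
class IterationTrace:
    iteration: int
    draft: str
    stage_reached: str
    feedback: List[FeedbackItem] = field(default_factory=list)


@dataclass
class TranslationResult:
    status: str  # valid | failed_validity | failed_discrepancy | failed_simulation
    final_document: Optional[XDLDocument] = None
    final_xdl: Optional[str] = None
    iterations_used: int = 0
    trace: List[IterationTrace] = field(default_factory=list)
    non_executable: List[Tuple[str, str]] = field(default_factory=list)
    labbook_id: Optional[str] = None


def run_pipeline(
    proc: SanitizedProcedure,
    graph: HardwareGraph,
    llm: CompletionProvider,
    cfg: Optional[WorkflowConfig] = None,
    store: Optional[VectorStore] = None,
    labbook: Optional[Labbook] = None,
    registry: Optional[Dict[str, StepSchema]] = None,
    no_xdl_db: bool = False,
    source_document: str = "",
    analytics: Optional[List[Dict[str, str]]] = None,
) -> TranslationResult:
    """Translate → validate → feedback → translate, up to the configured
    maximum number of iterations.

    Per iteration: generate (initial translate counts as iteration 1, each
    repair as one more) → validity check → if clean, critique → if no
    blocking discrepancies, vessel mapping + simulation → if clean, the
    result is valid and is persisted.  All failure modes are statuses,
    never exceptions.
    """
    cfg = cfg or WorkflowConfig()
    if proc.category == "incomplete":
        raise ValueError("incomplete procedures are rejected upstream of "
                         "translation")
    ctx = build_context(proc, store, registry, cfg.few_shot_k,
                        no_xdl_db=no_xdl_db)
    result = TranslationResult(status="failed_validity")
    draft_response: Optional[str] = None
    feedback: List[FeedbackItem] = []
    harvested: List[Tuple[str, str]] = []

    for iteration in range(1, cfg.max_repair_iterations + 1):
        result.iterations_used = iteration
        if iteration == 1:
            draft_response = translate(ctx, llm)
        else:
            draft_response = refine(draft_response or "", feedback, ctx, llm)
        trace = IterationTrace(iteration, draft_response, "validity")
        result.trace.append(trace)
        feedback = []

        xdl_text = extract_xdl_block(draft_response)
        if xdl_text is None:
            feedback = [FeedbackItem("validity", [NO_XDL_BLOCK])]
            trace.feedback = feedback
            result.status = "failed_validity"
            continue
        draft_response = xdl_text  # refine sees the extracted document

        # stage 1: validity
        try:
            doc, issues = parse_xdl(xdl_text, ctx.registry)
        except Exception as exc:
            doc, issues = None, [ValidationIssue(
                "PARSE_FAILURE", "syntax", "error", "/", str(exc))]
        errors = [i for i in issues if i.severity == "error"]
        if doc is None or errors:
            feedback = [FeedbackItem("validity", errors)]
            trace.feedback = feedback
            result.status = "failed_validity"
            continue

        # stage 2: discrepancy critique
        trace.stage_reached = "discrepancy"
        report = critique(proc, xdl_text, llm)
        harvested.extend(report.non_executable_steps)
        if report.blocking:
            feedback = [FeedbackItem("discrepancy", report)]
            trace.feedback = feedback
            result.status = "failed_discrepancy"
            continue

        # stage 3: hardware mapping + simulation
        trace.stage_reached = "simulation"
        try:
            mapping = map_vessels(doc, graph)
        except MappingError as exc:
            feedback = [FeedbackItem("simulation", str(exc))]
            trace.feedback = feedback
            result.status = "failed_simulation"
            continue
        sim = simulate(doc, graph, mapping)
        harvested.extend(
            (name, f"step '{name}' has no simulation support")
            for _, name in sim.unsupported)
        if sim.errors:
            feedback = [FeedbackItem("simulation", sim.errors)]
            trace.feedback = feedback
            result.status = "failed_simulation"
            continue

        # all three stages clean
        trace.stage_reached = "valid"
        result.status = "valid"
        result.final_document = doc
        result.final_xdl = xdl_text
        if store is not None:
            seed_xdl_store(store, [(proc.sanitized_text, xdl_text)],
                           ctx.registry)
        if labbook is not None:
            entry = LabbookEntry(
                source_document=source_document,
                procedure_text=proc.original_text,
                xdl=xdl_text,
                resolved_ambiguities=[
                    {"fragment": a.fragment, "explanation": a.explanation}
                    for a in proc.applied_ambiguities],
                analytics=analytics or [],
            )
            result.labbook_id = labbook.write(entry)
        break

    result.non_executable = harvested
    return result
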