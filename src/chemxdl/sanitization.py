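"""Procedure sanitization: classify, enrich, disambiguate, rewrite.

Before translation a procedure is (1) classified as ``executable``,
``blueprint`` (a general-method description) or ``incomplete``; (2) its
chemicals are enriched with physicochemical data from a local solvent
table and a cache-first chemical-information adapter; (3) ambiguity
guidance is retrieved from the chemical ambiguity database (CAD) by
per-sentence cosine similarity; and (4) the text is rewritten into a
complete, self-contained form by the procedure agent, with every edit
logged as a reconstructible (span, before, after, reason) record — the
audit surface for language-model edits.

Classification fails safe: anything the provider cannot place in the
closed category set lands in ``incomplete``, never ``executable``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Protocol, Sequence, Tuple

from .extraction import ProcedureRecord, _strip_fences, normalize_name
from .memory import VectorStore
from .providers import (CompletionProvider, CompletionRequest, SchemaError)

CATEGORIES = ("executable", "blueprint", "incomplete")


# --------------------------------------------------------------------------
# Classification


CLASSIFY_PROMPT = """Classify the following synthesis procedure as exactly one \
of: executable (complete and directly runnable), blueprint (a general method \
description requiring instantiation), incomplete (missing required \
information). Answer with the single category word.

PROCEDURE:
{text}
"""


def _validate_category(text: str) -> str:
    label = text.strip().lower().strip(".\"'")
    if label not in CATEGORIES:
        raise SchemaError(
            f"'{label}' is not one of {CATEGORIES}; answer with one word")
    return label


def classify_procedure(proc: ProcedureRecord, llm: CompletionProvider,
                       max_retries: int = 2) -> str:
    """Classify a procedure; out-of-vocabulary answers are re-asked up to
    *max_retries* times, then fail safe to ``incomplete``."""
    response = llm.complete(CompletionRequest(
        "classify", CLASSIFY_PROMPT.format(text=proc.text),
        _validate_category, max_retries))
    if response.ok and response.payload in CATEGORIES:
        return str(response.payload)
    return "incomplete"


# --------------------------------------------------------------------------
# Chemical enrichment


@dataclass
class ChemicalInfo:
    query: str
    iupac_name: Optional[str] = None
    molar_mass: Optional[float] = None  # g/mol
    boiling_point: Optional[float] = None  # °C
    density: Optional[float] = None  # g/mL
    source: str = "unresolved"  # pubchem-adapter | solvent-db | unresolved
    reason: Optional[str] = None


class ChemicalAdapter(Protocol):
    def lookup(self, name: str) -> Optional[ChemicalInfo]: ...


def _load_data(filename: str) -> dict:
    return json.loads(
        resources.files("chemxdl.data").joinpath(filename).read_text())


class SolventDB:
    """In-repo table of ~40 common solvents with boiling points/densities."""

    def __init__(self, raw: Optional[dict] = None):
        raw = raw or _load_data("solvents.json")
        self.solvents: Dict[str, dict] = raw["solvents"]
        self.aliases: Dict[str, str] = raw.get("aliases", {})

    def resolve(self, name: str) -> Optional[str]:
        key = normalize_name(name)
        key = self.aliases.get(key, key)
        return key if key in self.solvents else None

    def lookup(self, name: str) -> Optional[ChemicalInfo]:
        key = self.resolve(name)
        if key is None:
            return None
        entry = self.solvents[key]
        return ChemicalInfo(name, iupac_name=key,
                            boiling_point=entry.get("boiling_point"),
                            density=entry.get("density"), source="solvent-db")

    @property
    def known_names(self) -> List[str]:
        return list(self.solvents) + list(self.aliases)


class CachedChemicalAdapter:
    """Cache-first adapter over the shipped chemical-information fixture.

    Stands in for a remote chemical-database adapter so no test ever
    touches a network; a live adapter implements the same ``lookup``.
    """

    def __init__(self, cache: Optional[dict] = None):
        raw = cache if cache is not None else _load_data("chemical_info.json")
        self.cache = {k: v for k, v in raw.items() if not k.startswith("_")}

    def lookup(self, name: str) -> Optional[ChemicalInfo]:
        entry = self.cache.get(normalize_name(name))
        if entry is None:
            return None
        return ChemicalInfo(name, iupac_name=entry.get("iupac_name"),
                            molar_mass=entry.get("molar_mass"),
                            boiling_point=entry.get("boiling_point"),
                            source="pubchem-adapter")

    @property
    def known_names(self) -> List[str]:
        return list(self.cache)


def detect_chemicals(text: str, known_names: Sequence[str]) -> List[str]:
    """Find known chemical names mentioned in *text* (word-boundary,
    case-insensitive; longest names matched first)."""
    found = []
    seen = set()
    for name in sorted(known_names, key=len, reverse=True):
        if normalize_name(name) in seen:
            continue
        if re.search(rf"(?<!\w){re.escape(name)}(?!\w)", text, re.IGNORECASE):
            found.append(name)
            seen.add(normalize_name(name))
    return found


def enrich_chemicals(
    proc: ProcedureRecord,
    adapter: Optional[ChemicalAdapter] = None,
    solvents: Optional[SolventDB] = None,
    extra_names: Sequence[str] = (),
) -> List[ChemicalInfo]:
    """Attach physicochemical data to every chemical detected in the
    procedure.

    The local solvent table is consulted before the remote adapter;
    unresolved names are flagged, never dropped.  Adapter failures
    (network, absence) degrade to ``unresolved`` entries with a reason and
    the pipeline continues.
    """
    solvents = solvents or SolventDB()
    adapter = adapter if adapter is not None else CachedChemicalAdapter()
    known = set(solvents.known_names) | set(getattr(adapter, "known_names", []))
    known |= set(extra_names)
    out: List[ChemicalInfo] = []
    for name in detect_chemicals(proc.text, sorted(known)):
        info = solvents.lookup(name)
        if info is None:
            try:
                info = adapter.lookup(name)
            except Exception as exc:  # adapter failure: degrade, continue
                info = ChemicalInfo(name, reason=f"adapter failure: {exc}")
        if info is None:
            info = ChemicalInfo(name, reason="not found in any source")
        out.append(info)
    return out


# --------------------------------------------------------------------------
# Ambiguity retrieval and the expert channel


@dataclass
class AmbiguityEntry:
    fragment: str
    explanation: str
    record_id: Optional[str] = None


def seed_cad(store: VectorStore,
             entries: Optional[Sequence[dict]] = None) -> int:
    """Load the shipped (non-canonical) ambiguity seed into the CAD."""
    entries = entries if entries is not None else _load_data("cad_seed.json")["entries"]
    count = 0
    for e in entries:
        store.add_text("cad", e["fragment"],
                       {"explanation": e["explanation"]})
        count += 1
    return count


_SENTENCE_RE = re.compile(r"(?<=[.!?])\s+")


def split_sentences(text: str) -> List[str]:
    return [s for s in _SENTENCE_RE.split(text) if s.strip()]


def retrieve_ambiguities(
    proc: ProcedureRecord, store: VectorStore, k: int
) -> List[AmbiguityEntry]:
    """Top ambiguity matches for a procedure, at most *k* in total.

    Each sentence queries the CAD; candidates are pooled, deduplicated by
    record id (keeping the best score) and the global top-k returned.
    Deterministic under the deterministic mock embedding.
    """
    if not store.records("cad"):
        return []
    best: Dict[str, Tuple[float, AmbiguityEntry]] = {}
    for order, sentence in enumerate(split_sentences(proc.text)):
        for rec, score in store.query(sentence, "cad", k):
            entry = AmbiguityEntry(rec.text,
                                   str(rec.metadata.get("explanation", "")),
                                   rec.id)
            if rec.id not in best or score > best[rec.id][0]:
                best[rec.id] = (score, entry)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [entry for _, (_, entry) in ranked[:k]]


class ExpertChannel(Protocol):
    def ask(self, fragment: str, question: str) -> Optional[str]: ...


class ScriptedExpertChannel:
    """Answers from a scripted mapping question -> answer (an answer file)."""

    def __init__(self, answers: Dict[str, str]):
        self.answers = {normalize_name(q): a for q, a in answers.items()}

    @classmethod
    def from_file(cls, path: str) -> "ScriptedExpertChannel":
        return cls(json.loads(open(path).read()))

    def ask(self, fragment: str, question: str) -> Optional[str]:
        return self.answers.get(normalize_name(question))


class SilentExpertChannel:
    def ask(self, fragment: str, question: str) -> Optional[str]:
        return None


def ask_expert(
    fragment: str, question: str, channel: ExpertChannel, store: VectorStore
) -> Optional[AmbiguityEntry]:
    """Put a question to the expert channel and persist the answer to CAD.

    Re-asking an already-answered question returns the existing entry
    without duplicating it (dedup by normalized fragment+question); a
    silent channel returns None, leaving the question pending.
    """
    dedup_key = normalize_name(fragment) + "||" + normalize_name(question)
    for rec in store.records("cad"):
        if rec.metadata.get("dedup_key") == dedup_key:
            return AmbiguityEntry(rec.text,
                                  str(rec.metadata.get("explanation", "")),
                                  rec.id)
    answer = channel.ask(fragment, question)
    if answer is None:
        return None
    rec = store.add_text("cad", fragment, {
        "explanation": answer, "question": question, "dedup_key": dedup_key})
    return AmbiguityEntry(fragment, answer, rec.id)


# --------------------------------------------------------------------------
# Sanitization proper


@dataclass(frozen=True)
class Edit:
    start: int
    end: int
    before: str
    after: str
    reason: str


def apply_edits(original: str, edits: Sequence[Edit]) -> str:
    """Apply span edits to *original*; raises ValueError on inconsistent
    spans (spans index the original text and must not overlap)."""
    out = original
    for e in sorted(edits, key=lambda e: e.start, reverse=True):
        if original[e.start:e.end] != e.before:
            raise ValueError(
                f"edit span [{e.start}:{e.end}] does not match 'before' text")
        out = out[:e.start] + e.after + out[e.end:]
    return out


@dataclass
class SanitizedProcedure:
    original_text: str
    sanitized_text: str
    category: str
    chemicals: List[ChemicalInfo] = field(default_factory=list)
    applied_ambiguities: List[AmbiguityEntry] = field(default_factory=list)
    open_questions: List[Tuple[str, Optional[str]]] = field(default_factory=list)
    edits: List[Edit] = field(default_factory=list)
    sanitization_failed: bool = False
    procedure_id: Optional[str] = None
    language: str = "en"


SANITIZE_PROMPT = """You are a chemistry procedure-sanitization agent. Rewrite \
the procedure below into complete, self-contained natural language: resolve \
references to general procedures using the retrieved snippets, replace \
non-executable manipulations with chemically equivalent executable ones, and \
fix obvious reporting errors. Return JSON: {{"sanitized_text": str, "edits": \
[{{"start": int, "end": int, "before": str, "after": str, "reason": str}}], \
"open_questions": [str]}}. Spans index the ORIGINAL text; applying the edits \
must reproduce sanitized_text exactly.

CHEMICAL DATA:
{chemicals}

AMBIGUITY NOTES:
{ambiguities}

DOCUMENT SNIPPETS:
{snippets}

PROCEDURE:
{text}
"""


def _make_sanitize_validator(original: str):
    def validate(text: str) -> dict:
        try:
            payload = json.loads(_strip_fences(text))
        except json.JSONDecodeError as exc:
            raise SchemaError(f"not valid JSON: {exc}") from exc
        if not isinstance(payload, dict) or "sanitized_text" not in payload:
            raise SchemaError("payload must be an object with sanitized_text")
        edits = []
        for raw in payload.get("edits", []):
            try:
                edits.append(Edit(int(raw["start"]), int(raw["end"]),
                                  str(raw["before"]), str(raw["after"]),
                                  str(raw.get("reason", ""))))
            except (KeyError, TypeError, ValueError) as exc:
                raise SchemaError(f"bad edit record: {exc}") from exc
        try:
            rebuilt = apply_edits(original, edits)
        except ValueError as exc:
            raise SchemaError(str(exc)) from exc
        if rebuilt != payload["sanitized_text"]:
            raise SchemaError(
                "applying the edit log to the original does not reproduce "
                "sanitized_text")
        payload["_edits"] = edits
        return payload
    return validate


def sanitize(
    proc: ProcedureRecord,
    llm: CompletionProvider,
    category: Optional[str] = None,
    chemicals: Optional[List[ChemicalInfo]] = None,
    ambiguities: Optional[List[AmbiguityEntry]] = None,
    snippets: Sequence[str] = (),
    max_retries: int = 2,
) -> SanitizedProcedure:
    """Produce a translation-ready sanitized procedure.

    The provider must return the sanitized text together with a span edit
    log over the original; a log that does not reconstruct the sanitized
    text is rejected and re-asked.  On persistent provider failure the
    original text passes through unchanged with ``sanitization_failed``
    set.
    """
    chemicals = chemicals if chemicals is not None else []
    ambiguities = ambiguities if ambiguities is not None else []
    prompt = SANITIZE_PROMPT.format(
        chemicals="\n".join(
            f"- {c.query}: iupac={c.iupac_name}, M={c.molar_mass} g/mol, "
            f"bp={c.boiling_point} °C [{c.source}]" for c in chemicals) or "(none)",
        ambiguities="\n".join(
            f"- '{a.fragment}': {a.explanation}" for a in ambiguities) or "(none)",
        snippets="\n---\n".join(snippets) or "(none)",
        text=proc.text,
    )
    response = llm.complete(CompletionRequest(
        "sanitize", prompt, _make_sanitize_validator(proc.text), max_retries))
    if not response.ok or response.payload is None:
        return SanitizedProcedure(
            proc.text, proc.text, category or "incomplete", chemicals,
            ambiguities, [], [], sanitization_failed=True,
            procedure_id=proc.id, language=proc.language)
    payload = response.payload
    return SanitizedProcedure(
        original_text=proc.text,
        sanitized_text=payload["sanitized_text"],
        category=category or "executable",
        chemicals=chemicals,
        applied_ambiguities=ambiguities,
        open_questions=[(q, None) for q in payload.get("open_questions", [])],
        edits=payload["_edits"],
        procedure_id=proc.id,
        language=proc.language,
    )


def sanitize_procedure(
    proc: ProcedureRecord,
    llm: CompletionProvider,
    store: Optional[VectorStore] = None,
    adapter: Optional[ChemicalAdapter] = None,
    solvents: Optional[SolventDB] = None,
    ambiguity_k: int = 5,
    snippet_k: int = 2,
    no_cad: bool = False,
    no_chem_info: bool = False,
) -> SanitizedProcedure:
    """Full procedure-agent pass: classify, enrich, retrieve, sanitize."""
    category = classify_procedure(proc, llm)
    chemicals = [] if no_chem_info else enrich_chemicals(proc, adapter, solvents)
    ambiguities: List[AmbiguityEntry] = []
    snippets: List[str] = []
    if store is not None and not no_cad:
        ambiguities = retrieve_ambiguities(proc, store, ambiguity_k)
    if store is not None and store.records("doc-db"):
        snippets = [rec.text for rec, _ in
                    store.query(proc.text, "doc-db", snippet_k)]
    result = sanitize(proc, llm, category, chemicals, ambiguities, snippets)
    return result
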