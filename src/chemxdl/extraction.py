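"""Scraping stage: chunk documents, extract synthesis data, build the KG.

A source document is chunked into token-bounded fragments, each fragment
is handed to the extraction agent (any completion provider) which returns
a JSON payload in the versioned extraction schema, and the per-chunk
partial knowledge graphs are merged into one :class:`DocumentKG`:
chemical entities (with abbreviations and synonyms, deduplicated by
union–find over shared normalized names), verbatim procedure texts,
purification notes and analytical records.  The document is additionally
indexed into the ``doc-db`` vector collection in 2048-token chunks for
snippet retrieval during translation.

Also home to the set-based precision/recall/F1 scorer used to evaluate
entity extraction against a gold list.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .config import DEFAULT_TOKENIZER, CharTokenizer
from .memory import VectorStore
from .providers import CompletionProvider, CompletionRequest, SchemaError

EXTRACTION_SCHEMA_VERSION = "extraction.v1"

# --------------------------------------------------------------------------
# Chunking


@dataclass(frozen=True)
class DocumentChunk:
    index: int
    text: str
    token_span: Tuple[int, int]  # [start, end) in the document token stream


def chunk_text(
    text: str, limit: int, tokenizer: Optional[CharTokenizer] = None
) -> List[DocumentChunk]:
    """Split *text* into ordered, non-overlapping, covering chunks of at
    most *limit* tokens.

    Concatenating the chunk texts reproduces the input exactly.  Within
    the last 10% of a window the split prefers a paragraph break so
    procedures are less likely to be cut mid-sentence; otherwise the cut
    is hard at the token boundary.
    """
    if limit <= 0:
        raise ValueError("chunk limit must be positive")
    tok = tokenizer or DEFAULT_TOKENIZER
    if not text:
        return []
    window = tok.chars_for_tokens(limit)
    chunks: List[DocumentChunk] = []
    pos = 0
    token_pos = 0
    while pos < len(text):
        end = min(pos + window, len(text))
        if end < len(text):
            # prefer a paragraph break in the last 10% of the window
            soft = text.rfind("\n\n", pos + int(0.9 * window), end)
            if soft > pos:
                end = soft + 2
        piece = text[pos:end]
        ntok = tok.count(piece)
        chunks.append(DocumentChunk(len(chunks), piece,
                                    (token_pos, token_pos + ntok)))
        token_pos += ntok
        pos = end
    return chunks


# --------------------------------------------------------------------------
# Extraction schema (versioned, the contract the scraping agent must meet)


class ChemicalPayload(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = Field(min_length=1)
    abbreviations: List[str] = Field(default_factory=list)
    synonyms: List[str] = Field(default_factory=list)


class ProcedurePayload(BaseModel):
    model_config = ConfigDict(extra="forbid")
    text: str = Field(min_length=1)
    product: Optional[str] = None
    language: str = "en"


class AnalyticalPayload(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = Field(pattern="^(NMR|MS|IR|melting-point|other)$")
    text: str = Field(min_length=1)


class ExtractionPayload(BaseModel):
    """The JSON object the scraping agent must return per chunk."""

    model_config = ConfigDict(extra="forbid")
    chemicals: List[ChemicalPayload] = Field(default_factory=list)
    procedures: List[ProcedurePayload] = Field(default_factory=list)
    purifications: List[str] = Field(default_factory=list)
    analytics: List[AnalyticalPayload] = Field(default_factory=list)
    notes: List[str] = Field(default_factory=list)


def validate_extraction(text: str) -> ExtractionPayload:
    """Provider-output validator for the extraction schema."""
    try:
        return ExtractionPayload.model_validate(json.loads(_strip_fences(text)))
    except (json.JSONDecodeError, ValidationError) as exc:
        raise SchemaError(f"invalid extraction payload: {exc}") from exc


def _strip_fences(text: str) -> str:
    m = re.search(r"```(?:json)?\s*(.*?)```", text, re.DOTALL)
    return m.group(1) if m else text


# --------------------------------------------------------------------------
# Knowledge graph model


@dataclass
class ChemicalEntity:
    canonical_name: str
    abbreviations: List[str] = field(default_factory=list)
    synonyms: List[str] = field(default_factory=list)

    @property
    def all_names(self) -> List[str]:
        return [self.canonical_name] + self.abbreviations + self.synonyms


@dataclass
class ProcedureRecord:
    id: str
    text: str
    product: Optional[str] = None
    source_chunks: List[int] = field(default_factory=list)
    language: str = "en"


@dataclass
class AnalyticalRecord:
    kind: str
    text: str
    procedure_id: Optional[str] = None


@dataclass
class DocumentKG:
    entities: List[ChemicalEntity] = field(default_factory=list)
    procedures: List[ProcedureRecord] = field(default_factory=list)
    purifications: List[str] = field(default_factory=list)
    analytics: List[AnalyticalRecord] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)
    failures: List[Dict[str, object]] = field(default_factory=list)
    doc_ref: Optional[str] = None
    source_chunks: List[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "entities": [
                {"canonical_name": e.canonical_name,
                 "abbreviations": e.abbreviations, "synonyms": e.synonyms}
                for e in self.entities
            ],
            "procedures": [
                {"id": p.id, "text": p.text, "product": p.product,
                 "source_chunks": p.source_chunks, "language": p.language}
                for p in self.procedures
            ],
            "purifications": self.purifications,
            "analytics": [
                {"kind": a.kind, "text": a.text, "procedure_id": a.procedure_id}
                for a in self.analytics
            ],
            "notes": self.notes,
            "failures": self.failures,
            "doc_ref": self.doc_ref,
            "source_chunks": self.source_chunks,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DocumentKG":
        raw = json.loads(text)
        return cls(
            entities=[ChemicalEntity(e["canonical_name"], e["abbreviations"],
                                     e["synonyms"]) for e in raw["entities"]],
            procedures=[ProcedureRecord(p["id"], p["text"], p.get("product"),
                                        p.get("source_chunks", []),
                                        p.get("language", "en"))
                        for p in raw["procedures"]],
            purifications=raw.get("purifications", []),
            analytics=[AnalyticalRecord(a["kind"], a["text"],
                                        a.get("procedure_id"))
                       for a in raw.get("analytics", [])],
            notes=raw.get("notes", []),
            failures=raw.get("failures", []),
            doc_ref=raw.get("doc_ref"),
            source_chunks=raw.get("source_chunks", []),
        )


# --------------------------------------------------------------------------
# Per-chunk extraction


EXTRACT_PROMPT = """You are a chemistry data-extraction agent. From the text \
below, extract all chemical names with their abbreviations and synonyms, all \
verbatim synthesis procedure texts, purification data, analytical data (NMR, \
MS, IR, melting-point) and any additional notes. Respond with a single JSON \
object with keys: chemicals, procedures, purifications, analytics, notes \
(schema {version}).

TEXT:
{text}
"""


def extract_chunk(
    chunk: DocumentChunk, llm: CompletionProvider, max_retries: int = 2
) -> DocumentKG:
    """Extract one chunk into a partial KG via the completion provider.

    Provider output is validated against the extraction schema and
    re-asked up to *max_retries* times; persistent failure is recorded as
    a failure entry on the partial KG and the pipeline continues.
    """
    prompt = EXTRACT_PROMPT.format(version=EXTRACTION_SCHEMA_VERSION,
                                   text=chunk.text)
    response = llm.complete(CompletionRequest(
        "extract", prompt, validate_extraction, max_retries))
    partial = DocumentKG(source_chunks=[chunk.index])
    if not response.ok or response.payload is None:
        partial.failures.append({
            "chunk": chunk.index, "retries": response.retries_used,
            "reason": "schema-invalid provider output"})
        return partial
    payload: ExtractionPayload = response.payload
    partial.entities = [
        ChemicalEntity(c.name, list(c.abbreviations), list(c.synonyms))
        for c in payload.chemicals
    ]
    partial.procedures = [
        ProcedureRecord(f"chunk{chunk.index}-proc{i}", p.text, p.product,
                        [chunk.index], p.language)
        for i, p in enumerate(payload.procedures)
    ]
    partial.purifications = list(payload.purifications)
    partial.analytics = [AnalyticalRecord(a.kind, a.text)
                         for a in payload.analytics]
    partial.notes = list(payload.notes)
    return partial


# --------------------------------------------------------------------------
# Merging


def normalize_name(name: str) -> str:
    return " ".join(name.lower().split())


class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[int, int] = {}

    def find(self, x: int) -> int:
        while self.parent.setdefault(x, x) != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_kgs(partials: Sequence[DocumentKG]) -> DocumentKG:
    """Merge per-chunk partial KGs into one document KG.

    Entities are deduplicated by union–find over shared normalized names
    (canonical, abbreviation or synonym); procedures are concatenated in
    chunk order and re-identified; no source record is lost.  Idempotent
    and order-insensitive up to the canonical ordering (entities sorted
    by normalized canonical name, procedures by source chunk).
    """
    parts = sorted(partials, key=lambda p: min(p.source_chunks, default=0))
    flat: List[ChemicalEntity] = [e for p in parts for e in p.entities]
    uf = _UnionFind()
    by_name: Dict[str, int] = {}
    for i, entity in enumerate(flat):
        for name in entity.all_names:
            key = normalize_name(name)
            if not key:
                continue
            if key in by_name:
                uf.union(by_name[key], i)
            else:
                by_name[key] = i
    groups: Dict[int, List[ChemicalEntity]] = {}
    for i, entity in enumerate(flat):
        groups.setdefault(uf.find(i), []).append(entity)

    merged_entities = []
    for members in groups.values():
        canonical = max((m.canonical_name for m in members),
                        key=lambda n: (len(n), n))
        seen = {normalize_name(canonical)}
        abbrevs: List[str] = []
        synonyms: List[str] = []
        for m in members:
            for a in m.abbreviations:
                if normalize_name(a) not in seen:
                    seen.add(normalize_name(a))
                    abbrevs.append(a)
            for s in [m.canonical_name] + m.synonyms:
                if normalize_name(s) not in seen:
                    seen.add(normalize_name(s))
                    synonyms.append(s)
        merged_entities.append(
            ChemicalEntity(canonical, sorted(abbrevs), sorted(synonyms)))
    merged_entities.sort(key=lambda e: normalize_name(e.canonical_name))

    out = DocumentKG(entities=merged_entities)
    for p in parts:
        out.purifications.extend(p.purifications)
        out.analytics.extend(p.analytics)
        out.notes.extend(p.notes)
        out.failures.extend(p.failures)
        out.source_chunks.extend(p.source_chunks)
        for proc in p.procedures:
            out.procedures.append(ProcedureRecord(
                f"proc-{len(out.procedures) + 1:04d}", proc.text, proc.product,
                list(proc.source_chunks), proc.language))
    out.source_chunks = sorted(set(out.source_chunks))
    return out


def extract_document(
    text: str, llm: CompletionProvider, chunk_tokens: int = 4096,
    store: Optional[VectorStore] = None, index_tokens: int = 2048,
) -> DocumentKG:
    """Chunk, extract, merge — the full scraping stage for one document."""
    chunks = chunk_text(text, chunk_tokens)
    partials = [extract_chunk(c, llm) for c in chunks]
    kg = merge_kgs(partials) if partials else DocumentKG()
    if store is not None:
        kg.doc_ref = index_document(text, store, index_tokens)
    return kg


# --------------------------------------------------------------------------
# Document indexing


def index_document(text: str, store: VectorStore, limit: int = 2048) -> str:
    """Embed *text* into the doc-db collection in *limit*-token chunks.

    Returns the document reference recorded in the KG.  Empty text yields
    a reference with zero stored records.
    """
    from .memory import content_hash

    doc_id = f"doc-{content_hash(text)}" if text else "doc-empty"
    for chunk in chunk_text(text, limit):
        store.add_text("doc-db", chunk.text, {
            "doc_ref": doc_id, "chunk_index": chunk.index,
            "token_span": list(chunk.token_span)})
    return doc_id


# --------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class ExtractionScores:
    precision: float
    recall: float
    f1: float


def score_extraction(
    predicted: Sequence[str], gold: Sequence[str],
    matcher: Callable[[str], str] = normalize_name,
) -> ExtractionScores:
    """Set-based precision/recall/F1 under a normalization matcher.

    Empty predictions give precision 0 by convention (not undefined);
    F1 is 0 whenever P + R = 0.
    """
    pred = {matcher(x) for x in predicted}
    ref = {matcher(x) for x in gold}
    tp = len(pred & ref)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(ref) if ref else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return ExtractionScores(precision, recall, f1)
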