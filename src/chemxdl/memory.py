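"""Long-term memory: three vector collections and the virtual labbook.

The workflow keeps three exact-scoring (exhaustive cosine) vector
collections:

* ``xdl-db`` — previously validated procedure/XDL pairs, retrieved as
  few-shot examples during translation;
* ``cad`` — the chemical ambiguity database of procedure fragments paired
  with expert explanations;
* ``doc-db`` — 2048-token chunks of source documents for snippet
  retrieval.

Collections persist as JSON-lines files plus a manifest; the labbook is a
directory of JSON entries keyed by content hash (append-only,
idempotent).  No approximate index is used: desk-scale stores stay below
10^4 records and exhaustive scoring makes retrieval exactly testable
against a brute-force oracle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .providers import EmbeddingProvider
from .xdl_core import StepSchema, parse_xdl

COLLECTIONS = ("xdl-db", "cad", "doc-db")


class MemoryError_(ValueError):
    pass


@dataclass
class VectorRecord:
    id: str
    collection: str
    text: str
    vector: np.ndarray
    metadata: Dict[str, object] = field(default_factory=dict)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    denom = float(np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.dot(a, b)) / denom if denom else 0.0


def content_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


class VectorStore:
    """Three named collections with exhaustive cosine retrieval."""

    def __init__(self, embedder: EmbeddingProvider):
        self.embedder = embedder
        self._records: Dict[str, List[VectorRecord]] = {c: [] for c in COLLECTIONS}
        self._counter = 0

    # -- mutation ----------------------------------------------------------
    def add_record(self, rec: VectorRecord) -> VectorRecord:
        if rec.collection not in self._records:
            raise MemoryError_(f"unknown collection '{rec.collection}'")
        if len(rec.vector) != self.embedder.dim:
            raise MemoryError_(
                f"vector length {len(rec.vector)} != configured dim "
                f"{self.embedder.dim}")
        if not np.all(np.isfinite(rec.vector)) or not np.any(rec.vector):
            raise MemoryError_("stored vectors must be finite and non-zero")
        if any(r.id == rec.id for r in self._records[rec.collection]):
            raise MemoryError_(
                f"duplicate record id '{rec.id}' in '{rec.collection}'")
        self._records[rec.collection].append(rec)
        return rec

    def add_text(self, collection: str, text: str,
                 metadata: Optional[Dict[str, object]] = None,
                 record_id: Optional[str] = None) -> VectorRecord:
        self._counter += 1
        rec = VectorRecord(
            id=record_id or f"{collection}-{self._counter:06d}",
            collection=collection,
            text=text,
            vector=self.embedder.embed(text),
            metadata=dict(metadata or {}),
        )
        return self.add_record(rec)

    # -- access ------------------------------------------------------------
    def records(self, collection: str) -> List[VectorRecord]:
        if collection not in self._records:
            raise MemoryError_(f"unknown collection '{collection}'")
        return list(self._records[collection])

    def __len__(self) -> int:
        return sum(len(v) for v in self._records.values())

    def query(
        self, text: str, collection: str, k: int,
        where: Optional[Callable[[VectorRecord], bool]] = None,
    ) -> List[Tuple[VectorRecord, float]]:
        """Top-*k* records by cosine similarity to *text*.

        Exhaustive scoring; ties broken by insertion order (stable sort).
        ``k`` larger than the collection returns the whole collection.
        """
        records = [r for r in self.records(collection) if where is None or where(r)]
        if not records:
            return []
        qvec = self.embedder.embed(text)
        matrix = np.stack([r.vector for r in records])
        norms = np.linalg.norm(matrix, axis=1) * np.linalg.norm(qvec)
        scores = matrix @ qvec / norms
        order = np.argsort(-scores, kind="stable")[:k]
        return [(records[i], float(scores[i])) for i in order]

    # -- persistence -------------------------------------------------------
    def save(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"dim": self.embedder.dim, "counter": self._counter,
                    "collections": {}}
        for collection, records in self._records.items():
            fname = collection.replace("-", "_") + ".jsonl"
            manifest["collections"][collection] = {
                "file": fname, "count": len(records)}
            with open(directory / fname, "w") as fh:
                for r in records:
                    fh.write(json.dumps({
                        "id": r.id, "text": r.text,
                        "vector": r.vector.tolist(), "metadata": r.metadata,
                    }) + "\n")
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: Union[str, Path],
             embedder: EmbeddingProvider) -> "VectorStore":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest["dim"] != embedder.dim:
            raise MemoryError_(
                f"store dim {manifest['dim']} != embedder dim {embedder.dim}")
        store = cls(embedder)
        store._counter = manifest.get("counter", 0)
        for collection, info in manifest["collections"].items():
            path = directory / info["file"]
            if not path.exists():
                continue
            for line in path.read_text().splitlines():
                if not line.strip():
                    continue
                raw = json.loads(line)
                store._records[collection].append(VectorRecord(
                    raw["id"], collection, raw["text"],
                    np.asarray(raw["vector"]), raw.get("metadata", {})))
        return store


# --------------------------------------------------------------------------
# Validated-XDL seeding


def seed_xdl_store(
    store: VectorStore,
    pairs: Sequence[Tuple[str, str]],
    registry: Optional[Dict[str, StepSchema]] = None,
) -> int:
    """Seed the validated-XDL collection with (procedure text, XDL) pairs.

    Each XDL must re-parse cleanly under the registry; pairs that do not
    are stored with a ``dialect_mismatch`` flag and excluded from
    few-shot retrieval.  Returns the number of cleanly accepted pairs.
    """
    accepted = 0
    for proc_text, xdl_text in pairs:
        try:
            _, issues = parse_xdl(xdl_text, registry)
            flagged = any(i.severity == "error" for i in issues)
        except Exception:
            flagged = True
        chash = content_hash(proc_text + "\n" + xdl_text)
        if any(r.metadata.get("content_hash") == chash
               for r in store.records("xdl-db")):
            continue  # idempotent seeding
        store.add_text("xdl-db", proc_text, {
            "xdl": xdl_text, "content_hash": chash,
            "dialect_mismatch": flagged,
        })
        if not flagged:
            accepted += 1
    return accepted


def retrievable_xdl(record: VectorRecord) -> bool:
    return not record.metadata.get("dialect_mismatch", False)


# --------------------------------------------------------------------------
# Labbook


@dataclass
class LabbookEntry:
    source_document: str
    procedure_text: str
    xdl: str
    resolved_ambiguities: List[Dict[str, str]] = field(default_factory=list)
    analytics: List[Dict[str, str]] = field(default_factory=list)
    execution_outcome: Optional[str] = None

    def entry_id(self) -> str:
        return content_hash(self.procedure_text + "\n" + self.xdl)


class Labbook:
    """Append-only directory of JSON entries, keyed by content hash.

    Writing an entry whose XDL does not re-parse cleanly is refused;
    writing the same entry twice returns the same id and leaves the book
    unchanged.
    """

    def __init__(self, directory: Union[str, Path],
                 registry: Optional[Dict[str, StepSchema]] = None):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.registry = registry
        self._index_path = self.directory / "index.json"
        if not self._index_path.exists():
            self._index_path.write_text("[]")

    @property
    def ids(self) -> List[str]:
        return json.loads(self._index_path.read_text())

    def __len__(self) -> int:
        return len(self.ids)

    def write(self, entry: LabbookEntry) -> str:
        _, issues = parse_xdl(entry.xdl, self.registry)
        if any(i.severity == "error" for i in issues):
            raise MemoryError_(
                "labbook refuses entry: XDL fails validation at write time "
                f"({len(issues)} issues)")
        eid = entry.entry_id()
        ids = self.ids
        if eid in ids:
            return eid
        (self.directory / f"{eid}.json").write_text(json.dumps({
            "id": eid,
            "source_document": entry.source_document,
            "procedure_text": entry.procedure_text,
            "xdl": entry.xdl,
            "resolved_ambiguities": entry.resolved_ambiguities,
            "analytics": entry.analytics,
            "execution_outcome": entry.execution_outcome,
        }, indent=2))
        ids.append(eid)
        self._index_path.write_text(json.dumps(ids))
        return eid

    def load_entry(self, eid: str) -> LabbookEntry:
        raw = json.loads((self.directory / f"{eid}.json").read_text())
        return LabbookEntry(
            raw["source_document"], raw["procedure_text"], raw["xdl"],
            raw.get("resolved_ambiguities", []), raw.get("analytics", []),
            raw.get("execution_outcome"))
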