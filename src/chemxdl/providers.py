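"""Provider contracts for text completion and embeddings.

Every language-model interaction in the pipeline goes through
:class:`CompletionProvider`; every embedding through
:class:`EmbeddingProvider`.  The shipped implementations are all
deterministic and offline:

* :class:`ScriptedProvider` — fixed response queues per template id, for
  unit tests and fixtures.
* :class:`RuleProvider` — first-match predicate rules over the rendered
  prompt, for end-to-end mock runs.
* :class:`ReplayProvider` / :class:`RecordingProvider` — transcripts keyed
  by a whitespace-normalized prompt hash, so a recorded session replays
  bit-identically and a cosmetic template edit invalidates the replay
  loudly (hash miss) instead of silently.
* :class:`HashEmbeddingProvider` — a seeded random projection of the
  token-count vector onto the unit sphere: identical texts embed
  identically and token overlap raises cosine similarity.  Non-semantic
  by construction, but order-preserving for overlap, which is all the
  retrieval tests need.

A live adapter can implement the same contracts behind an explicit flag;
no test path can reach a network.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

# --------------------------------------------------------------------------
# Completion contract


class ProviderError(RuntimeError):
    pass


class ReplayMissError(ProviderError):
    def __init__(self, prompt_hash: str):
        super().__init__(f"no recorded response for prompt hash {prompt_hash}")
        self.prompt_hash = prompt_hash


class SchemaError(ValueError):
    pass


Validator = Callable[[str], object]


@dataclass
class CompletionRequest:
    template_id: str
    prompt: str
    validator: Optional[Validator] = None  # raises SchemaError on bad output
    max_retries: int = 2


@dataclass
class CompletionResponse:
    text: str
    payload: Optional[object] = None
    retries_used: int = 0
    provider_name: str = ""
    ok: bool = True


def prompt_hash(prompt: str) -> str:
    """Whitespace-normalized SHA-256 of a prompt (keys replay transcripts)."""
    normalized = " ".join(prompt.split())
    return hashlib.sha256(normalized.encode()).hexdigest()


class CompletionProvider:
    """Base class: subclasses implement ``generate``; ``complete`` adds the
    bounded schema-validation retry loop shared by every agent."""

    name = "base"

    def generate(self, req: CompletionRequest, attempt: int,
                 previous_error: Optional[str]) -> str:
        raise NotImplementedError

    def complete(self, req: CompletionRequest) -> CompletionResponse:
        error: Optional[str] = None
        text = ""
        for attempt in range(req.max_retries + 1):
            text = self.generate(req, attempt, error)
            if req.validator is None:
                return CompletionResponse(text, None, attempt, self.name, True)
            try:
                payload = req.validator(text)
            except SchemaError as exc:
                error = str(exc)
                continue
            return CompletionResponse(text, payload, attempt, self.name, True)
        return CompletionResponse(text, None, req.max_retries, self.name, False)


class ScriptedProvider(CompletionProvider):
    """Pops responses from per-template queues; exhausting a queue repeats
    its last entry (convenient for never-repairing mocks)."""

    name = "scripted"

    def __init__(self, scripts: Dict[str, Sequence[str]]):
        self._queues: Dict[str, List[str]] = {
            k: list(v) for k, v in scripts.items()
        }
        self.calls: List[Tuple[str, str]] = []  # (template_id, prompt)

    def generate(self, req: CompletionRequest, attempt: int,
                 previous_error: Optional[str]) -> str:
        self.calls.append((req.template_id, req.prompt))
        queue = self._queues.get(req.template_id)
        if not queue:
            raise ProviderError(
                f"scripted provider has no responses for template "
                f"'{req.template_id}'")
        return queue.pop(0) if len(queue) > 1 else queue[0]


class RuleProvider(CompletionProvider):
    """First-match rules: (predicate(template_id, prompt), response-or-fn)."""

    name = "rule"

    def __init__(self, rules: Sequence[Tuple[Callable[[str, str], bool],
                                             Union[str, Callable[[str], str]]]]):
        self.rules = list(rules)

    def generate(self, req: CompletionRequest, attempt: int,
                 previous_error: Optional[str]) -> str:
        for predicate, response in self.rules:
            if predicate(req.template_id, req.prompt):
                return response(req.prompt) if callable(response) else response
        raise ProviderError(f"no rule matches template '{req.template_id}'")


class ReplayProvider(CompletionProvider):
    """Replays a recorded transcript; a miss is an explicit error, never a
    silent fabrication."""

    name = "replay"

    def __init__(self, transcript: Dict[str, str]):
        self.transcript = dict(transcript)

    @classmethod
    def from_jsonl(cls, path: Union[str, Path]) -> "ReplayProvider":
        transcript = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                rec = json.loads(line)
                transcript[rec["hash"]] = rec["response"]
        return cls(transcript)

    def generate(self, req: CompletionRequest, attempt: int,
                 previous_error: Optional[str]) -> str:
        key = prompt_hash(req.prompt + f"#attempt{attempt}")
        if key in self.transcript:
            return self.transcript[key]
        base = prompt_hash(req.prompt)
        if base in self.transcript:
            return self.transcript[base]
        raise ReplayMissError(base)


class RecordingProvider(CompletionProvider):
    """Wraps another provider and records its responses for later replay."""

    name = "recording"

    def __init__(self, inner: CompletionProvider):
        self.inner = inner
        self.records: List[Dict[str, str]] = []

    def generate(self, req: CompletionRequest, attempt: int,
                 previous_error: Optional[str]) -> str:
        text = self.inner.generate(req, attempt, previous_error)
        key = prompt_hash(req.prompt + f"#attempt{attempt}") if attempt else \
            prompt_hash(req.prompt)
        self.records.append(
            {"hash": key, "template_id": req.template_id, "response": text})
        return text

    def dump_jsonl(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            "".join(json.dumps(r) + "\n" for r in self.records))

    def to_replay(self) -> ReplayProvider:
        return ReplayProvider({r["hash"]: r["response"] for r in self.records})


# --------------------------------------------------------------------------
# Embedding contract

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


class EmbeddingProvider:
    dim: int

    def embed(self, text: str) -> np.ndarray:
        raise NotImplementedError


class HashEmbeddingProvider(EmbeddingProvider):
    """Deterministic mock embedding: seeded token-hash random projection.

    Each distinct token contributes a fixed pseudo-random direction
    (seeded by a stable blake2b hash of the token XOR the global seed);
    a text's vector is the count-weighted sum projected to the unit
    sphere.  Identical texts give identical vectors; texts sharing tokens
    have strictly higher expected cosine than disjoint ones.
    """

    def __init__(self, dim: int = 2048, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._token_cache: Dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._token_cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(token.encode(), digest_size=8).digest()
            token_seed = (int.from_bytes(digest, "big") ^ (self.seed & 0xFFFFFFFF)) \
                % (2**63)
            rng = np.random.default_rng(token_seed)
            vec = rng.standard_normal(self.dim)
            self._token_cache[token] = vec
        return vec

    def embed(self, text: str) -> np.ndarray:
        if not (text and text.strip()):
            raise ValueError("cannot embed empty text")
        tokens = [t.lower() for t in _TOKEN_RE.findall(text)]
        if not tokens:
            raise ValueError("cannot embed text with no tokens")
        acc = np.zeros(self.dim)
        for token in tokens:
            acc += self._token_vector(token)
        norm = float(np.linalg.norm(acc))
        if norm == 0.0:  # astronomically unlikely; perturb deterministically
            acc[0] = 1.0
            norm = 1.0
        return acc / norm


def get_completion_provider(name: str, **kwargs) -> CompletionProvider:
    if name in ("scripted", "mock"):
        return ScriptedProvider(kwargs.get("scripts", {}))
    if name == "rule":
        return RuleProvider(kwargs.get("rules", []))
    if name == "replay":
        return ReplayProvider.from_jsonl(kwargs["path"])
    if name == "live":  # pragma: no cover - requires explicit opt-in + network
        raise ProviderError(
            "live provider requires an API adapter; configure it explicitly")
    raise ProviderError(f"unknown completion provider '{name}'")


def get_embedding_provider(name: str, dim: int = 2048,
                           seed: int = 0) -> EmbeddingProvider:
    if name in ("mock", "hash"):
        return HashEmbeddingProvider(dim, seed)
    raise ProviderError(f"unknown embedding provider '{name}'")
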