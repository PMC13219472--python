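"""Workflow configuration.

Every named numeric parameter of the pipeline lives in one typed object so
that chunking, retrieval, embedding and the repair loop all read from a
single source of truth.  Configuration files are YAML; unknown keys are
rejected loudly.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class ConfigError(ValueError):
    """Raised for malformed or invalid configuration files."""


class WorkflowConfig(BaseModel):
    """Typed bundle of the workflow's numeric parameters.

    Defaults encode the published operating point of the workflow:
    documents are chunked into 4096-token fragments for extraction and
    2048-token fragments for the retrieval index, embeddings are
    2048-dimensional, five few-shot procedure/XDL pairs are retrieved per
    translation prompt, and the translate→validate→repair loop runs at
    most six iterations.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    extraction_chunk_tokens: int = Field(default=4096, gt=0)
    document_index_chunk_tokens: int = Field(default=2048, gt=0)
    embedding_dim: int = Field(default=2048, gt=0)
    few_shot_k: int = Field(default=5, gt=0)
    max_repair_iterations: int = Field(default=6, gt=0)
    random_seed: int = 0
    llm_provider_name: str = "mock"
    embedding_provider_name: str = "mock"

    @model_validator(mode="after")
    def _chunk_ordering(self) -> "WorkflowConfig":
        # The retrieval index uses finer chunks than extraction; a coarser
        # index than the extraction window is almost certainly a typo.
        if self.document_index_chunk_tokens > self.extraction_chunk_tokens:
            raise ValueError(
                "document_index_chunk_tokens must not exceed extraction_chunk_tokens"
            )
        return self


def load_config(path: Optional[Union[str, Path]] = None) -> WorkflowConfig:
    """Load a :class:`WorkflowConfig` from a YAML file.

    With ``path=None`` (or a missing optional path) the defaults are
    returned.  Explicit keys override defaults; unknown or invalid keys
    raise :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return WorkflowConfig()
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if raw is None:
        return WorkflowConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    try:
        return WorkflowConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config key '{key}': {first['msg']}") from exc


def save_config(cfg: WorkflowConfig, path: Union[str, Path]) -> None:
    """Write *cfg* to *path* as YAML; ``load_config`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))


class CharTokenizer:
    """Approximate tokenizer: one token per four characters, rounded up.

    The workflow's token budgets only need to be internally consistent,
    not vendor-exact, so no external tokenizer dependency is required.
    All chunking and indexing arithmetic in the package goes through this
    contract; swapping in a vendor tokenizer only requires implementing
    ``count`` and ``chars_for_tokens``.
    """

    chars_per_token = 4

    def count(self, text: str) -> int:
        return math.ceil(len(text) / self.chars_per_token)

    def chars_for_tokens(self, tokens: int) -> int:
        return tokens * self.chars_per_token


DEFAULT_TOKENIZER = CharTokenizer()
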