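"""Language-roadmap generation from non-executable steps.

Procedure operations that the current step vocabulary cannot express are
harvested from critique reports, embedded, clustered (average-linkage
agglomerative clustering on cosine distance), categorized by the kind of
change needed to support them (a new step attribute, a new step, or a new
step plus hardware), and ranked into a roadmap: easier modification
classes first, larger (more frequently requested) clusters first within a
class.  Urgency-as-cluster-size and the fixed ease order are this
package's operationalization of a qualitative ranking; see
``docs/methods.md``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .providers import (CompletionProvider, CompletionRequest,
                        EmbeddingProvider, SchemaError)

MODIFICATION_TYPES = ("new-attribute", "new-step", "new-step-and-hardware")
_EASE_ORDER = {t: i for i, t in enumerate(MODIFICATION_TYPES)}


@dataclass
class NonExecutableStep:
    text: str
    source: str = ""  # procedure id + span
    vector: Optional[np.ndarray] = None


@dataclass
class StepSuggestion:
    name: str
    modification_type: str
    members: List[NonExecutableStep] = field(default_factory=list)
    urgency_rank: int = 0  # 1 = most urgent (largest cluster)
    ease_rank: int = 0  # 1 = easiest modification class


def embed_steps(steps: Sequence[NonExecutableStep],
                embedder: EmbeddingProvider) -> None:
    for step in steps:
        if step.vector is None:
            step.vector = embedder.embed(step.text)


def cluster_steps(
    steps: Sequence[NonExecutableStep],
    threshold: float = 0.6,
    embedder: Optional[EmbeddingProvider] = None,
) -> List[List[NonExecutableStep]]:
    """Partition steps by average-linkage agglomerative clustering at the
    given cosine-distance threshold.

    Deterministic: input order is canonicalized by (text, source) before
    clustering, and every step lands in exactly one cluster.  Threshold 0
    separates everything except exact-duplicate embeddings.
    """
    if not steps:
        raise ValueError("cluster_steps requires at least one step")
    ordered = sorted(steps, key=lambda s: (s.text, s.source))
    if embedder is not None:
        embed_steps(ordered, embedder)
    if any(s.vector is None for s in ordered):
        raise ValueError("steps must carry embedding vectors (pass embedder)")
    if len(ordered) == 1:
        return [list(ordered)]
    matrix = np.stack([s.vector for s in ordered])
    links = linkage(matrix, method="average", metric="cosine")
    labels = fcluster(links, t=threshold, criterion="distance")
    clusters: Dict[int, List[NonExecutableStep]] = {}
    for label, step in zip(labels, ordered):
        clusters.setdefault(int(label), []).append(step)
    # canonical cluster order: by size descending, then first member text
    return sorted(clusters.values(), key=lambda c: (-len(c), c[0].text))


CATEGORIZE_PROMPT = """A set of chemistry procedure operations could not be \
expressed in the current synthesis description language. Decide what kind of \
language modification would support them: 'new-attribute' (an existing step \
needs a new attribute, e.g. a heating ramp rate), 'new-step' (a new step type \
with existing hardware), or 'new-step-and-hardware' (a new step requiring new \
hardware support, e.g. inline TLC analysis). Answer with exactly one of the \
three labels.

OPERATIONS:
{ops}
"""


def _validate_modification(text: str) -> str:
    label = text.strip().lower().strip(".\"'")
    if label not in MODIFICATION_TYPES:
        raise SchemaError(f"'{label}' is not one of {MODIFICATION_TYPES}")
    return label


def categorize_cluster(
    cluster: Sequence[NonExecutableStep], llm: CompletionProvider,
    max_retries: int = 2,
) -> StepSuggestion:
    """Name a cluster and assign its modification type via the provider;
    out-of-vocabulary answers are re-asked, then default to ``new-step``."""
    ops = "\n".join(f"- {s.text}" for s in cluster)
    response = llm.complete(CompletionRequest(
        "categorize", CATEGORIZE_PROMPT.format(ops=ops),
        _validate_modification, max_retries))
    mod_type = (str(response.payload)
                if response.ok and response.payload else "new-step")
    # name from the most common leading words of the member texts
    words = Counter(" ".join(s.text.lower().split()[:3]) for s in cluster)
    name = words.most_common(1)[0][0]
    return StepSuggestion(name, mod_type, list(cluster))


def rank_suggestions(suggestions: Sequence[StepSuggestion]) -> List[StepSuggestion]:
    """Order suggestions into the roadmap.

    Ease class ascending (new-attribute < new-step < new-step-and-hardware),
    then urgency: bigger clusters (more frequent requests) first.  Stable
    and deterministic under input permutation.
    """
    ordered = sorted(
        suggestions,
        key=lambda s: (_EASE_ORDER[s.modification_type], -len(s.members),
                       s.name))
    by_size = sorted(ordered, key=lambda s: -len(s.members))
    urgency = {id(s): i + 1 for i, s in enumerate(by_size)}
    for s in ordered:
        s.urgency_rank = urgency[id(s)]
        s.ease_rank = _EASE_ORDER[s.modification_type] + 1
    return ordered


def roadmap_report(suggestions: Sequence[StepSuggestion]) -> str:
    """Human-readable roadmap grouped by modification type."""
    lines = []
    for mod_type in MODIFICATION_TYPES:
        group = [s for s in suggestions if s.modification_type == mod_type]
        if not group:
            continue
        lines.append(f"## {mod_type}")
        for s in group:
            lines.append(f"- {s.name} ({len(s.members)} requests, "
                         f"urgency rank {s.urgency_rank})")
    return "\n".join(lines)


def keyword_frequencies(texts: Sequence[str],
                        keywords: Sequence[str]) -> Dict[str, int]:
    """Occurrence counts of keywords over a local procedure corpus."""
    counts = {k: 0 for k in keywords}
    for text in texts:
        lowered = text.lower()
        for k in keywords:
            counts[k] += lowered.count(k.lower())
    return counts
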