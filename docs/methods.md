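# Methods

This note documents the models, defaults and design decisions behind
`chemxdl`, and what the test suite does and does not establish.

## Workflow parameters

All named numeric parameters live in `chemxdl.config.WorkflowConfig`:

| parameter | default | meaning |
|---|---|---|
| `extraction_chunk_tokens` | 4096 | window for per-chunk KG extraction |
| `document_index_chunk_tokens` | 2048 | window for the retrieval index |
| `embedding_dim` | 2048 | embedding vector length |
| `few_shot_k` | 5 | validated procedure/XDL pairs per translation prompt |
| `max_repair_iterations` | 6 | hard stop for the translate→validate→repair loop |
| `random_seed` | 0 | single seed governing every stochastic component |

These defaults are the workflow's stated operating point, not tuning
knobs; the config file (YAML) may override them, and unknown keys are
rejected.

Token counting is a pluggable contract whose default approximates one
token per four characters (rounded up). Counts are therefore internally
consistent rather than vendor-exact; no vendor tokenizer is required and
none is bundled.

## The XDL dialect

XDL documents are XML with root `<Synthesis>` and children `<Hardware>`
(`<Component id type>`), `<Reagents>` (`<Reagent id name role
iupac_name molar_mass boiling_point>`), optional `<Metadata>`, and
`<Procedure>`. The step vocabulary is a data-driven registry of 16
defaults — Add, Transfer, HeatChill, HeatChillToTemp, Stir, StartStir,
StopStir, Wait, Evaporate, Filter, WashSolid, Dry, Separate, Dissolve,
Precipitate, Repeat — chosen to cover the operations appearing in
ordinary batch-synthesis narratives. Platforms with a restricted
instruction set pass a sub-registry; validation, prompting and
simulation all honor it. This is explicitly a *dialect*: the attribute
inventory of production XDL parsers is not public, so byte-compatibility
is a non-goal.

Seven quantity dimensions are supported (volume, mass, amount,
temperature, time, pressure, rotation-rate), each with a closed table of
accepted spellings and exact factors to a base unit (mL, g, mol, °C, s,
mbar, rpm). Temperature is Celsius-only by design: Kelvin input is
reported as a unit issue rather than auto-converted, because a silent
conversion bug is precisely the class of error the validator exists to
surface. Base-unit round-trips are exact to 1e-9 relative.

### Parsing philosophy

The parser is total over content: a single pass reports *all* detectable
issues (five categories: syntax, unit, missing-hardware, missing-reagent,
schema), each with an element path and — when parsed from source — a line
number, so one repair iteration receives complete feedback. Only
XML well-formedness failures truncate the analysis (the underlying
stream parser cannot recover), and only an empty input raises. Duplicate
ids keep the first declaration and flag the duplicate, keeping parsing
total.

## Hardware graphs and vessel mapping

Hardware graphs are JSON (`nodes`/`edges`) with nine node classes; the
capability bundle (temperature range, stir-rate range, max volume,
filter/separate/evaporate flags) is inferred from the constraint types a
simulation must check — the authors' own capability vocabulary is not
published. Transfers are legal only along paths whose interior nodes are
pumps or valves (the syringe-pump backbone architecture); multi-leg
transfers via buffer flasks are out of scope.

Vessel requirements are derived purely from the document: min/max of
requested temperatures and stir rates per vessel, the peak volume from
the volume ledger, and capability flags from step semantics
(Filter/WashSolid/Dry ⇒ filtration; Separate's source ⇒ phase
separation; Evaporate ⇒ evaporation). Mapping is a backtracking search
over vessels ordered most-constrained-first with lexicographic
tie-breaks — instances are tiny (≤ 6 candidate nodes), so the search is
exact, and the tests verify its feasibility decision against brute-force
enumeration of all injective assignments.

## Simulation

The simulator validates *executability*, not chemistry: no reactions,
kinetics, densities or pressures. Mass-only additions are tracked as
zero-volume solids (no 1 g/mL equivalence is applied). Volumes follow an
exact ledger; "all"-transfers empty the source; over-draws move what is
present and record `INSUFFICIENT_VOLUME`; after `OVERFLOW` the vessel is
clamped at capacity so later steps remain checkable. The simulator
collects *all* constraint violations rather than halting at the first —
consistent with the parallel-error philosophy of the parser; whether a
production simulation would halt earlier is unknown, and this choice is
a documented divergence risk. Model time advances only by explicit step
durations; the conventional approximation for "dropwise" transfers is a
10-minute timed transfer (`DEFAULT_DROPWISE_DURATION_S`).

An independent scalar volume ledger (`volume_ledger`) replays the same
sequence with pure arithmetic and no graph or state machinery; the test
suite requires exact agreement between the two implementations, and uses
the ledger's peak volumes for requirement derivation.

## Memory and retrieval

Three vector collections (validated-XDL store, chemical ambiguity
database, document index) use exhaustive cosine scoring — store sizes at
desk scale are ≤ 10⁴ records, and exactness makes retrieval testable
against a brute-force oracle. Persistence is JSON-lines plus a manifest;
the labbook is an append-only directory of JSON entries keyed by content
hash, so repeated writes are idempotent and entries are diffable.

The mock embedding is a seeded random projection of the token-count
vector onto the unit sphere: identical texts embed identically, and
token overlap raises expected cosine. It is deliberately *non-semantic*;
a green retrieval test establishes ranking correctness and determinism,
not semantic quality. The live embedding adapter implements the same
contract behind an explicit opt-in; the 2048-dimension default is a
configuration value, not a requirement of any provider.

## Agents and the repair loop

All four agent roles (scraping, procedure, translation, critique) are
prompt templates (versioned text files under `chemxdl/data/prompts/`)
over a completion-provider contract with a shared bounded
schema-validation retry loop. Replay transcripts are keyed by a
whitespace-normalized prompt hash: a cosmetic template edit invalidates a
replay loudly instead of silently.

Loop accounting: one iteration = one generation attempt (the initial
translation counts as iteration 1), hard stop after 6. Stage gating is
sequential — critique only after validity passes, simulation only when
the critique reports no missing/disordered steps. Extraneous steps warn;
non-executable steps do not block (approximations like dropwise → timed
transfer proceed) and are harvested for the roadmap. Each iteration
re-runs all stages from the top; whether an incremental re-check would
match production behavior is unknown. Classification fails safe to
`incomplete`, never `executable`. Every sanitization edit is a span diff
over the original text with a reason; the provider's edit log must
reconstruct the sanitized text exactly or the output is rejected — this
invented representation is the audit surface for language-model edits.

## Roadmap generation

Non-executable steps are clustered by average-linkage agglomerative
clustering on cosine distance (default threshold 0.6); the algorithm
choice is this package's — the source workflow says only that steps are
clustered. Urgency = cluster size (a frequency proxy) and ease = the
fixed order new-attribute < new-step < new-step-and-hardware are invented
operationalizations of a qualitative ranking; the roadmap sort is stable
and deterministic under input permutation.

## Synthetic data

The fixture generators (`chemxdl.synth`) emulate the three input kinds —
procedure texts with controlled ambiguities, XDL documents with
manifest-tracked seeded errors (k ≤ 5, one per category, each targeting
a distinct element), and small hardware graphs — because the benchmark
corpora (publication sets, a thesis, a German practical script,
proprietary reaction databases) cannot be packaged. The shipped
ambiguity seed and chemical-information cache are synthetic stand-ins,
clearly non-canonical. Scripted agent responses drive the end-to-end
run; a green end-to-end test therefore establishes the correctness of
the *machinery* (gating, persistence, idempotence, replayability), not
the translation quality of any particular language model — the headline
success rates of a live frontier model on real corpora are out of scope
by construction.

## Known limitations

- No PDF layout parsing or figure/table OCR; inputs are plain text.
- Entity merging is string-normalized (no structure-aware resolution via
  InChI or similar), so unrelated chemicals sharing a name string would
  merge.
- The simulator's work-up semantics are coarse (Filter/Evaporate empty
  the vessel's liquid; Separate moves everything), adequate for
  executability checking but not for yield reasoning.
- Buffer-flask multi-leg transfers and pH control are unsupported; both
  surface as roadmap candidates rather than silent failures.
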