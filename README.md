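# chemxdl

**From literature chemistry procedures to validated, executable XDL.**

Published synthesis procedures are written for human chemists: units are
sloppy, steps are implied, "general procedure A" is referenced but not
restated, and manipulations like *"the flask was lifted halfway from the
oil bath"* have no direct robotic equivalent. `chemxdl` is a pipeline for
digitizing such procedures into XDL — an XML chemical description
language of declared reagents, abstract vessels and ordered steps — and
*validating* the result well enough that it could be handed to a robotic
synthesis platform.

It is aimed at lab-automation and literature-mining groups who want the
full agentic workflow (extraction → sanitization → translation →
validation) as an offline-testable library: every language-model and
embedding call goes through a provider contract with deterministic
scripted/replay/mock implementations, so the whole pipeline runs and
tests without a network.

## The core loop

A draft XDL document `x` for procedure text `p` must pass three gates:

1. **Validity** — a single-pass exhaustive parser reports *all* issues at
   once (malformed structure, unknown steps, missing required
   attributes, wrong-dimension units such as Kelvin, unresolved vessel or
   reagent references), each with a source location.
2. **Discrepancy** — an LLM-as-a-judge critique compares `p` and `x` for
   missing, disordered, extraneous and non-executable steps. Missing or
   disordered steps block; non-executable steps are harvested for the
   language roadmap.
3. **Simulation** — abstract vessels are mapped onto a hardware graph
   (capability-annotated nodes, tubing edges) by a most-constrained-first
   backtracking search, and the procedure is executed in a stateful
   simulation that checks temperature and stir-rate envelopes, vessel
   capacities, transfer reachability through the pump/valve backbone, and
   an exact volume ledger.

Failures at any gate become structured feedback for the next drafting
iteration:

```
x_{i+1} = refine(x_i, feedback_i, context),   i = 1 .. 6
```

where the context carries the k = 5 most similar previously *validated*
procedure/XDL pairs retrieved by cosine similarity from a vector store
(retrieval-augmented few-shot prompting), ambiguity notes from a chemical
ambiguity database, and snippets of the source document indexed in
2048-token chunks. A fully clean pass stores the pair back into the
vector store and writes a content-hash-keyed labbook entry.

## Worked example

```python
from chemxdl import VectorStore, run_pipeline
from chemxdl.providers import HashEmbeddingProvider, ScriptedProvider
from chemxdl.extraction import extract_document
from chemxdl.sanitization import sanitize_procedure, seed_cad
from chemxdl.synth import e2e_scripts, fixture_paper_text, standard_graph
from chemxdl.memory import Labbook

llm = ScriptedProvider(e2e_scripts())          # offline scripted agents
store = VectorStore(HashEmbeddingProvider(2048, seed=0))
seed_cad(store)                                # ambiguity database

kg = extract_document(fixture_paper_text(), llm, store=store)
print(f"extracted {len(kg.entities)} entities, {len(kg.procedures)} procedures")

sanitized = [sanitize_procedure(p, llm, store) for p in kg.procedures]
print("categories:", [s.category for s in sanitized])
proc = next(s for s in sanitized if s.category == "executable")
print("edit:", proc.edits[0].before, "->", proc.edits[0].after)

book = Labbook("scratch/labbook")
result = run_pipeline(proc, standard_graph(), llm, store=store, labbook=book)
print(f"translation: {result.status} after {result.iterations_used} iteration(s)")
```

prints

```
extracted 6 entities, 2 procedures
categories: ['blueprint', 'executable']
edit: extracted 30 times with 20 ml -> extracted 3 times with 20 ml
translation: valid after 1 iteration(s)
```

The fixture document contains a general-method paragraph (classified
`blueprint`, not translatable as-is) and a complete amination procedure
(classified `executable`). Sanitization catches a reporting error — an
implausible "extracted 30 times" — and logs the correction as a
reconstructible span edit. Translation then passes all three validation
gates on the first iteration, and the validated XDL lands in the labbook
together with the resolved ambiguities and the analytical data carried
over from the source document.

A thin CLI wraps the same library calls:

```bash
chemxdl validate procedure.xdl          # exhaustive issue listing
chemxdl map procedure.xdl graph.json    # vessel → node assignment
chemxdl simulate procedure.xdl graph.json
chemxdl extract paper.txt --out kg.json --scripts agents.json
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computations from scratch on generated inputs:
seeded-error parsing against the seed manifests, serialization
round-trips, vessel mapping against brute-force enumeration of injective
assignments, simulation against an independent scalar volume ledger, the
scripted end-to-end pipeline run, and roadmap clustering. It prints a
summary of each stage and writes the results JSON to `--out`.

## Scope notes

The step vocabulary (16 default steps) is a documented dialect, not a
byte-compatible clone of any proprietary XDL schema, and the live
LLM/embedding adapters are opt-in stubs: the published headline success
rates of this kind of workflow require a frontier model and benchmark
corpora that cannot be packaged, so the test suite asserts the
*properties* of the machinery instead. See `docs/methods.md` for the
model assumptions, parameter defaults and known limitations.
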