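import json

import pytest

from chemxdl.config import WorkflowConfig
from chemxdl.memory import Labbook, cosine, seed_xdl_store
from chemxdl.providers import ScriptedProvider
from chemxdl.sanitization import SanitizedProcedure
from chemxdl.synth import (FIXTURE_PROCEDURE, FIXTURE_XDL, e2e_scripts,
                           fixture_critique_response, standard_graph)
from chemxdl.translation import (FeedbackItem, build_context, critique,
                                 extract_xdl_block, refine,
                                 render_translate_prompt, run_pipeline,
                                 translate)
from chemxdl.xdl_core import DEFAULT_REGISTRY, parse_xdl


def _proc(text=FIXTURE_PROCEDURE, category="executable"):
    return SanitizedProcedure(text, text, category, procedure_id="p1")


CLEAN_CRITIQUE = json.dumps({"missing_steps": [], "disordered_steps": [],
                             "extraneous_steps": [],
                             "non_executable_steps": []})


def _fenced(xdl):
    return f"thinking...\n```xml\n{xdl}```\n"


# -- context assembly -------------------------------------------------------

def test_empty_store_gives_no_few_shot(store):
    ctx = build_context(_proc(), store)
    assert ctx.few_shot == []


def test_exactly_k_pairs_match_bruteforce(store, embedder):
    pairs = [(f"procedure about {topic} chemistry step {i}", FIXTURE_XDL)
             for i, topic in enumerate(["amide", "ester", "ether", "amine",
                                        "ketone", "aldehyde", "acid"])]
    seed_xdl_store(store, pairs)
    proc = _proc("a procedure about amine chemistry")
    ctx = build_context(proc, store, k=5)
    assert len(ctx.few_shot) == 5
    qvec = embedder.embed(proc.sanitized_text)
    records = store.records("xdl-db")
    brute = sorted(range(len(records)),
                   key=lambda i: (-cosine(qvec, records[i].vector), i))[:5]
    assert [p for p, _ in ctx.few_shot] == [records[i].text for i in brute]


def test_restricted_registry_carried_and_documented(store):
    limited = {k: v for k, v in DEFAULT_REGISTRY.items()
               if k in ("Add", "Transfer", "Stir", "Wait", "HeatChill",
                        "Dissolve", "Evaporate", "Repeat")}
    ctx = build_context(_proc(), store, registry=limited)
    assert set(ctx.registry) == set(limited)
    prompt = render_translate_prompt(ctx)
    assert "Separate" not in prompt
    assert "- Add(" in prompt


def test_ablation_no_xdl_db(store):
    seed_xdl_store(store, [("some procedure", FIXTURE_XDL)])
    ctx = build_context(_proc(), store, no_xdl_db=True)
    assert ctx.few_shot == []


def test_prompt_contains_few_shot_pairs_verbatim(store):
    seed_xdl_store(store, [("pair one text", FIXTURE_XDL),
                           ("pair two text", FIXTURE_XDL)])
    ctx = build_context(_proc(), store)
    prompt = render_translate_prompt(ctx)
    assert "pair one text" in prompt and "pair two text" in prompt
    assert ctx.procedure.sanitized_text in prompt


# -- block extraction -------------------------------------------------------

def test_fenced_block_extraction():
    assert extract_xdl_block(_fenced("<Synthesis />\n")) == "<Synthesis />\n"
    assert extract_xdl_block("no block here at all") is None


def test_translate_passthrough():
    llm = ScriptedProvider({"translate": [_fenced(FIXTURE_XDL)]})
    ctx = build_context(_proc(), None)
    text = translate(ctx, llm)
    assert extract_xdl_block(text) is not None


# -- critique ---------------------------------------------------------------

def test_critique_missing_step_passthrough():
    payload = json.dumps({
        "missing_steps": [{"span": "washed with brine",
                           "description": "wash step absent from XDL"}],
        "disordered_steps": [], "extraneous_steps": [],
        "non_executable_steps": []})
    llm = ScriptedProvider({"critique": [payload]})
    report = critique(_proc(), FIXTURE_XDL, llm)
    assert report.missing_steps == [("washed with brine",
                                     "wash step absent from XDL")]
    assert report.blocking


def test_critique_non_executable_does_not_block():
    llm = ScriptedProvider({"critique": [fixture_critique_response()]})
    report = critique(_proc(), FIXTURE_XDL, llm)
    assert report.non_executable_steps
    assert not report.blocking


def test_critique_schema_failure_degrades_to_low_confidence():
    llm = ScriptedProvider({"critique": ["not json"]})
    report = critique(_proc(), FIXTURE_XDL, llm, max_retries=1)
    assert report.low_confidence and report.empty


# -- refine -----------------------------------------------------------------

def test_refine_requires_feedback():
    llm = ScriptedProvider({"refine": ["x"]})
    ctx = build_context(_proc(), None)
    with pytest.raises(ValueError):
        refine("draft", [], ctx, llm)


def test_refine_prompt_carries_error_locations():
    broken = FIXTURE_XDL.replace('temp="100 °C"', 'temp="300 K"')
    _, issues = parse_xdl(broken)
    captured = {}

    class Spy(ScriptedProvider):
        def generate(self, req, attempt, previous_error):
            captured["prompt"] = req.prompt
            return super().generate(req, attempt, previous_error)

    llm = Spy({"refine": [_fenced(FIXTURE_XDL)]})
    ctx = build_context(_proc(), None)
    refine(broken, [FeedbackItem("validity", issues)], ctx, llm)
    assert "BAD_UNIT" in captured["prompt"]
    assert "HeatChill" in captured["prompt"]


# -- the pipeline -----------------------------------------------------------

def test_clean_first_turn_is_valid_at_iteration_one(store, tmp_path):
    llm = ScriptedProvider(e2e_scripts())
    book = Labbook(tmp_path / "book")
    result = run_pipeline(_proc(), standard_graph(), llm, store=store,
                          labbook=book)
    assert result.status == "valid"
    assert result.iterations_used == 1
    assert len(result.trace) == 1
    assert result.labbook_id is not None and len(book) == 1
    # stored artifact independently re-passes validity
    _, issues = parse_xdl(result.final_xdl)
    assert issues == []


def test_fix_on_turn_two(store):
    broken = FIXTURE_XDL.replace('temp="100 °C"', 'temp="300 K"')
    llm = ScriptedProvider({
        "translate": [_fenced(broken)],
        "refine": [_fenced(FIXTURE_XDL)],
        "critique": [CLEAN_CRITIQUE],
    })
    result = run_pipeline(_proc(), standard_graph(), llm, store=store)
    assert result.status == "valid"
    assert result.iterations_used == 2
    assert len(result.trace) == 2
    assert result.trace[0].feedback[0].stage == "validity"


def test_never_repairing_mock_stops_at_six(store):
    broken = FIXTURE_XDL.replace('temp="100 °C"', 'temp="300 K"')
    llm = ScriptedProvider({"translate": [_fenced(broken)],
                            "refine": [_fenced(broken)]})
    result = run_pipeline(_proc(), standard_graph(), llm, store=store)
    assert result.status == "failed_validity"
    assert result.iterations_used == 6
    assert len(result.trace) == 6


def test_blocking_discrepancy_fails_that_stage(store):
    blocking = json.dumps({
        "missing_steps": [{"span": "wash", "description": "missing"}],
        "disordered_steps": [], "extraneous_steps": [],
        "non_executable_steps": []})
    llm = ScriptedProvider({"translate": [_fenced(FIXTURE_XDL)],
                            "refine": [_fenced(FIXTURE_XDL)],
                            "critique": [blocking]})
    result = run_pipeline(_proc(), standard_graph(), llm, store=store)
    assert result.status == "failed_discrepancy"
    assert result.iterations_used == 6


def test_simulation_failure_fed_back(store):
    hot = FIXTURE_XDL.replace('temp="100 °C"', 'temp="179 °C"') \
                     .replace('temp="50 °C"', 'temp="200 °C"')
    llm = ScriptedProvider({"translate": [_fenced(hot)],
                            "refine": [_fenced(hot)],
                            "critique": [CLEAN_CRITIQUE]})
    result = run_pipeline(_proc(), standard_graph(), llm, store=store,
                          cfg=WorkflowConfig(max_repair_iterations=2))
    assert result.status == "failed_simulation"
    assert result.iterations_used == 2


def test_no_xdl_block_is_a_validity_failure(store):
    llm = ScriptedProvider({"translate": ["just prose, no code block"],
                            "refine": ["still no block"]})
    result = run_pipeline(_proc(), standard_graph(), llm, store=store,
                          cfg=WorkflowConfig(max_repair_iterations=2))
    assert result.status == "failed_validity"
    assert result.trace[0].feedback[0].payload[0].code == "NO_XDL_BLOCK"


def test_incomplete_procedure_rejected_upstream(store):
    llm = ScriptedProvider({})
    with pytest.raises(ValueError):
        run_pipeline(_proc(category="incomplete"), standard_graph(), llm,
                     store=store)


def test_valid_result_stored_once_and_rerun_idempotent(store, tmp_path):
    llm = ScriptedProvider(e2e_scripts())
    book = Labbook(tmp_path / "book")
    first = run_pipeline(_proc(), standard_graph(), llm, store=store,
                         labbook=book)
    xdl_records = len(store.records("xdl-db"))
    second = run_pipeline(_proc(), standard_graph(), llm, store=store,
                          labbook=book)
    assert second.status == "valid"
    assert second.labbook_id == first.labbook_id
    assert len(book) == 1
    assert len(store.records("xdl-db")) == xdl_records
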