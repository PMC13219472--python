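import json

import pytest

from chemxdl.extraction import ProcedureRecord
from chemxdl.memory import cosine
from chemxdl.providers import ScriptedProvider
from chemxdl.sanitization import (CachedChemicalAdapter, Edit,
                                  ScriptedExpertChannel, SilentExpertChannel,
                                  SolventDB, apply_edits, ask_expert,
                                  classify_procedure, detect_chemicals,
                                  enrich_chemicals, retrieve_ambiguities,
                                  sanitize, seed_cad)
from chemxdl.synth import (FIXTURE_GENERAL, FIXTURE_PROCEDURE,
                           fixture_sanitize_response)


def _proc(text=FIXTURE_PROCEDURE, pid="p1"):
    return ProcedureRecord(pid, text)


# -- classification ---------------------------------------------------------

def test_classification_passthrough_and_blueprint():
    llm = ScriptedProvider({"classify": ["executable"]})
    assert classify_procedure(_proc(), llm) == "executable"
    llm = ScriptedProvider({"classify": ["blueprint"]})
    assert classify_procedure(_proc(FIXTURE_GENERAL), llm) == "blueprint"


def test_out_of_vocabulary_fails_safe_to_incomplete():
    llm = ScriptedProvider({"classify": ["runnable", "doable", "excellent"]})
    assert classify_procedure(_proc(), llm) == "incomplete"


def test_classification_retry_recovers():
    llm = ScriptedProvider({"classify": ["sort of fine?", "executable"]})
    assert classify_procedure(_proc(), llm) == "executable"


# -- enrichment -------------------------------------------------------------

def test_solvent_table_consulted_before_adapter():
    infos = enrich_chemicals(_proc("dissolve the solid in methanol"))
    (methanol,) = [c for c in infos if c.query == "methanol"]
    assert methanol.source == "solvent-db"
    assert methanol.boiling_point == pytest.approx(64.7)


def test_cached_adapter_resolves_abbreviation():
    infos = enrich_chemicals(_proc("washed with DCM and dried"))
    (dcm,) = [c for c in infos if c.query.lower() == "dcm"]
    # DCM is in the solvent alias table, so solvent-db wins (cache-first order)
    assert dcm.source in ("solvent-db", "pubchem-adapter")
    assert dcm.iupac_name == "dichloromethane"


def test_adapter_lookup_carries_molar_mass():
    adapter = CachedChemicalAdapter()
    info = adapter.lookup("sodium hydroxide")
    assert info.molar_mass == pytest.approx(40.0)
    assert info.source == "pubchem-adapter"


def test_unresolved_chemical_flagged_never_dropped():
    infos = enrich_chemicals(
        _proc("add unobtainium chloride to the water"),
        extra_names=["unobtainium chloride"])
    (unknown,) = [c for c in infos if c.query == "unobtainium chloride"]
    assert unknown.source == "unresolved"
    assert unknown.reason


def test_detect_chemicals_word_boundaries():
    names = detect_chemicals("add ethanol, not methanol", ["ethanol",
                                                           "methanol", "than"])
    assert set(names) == {"ethanol", "methanol"}


# -- ambiguity retrieval ----------------------------------------------------

def test_empty_cad_returns_nothing(store):
    assert retrieve_ambiguities(_proc(), store, 5) == []


def test_seeded_fragment_retrieved_at_rank_one(store):
    seed_cad(store)
    proc = _proc("The flask was lifted halfway from the oil bath. "
                 "Stirring continued overnight.")
    entries = retrieve_ambiguities(proc, store, 3)
    assert entries[0].fragment == "the flask was lifted halfway from the oil bath"
    assert "set temperature" in entries[0].explanation.lower() or \
        "temperature" in entries[0].explanation.lower()


def test_topk_matches_bruteforce_ranking(store, embedder):
    seed_cad(store)
    proc = _proc("extracted with ethyl acetate and washed with brine")
    entries = retrieve_ambiguities(proc, store, 2)
    assert len(entries) == 2
    # brute-force oracle: best cosine over sentences per record
    qvec = embedder.embed(proc.text)
    scored = sorted(
        ((cosine(qvec, r.vector), r.id) for r in store.records("cad")),
        reverse=True)
    assert entries[0].record_id == scored[0][1]


# -- expert channel ---------------------------------------------------------

def test_ask_expert_persists_and_dedups(store):
    channel = ScriptedExpertChannel({"what does reflux mean": "boil with "
                                     "condenser return"})
    first = ask_expert("heat to reflux", "what does reflux mean",
                       channel, store)
    assert first is not None
    size = len(store.records("cad"))
    again = ask_expert("heat to reflux", "what does reflux mean",
                       SilentExpertChannel(), store)
    assert again is not None and again.record_id == first.record_id
    assert len(store.records("cad")) == size


def test_silent_channel_leaves_question_pending(store):
    assert ask_expert("frag", "unanswerable?", SilentExpertChannel(),
                      store) is None


# -- sanitize ---------------------------------------------------------------

def test_sanitize_edit_log_reconstructs_text():
    llm = ScriptedProvider({"sanitize": [fixture_sanitize_response()]})
    result = sanitize(_proc(), llm, category="executable")
    assert "extracted 3 times" in result.sanitized_text
    assert apply_edits(result.original_text, result.edits) == \
        result.sanitized_text
    assert result.edits[0].reason


def test_sanitize_rejects_inconsistent_edit_log_then_falls_back():
    bad = json.dumps({"sanitized_text": "something else entirely",
                      "edits": [], "open_questions": []})
    llm = ScriptedProvider({"sanitize": [bad]})
    result = sanitize(_proc(), llm, category="executable", max_retries=1)
    assert result.sanitization_failed
    assert result.sanitized_text == result.original_text


def test_identity_sanitization_empty_edit_log():
    identity = json.dumps({"sanitized_text": FIXTURE_PROCEDURE, "edits": [],
                           "open_questions": []})
    llm = ScriptedProvider({"sanitize": [identity]})
    result = sanitize(_proc(), llm, category="executable")
    assert result.sanitized_text == FIXTURE_PROCEDURE
    assert result.edits == []


def test_apply_edits_validates_spans():
    with pytest.raises(ValueError):
        apply_edits("abcdef", [Edit(0, 3, "xyz", "q", "bad span")])
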