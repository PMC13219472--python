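import json

import pytest
from hypothesis import given, settings, strategies as st

from chemxdl.config import DEFAULT_TOKENIZER
from chemxdl.extraction import (ChemicalEntity, DocumentKG, DocumentChunk,
                                ProcedureRecord, chunk_text, extract_chunk,
                                index_document, merge_kgs, score_extraction)
from chemxdl.providers import ScriptedProvider
from chemxdl.synth import fixture_extraction_response, fixture_paper_text


# -- chunking ---------------------------------------------------------------

def test_empty_text_gives_no_chunks():
    assert chunk_text("", 100) == []


def test_exactly_limit_tokens_is_one_chunk():
    text = "a" * 400  # 100 tokens under the 4-chars/token default
    chunks = chunk_text(text, 100)
    assert len(chunks) == 1
    assert chunks[0].token_span == (0, 100)


@settings(max_examples=60, derandomize=True)
@given(st.text(min_size=0, max_size=3000), st.integers(min_value=1, max_value=64))
def test_chunking_lossless_and_bounded(text, limit):
    chunks = chunk_text(text, limit)
    assert "".join(c.text for c in chunks) == text
    assert all(DEFAULT_TOKENIZER.count(c.text) <= limit for c in chunks)
    assert [c.index for c in chunks] == list(range(len(chunks)))


def test_chunk_count_matches_token_arithmetic():
    # no paragraph breaks → hard cuts → exactly ceil(total/limit) chunks
    text = "x" * 4096 * 3  # 3072 tokens
    assert len(chunk_text(text, 1024)) == 3
    assert len(chunk_text(text, 1000)) == 4  # ceil(3072/1000)


def test_paragraph_break_preferred_near_window_end():
    # paragraph break at 97% of the window is taken instead of a hard cut
    limit = 100
    text = "a" * 388 + "\n\n" + "b" * 600
    chunks = chunk_text(text, limit)
    assert chunks[0].text.endswith("\n\n")


# -- per-chunk extraction ---------------------------------------------------

def _chunk(text="some chemistry text"):
    return DocumentChunk(0, text, (0, 5))


def test_extract_chunk_passthrough():
    llm = ScriptedProvider({"extract": [fixture_extraction_response()]})
    partial = extract_chunk(_chunk(), llm)
    assert len(partial.entities) == 6
    assert not partial.failures


def test_extract_chunk_retries_then_succeeds():
    llm = ScriptedProvider({"extract": ["not json at all",
                                        fixture_extraction_response()]})
    partial = extract_chunk(_chunk(), llm)
    assert len(partial.entities) == 6


def test_extract_chunk_bounded_failure():
    llm = ScriptedProvider({"extract": ["still not json"]})
    partial = extract_chunk(_chunk(), llm, max_retries=2)
    assert partial.entities == []
    assert partial.failures[0]["retries"] == 2


# -- merging ----------------------------------------------------------------

def test_merge_unifies_synonym_sharing_entities():
    a = DocumentKG(entities=[ChemicalEntity("THF")], source_chunks=[0])
    b = DocumentKG(entities=[ChemicalEntity("tetrahydrofuran",
                                            abbreviations=["THF"])],
                   source_chunks=[1])
    merged = merge_kgs([a, b])
    assert len(merged.entities) == 1
    entity = merged.entities[0]
    assert entity.canonical_name == "tetrahydrofuran"
    assert set(entity.all_names) >= {"tetrahydrofuran", "THF"}


def test_merge_is_idempotent():
    kg = merge_kgs([DocumentKG(
        entities=[ChemicalEntity("water"), ChemicalEntity("ethanol")],
        procedures=[ProcedureRecord("p", "mix things", source_chunks=[0])],
        source_chunks=[0])])
    again = merge_kgs([kg])
    assert again == kg


def test_merge_order_insensitive_for_disjoint_partials(rng):
    partials = [
        DocumentKG(entities=[ChemicalEntity(f"chem{i}")],
                   procedures=[ProcedureRecord(f"x{i}", f"step {i}",
                                               source_chunks=[i])],
                   source_chunks=[i])
        for i in range(5)
    ]
    reference = merge_kgs(partials)
    for _ in range(5):
        perm = [partials[i] for i in rng.permutation(5)]
        assert merge_kgs(perm) == reference


def test_no_record_lost_in_merge():
    partials = [
        DocumentKG(purifications=["recrystallize"], notes=["caution"],
                   source_chunks=[0]),
        DocumentKG(purifications=["distill"], source_chunks=[1]),
    ]
    merged = merge_kgs(partials)
    assert merged.purifications == ["recrystallize", "distill"]
    assert merged.notes == ["caution"]


# -- indexing ---------------------------------------------------------------

def test_index_document_record_count(store):
    text = "y" * 4 * 5000  # 5000 tokens
    ref = index_document(text, store, limit=2048)
    records = store.records("doc-db")
    assert len(records) == 3  # ceil(5000/2048)
    assert all(r.metadata["doc_ref"] == ref for r in records)


def test_index_empty_document(store):
    index_document("", store)
    assert store.records("doc-db") == []


def test_self_retrieval_ranks_own_chunk_first(store):
    text = fixture_paper_text()
    index_document(text, store, limit=64)
    sentence = "extracted 30 times with 20 ml ethyl acetate"
    (top, score), *_ = store.query(sentence, "doc-db", 3)
    assert sentence.split()[1] in top.text or "extracted" in top.text


# -- scoring ----------------------------------------------------------------

@pytest.mark.parametrize("predicted, gold, p, r, f1", [
    (["a", "b"], ["a", "b"], 1.0, 1.0, 1.0),
    (["a", "b", "c"], ["a", "b", "x", "y"], 2 / 3, 1 / 2, 4 / 7),
    ([], ["a"], 0.0, 0.0, 0.0),
    (["A "], ["a"], 1.0, 1.0, 1.0),  # normalization
    (["a", "b", "c", "d"], ["a"], 1 / 4, 1.0, 2 / 5),
])
def test_score_extraction_hand_counts(predicted, gold, p, r, f1):
    scores = score_extraction(predicted, gold)
    assert scores.precision == pytest.approx(p)
    assert scores.recall == pytest.approx(r)
    assert scores.f1 == pytest.approx(f1)


def test_kg_json_roundtrip():
    llm = ScriptedProvider({"extract": [fixture_extraction_response()]})
    partial = extract_chunk(_chunk(), llm)
    kg = merge_kgs([partial])
    assert DocumentKG.from_json(kg.to_json()) == kg
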