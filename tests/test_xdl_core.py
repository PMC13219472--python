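import numpy as np
import pytest

from chemxdl.synth import (random_valid_document, seeded_error_fixture)
from chemxdl.units import Quantity
from chemxdl.xdl_core import (DEFAULT_REGISTRY, XDLDocument, XDLError,
                              XDLStep, parse_xdl, serialize_xdl,
                              validate_document)

SIMPLE = """
<Synthesis>
  <Hardware><Component id="reactor" type="reactor" /></Hardware>
  <Reagents><Reagent id="water" name="water" role="solvent" /></Reagents>
  <Procedure>
    <Add vessel="reactor" reagent="water" volume="20 mL" />
    <Stir vessel="reactor" time="5 min" />
    <HeatChill vessel="reactor" temp="65 °C" time="1 h" />
  </Procedure>
</Synthesis>
"""


def test_wellformed_document_has_no_issues():
    doc, issues = parse_xdl(SIMPLE)
    assert issues == []
    assert [s.step_name for s in doc.procedure] == ["Add", "Stir", "HeatChill"]
    assert doc.procedure[0].attributes["volume"] == Quantity(20.0, "mL", "volume")


def test_registry_has_the_sixteen_default_steps():
    assert len(DEFAULT_REGISTRY) == 16
    assert DEFAULT_REGISTRY["Repeat"].allows_children
    assert all(not s.allows_children for n, s in DEFAULT_REGISTRY.items()
               if n != "Repeat")


def test_two_independent_errors_reported_in_one_call():
    text = SIMPLE.replace("<Stir vessel=\"reactor\" time=\"5 min\" />",
                          "<Sonicate vessel=\"reactor\" time=\"5 min\" />") \
                 .replace("reagent=\"water\"", "reagent=\"ghost\"")
    _, issues = parse_xdl(text)
    assert len(issues) == 2
    assert {i.category for i in issues} == {"schema", "missing-reagent"}


def test_kelvin_temperature_is_a_unit_issue():
    text = SIMPLE.replace('temp="65 °C"', 'temp="300 K"')
    _, issues = parse_xdl(text)
    assert len(issues) == 1
    assert issues[0].category == "unit"
    assert issues[0].line is not None


def test_malformed_xml_is_a_single_syntax_issue():
    doc, issues = parse_xdl("<Synthesis><Procedure>")
    assert doc is None
    assert len(issues) == 1
    assert issues[0].category == "syntax"


def test_empty_input_raises():
    with pytest.raises(XDLError):
        parse_xdl("   ")


def test_duplicate_reagent_first_declaration_wins():
    text = SIMPLE.replace(
        '<Reagent id="water" name="water" role="solvent" />',
        '<Reagent id="water" name="water" role="solvent" />'
        '<Reagent id="water" name="heavy water" />')
    doc, issues = parse_xdl(text)
    assert [i.code for i in issues] == ["DUPLICATE_ID"]
    assert [r.name for r in doc.reagents] == ["water"]


@pytest.mark.parametrize("seed", range(8))
def test_seeded_error_manifest_oracle(seed):
    """Fixtures with k seeded independent errors yield exactly k issues
    whose (category, location) match the seed manifest."""
    rng = np.random.default_rng(seed)
    xml_text, manifest = seeded_error_fixture(rng)
    _, issues = parse_xdl(xml_text)
    got = sorted((i.category, i.location) for i in issues)
    assert got == manifest


@pytest.mark.parametrize("seed", range(5))
def test_roundtrip_and_validation_idempotence(seed):
    doc = random_valid_document(np.random.default_rng(seed))
    assert validate_document(doc) == []
    text = serialize_xdl(doc)
    doc2, issues = parse_xdl(text)
    assert issues == []
    assert doc2 == doc
    assert validate_document(doc2) == []
    assert serialize_xdl(doc2) == text  # stable serialization


def test_repeat_children_preserved_through_roundtrip():
    doc, issues = parse_xdl(SIMPLE.replace(
        "<Stir vessel=\"reactor\" time=\"5 min\" />",
        "<Repeat repeats=\"3\"><Stir vessel=\"reactor\" time=\"5 min\" />"
        "<Wait time=\"1 min\" /></Repeat>"))
    assert issues == []
    repeat = doc.procedure[1]
    assert repeat.attributes["repeats"] == 3
    assert [c.step_name for c in repeat.children] == ["Stir", "Wait"]
    doc2, issues2 = parse_xdl(serialize_xdl(doc))
    assert issues2 == [] and doc2 == doc


def test_serializer_refuses_invalid_document():
    doc = XDLDocument(procedure=[])  # empty procedure violates invariants
    with pytest.raises(XDLError) as exc:
        serialize_xdl(doc)
    assert exc.value.issues


def test_validate_flags_undeclared_vessel():
    doc, _ = parse_xdl(SIMPLE)
    doc.procedure.append(XDLStep("Stir", {
        "vessel": "reactor2", "time": Quantity(1, "min", "time")}))
    issues = validate_document(doc)
    assert [i.category for i in issues] == ["missing-hardware"]


def test_restricted_registry_rejects_outside_steps():
    limited = {k: v for k, v in DEFAULT_REGISTRY.items()
               if k in ("Add", "Stir")}
    _, issues = parse_xdl(SIMPLE, limited)
    assert [i.code for i in issues] == ["UNKNOWN_STEP"]
    assert "HeatChill" in issues[0].message
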