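"""Value-set content, concept invariants and label resolution."""

import pytest
from hypothesis import given, settings, strategies as st

from boafhir import config
from boafhir.terminology import (
    SHIPPED_VALUESETS,
    Concept,
    TerminologyRegistry,
    UnknownValueSetError,
    UnmappedLabelError,
    default_registry,
    lookup_concept,
    to_fhir_valueset,
    validate_membership,
    valueset_members,
)

EXPECTED_SIZES = {
    "BCABodySiteVS": 4,
    "BCAMeasurementsVS": 2,
    "BCATissueVS": 8,
    "BCARegionVS": 8,
    "BodyStructureLandmarkVS": 104,
}


@pytest.mark.parametrize("vs_id,size", sorted(EXPECTED_SIZES.items()))
def test_shipped_cardinalities(vs_id, size):
    assert len(valueset_members(vs_id)) == size


def test_body_site_displays():
    displays = {c.display for c in valueset_members("BCABodySiteVS")}
    assert displays == {
        "abdominal cavity",
        "thoracic cavity",
        "mediastinum",
        "pericardium",
    }
    assert all(
        c.system == config.SNOMED_CT for c in valueset_members("BCABodySiteVS")
    )


def test_measurement_modes_cover_both_extremity_options():
    displays = [c.display for c in valueset_members("BCAMeasurementsVS")]
    assert any("including extremities" in d for d in displays)
    assert any("excluding extremities" in d for d in displays)


def test_unknown_valueset_raises():
    with pytest.raises(UnknownValueSetError):
        valueset_members("NoSuchVS")
    with pytest.raises(UnknownValueSetError):
        validate_membership(
            Concept(system=config.SNOMED_CT, code="1", display="x"), "NoSuchVS"
        )


@pytest.mark.parametrize("vs_id", SHIPPED_VALUESETS)
def test_concept_invariants_and_uniqueness(vs_id):
    members = valueset_members(vs_id)
    keys = [c.key for c in members]
    assert len(set(keys)) == len(keys), "duplicate (system, code) pair"
    for c in members:
        assert c.code and not any(ch.isspace() for ch in c.code)
        assert c.system in config.SYSTEM_KEYS.values()
        assert c.display.strip()


@pytest.mark.parametrize("vs_id", SHIPPED_VALUESETS)
def test_lookup_total_over_shipped_displays(vs_id):
    """Every shipped display resolves, and the resolved concept is a member
    of its home set; with the home system preferred the round trip is exact."""
    for c in valueset_members(vs_id):
        found = lookup_concept(c.display)
        assert validate_membership(found, vs_id)
        assert lookup_concept(c.display, preferred_system=c.system) == c


def test_membership_checks_system_and_code_not_display(registry):
    member = valueset_members("BCABodySiteVS")[0]
    assert validate_membership(member, "BCABodySiteVS")
    renamed = Concept(system=member.system, code=member.code, display="whatever")
    assert validate_membership(renamed, "BCABodySiteVS")
    bad_code = Concept(system=member.system, code="000", display=member.display)
    assert not validate_membership(bad_code, "BCABodySiteVS")
    # same code under another system never matches (brute-force scan)
    other = Concept(
        system=config.LOCAL_SYSTEM, code=member.code, display=member.display
    )
    assert not any(
        other.key == m.key for m in valueset_members("BCABodySiteVS")
    )
    assert not validate_membership(other, "BCABodySiteVS")


def test_lookup_prefers_snomed_then_local(registry):
    # "abdominal cavity" exists only in SNOMED; a synonym lookup still
    # lands on the SNOMED concept via the priority chain
    c = lookup_concept("Abdominal   Cavity")
    assert c.system == config.SNOMED_CT
    c2 = lookup_concept("sat")
    assert c2.display == "subcutaneous adipose tissue"


def test_unmapped_label_errors():
    with pytest.raises(UnmappedLabelError) as exc:
        lookup_concept("xyzzy-nonsense")
    assert exc.value.label == "xyzzy-nonsense"
    with pytest.raises(UnmappedLabelError):
        lookup_concept("   ")


@settings(max_examples=60, derandomize=True)
@given(
    vs_id=st.sampled_from(SHIPPED_VALUESETS),
    index=st.integers(min_value=0, max_value=200),
    spacing=st.sampled_from([" ", "  ", "\t"]),
    case=st.sampled_from([str.upper, str.lower, str.title]),
)
def test_lookup_is_case_and_whitespace_insensitive(vs_id, index, spacing, case):
    members = valueset_members(vs_id)
    c = members[index % len(members)]
    mangled = spacing + case(c.display).replace(" ", spacing) + spacing
    found = lookup_concept(mangled, preferred_system=c.system)
    assert found == c


def test_concept_rejects_whitespace_code():
    with pytest.raises(ValueError):
        Concept(system=config.SNOMED_CT, code="12 34", display="x")
    with pytest.raises(ValueError):
        Concept(system=config.SNOMED_CT, code="", display="x")


def test_fhir_valueset_export_round_trips_concepts():
    doc = to_fhir_valueset("BCATissueVS")
    assert doc["resourceType"] == "ValueSet"
    assert doc["url"].endswith("/ValueSet/BCATissueVS")
    exported = {
        (inc["system"], c["code"])
        for inc in doc["compose"]["include"]
        for c in inc["concept"]
    }
    assert exported == {c.key for c in valueset_members("BCATissueVS")}


def test_custom_table_loading(tmp_path):
    table = "display\tsystem\tcode\tsynonyms\nfoo organ\tlocal\tfoo\tbar|baz\n"
    reg = TerminologyRegistry()
    reg.load_table(table.splitlines(), "CustomVS")
    assert len(reg.valueset_members("CustomVS")) == 1
    assert reg.lookup_concept("baz").code == "foo"


def test_stable_member_order():
    assert valueset_members("BodyStructureLandmarkVS") == valueset_members(
        "BodyStructureLandmarkVS"
    )
    assert valueset_members("BodyStructureLandmarkVS")[0].display == "spleen"
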