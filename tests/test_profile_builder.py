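"""Resource builders, provenance tagging, bundle assembly, profile export."""

import copy
import json

import pytest

from boafhir import (
    BuildContext,
    BuildError,
    OrganVolume,
    assemble_bundle,
    build_bca_observation,
    build_body_structure_observation,
    build_diagnostic_report,
    build_imaging_study,
    build_read_procedure,
    bundle_to_ndjson,
    config,
    export_profile_definitions,
    generate_synthetic_result,
    lookup_concept,
    profile_from_structure_definition,
    tag_ai_provenance,
    validate_bundle,
)
from boafhir.boa_model import GenerationConfig
from boafhir.profile_builder import (
    procedure_model_metadata,
    profile_canonical,
    study_uid_from_identifier,
)
from boafhir.terminology import Concept

CTX = BuildContext(patient_reference="Patient/p1")


def test_bca_observation_component_layout(result):
    """8 tissues with densities plus a slice range -> 17 components."""
    region = result.regions[0]
    assert region.slice_range is not None
    obs = build_bca_observation(region, CTX, "ImagingStudy/s1")
    assert obs["status"] == "final"
    assert len(obs["component"]) == 17  # 8 volume + 8 density + 1 sliceRange
    assert obs["meta"]["profile"] == [profile_canonical("bca")]
    volume_units = {
        c["valueQuantity"]["code"]
        for c in obs["component"]
        if "valueQuantity" in c
    }
    assert volume_units == {config.UCUM_ML, config.UCUM_HU}
    site_codings = obs["bodySite"]["coding"]
    assert site_codings[0]["system"] == config.SNOMED_CT


def test_bca_observation_slice_range_is_integer_range(result):
    obs = build_bca_observation(result.regions[0], CTX, "ImagingStudy/s1")
    rng = obs["component"][-1]["valueRange"]
    low, high = rng["low"]["value"], rng["high"]["value"]
    assert (low, high) == (
        result.regions[0].slice_range.low,
        result.regions[0].slice_range.high,
    )
    assert low <= high


def test_bca_observation_rejects_non_member_bodysite(result):
    region = result.regions[0].model_copy(
        update={
            "body_site": Concept(
                system=config.SNOMED_CT, code="000", display="nowhere"
            )
        }
    )
    with pytest.raises(BuildError):
        build_bca_observation(region, CTX, "ImagingStudy/s1")


def test_body_structure_observation_components(result):
    obs = build_body_structure_observation(result.organs, CTX, "ImagingStudy/s1")
    assert len(obs["component"]) == 104
    assert all(
        c["valueQuantity"]["code"] == config.UCUM_ML for c in obs["component"]
    )
    single = build_body_structure_observation(
        [OrganVolume(structure=lookup_concept("spleen"), volume_ml=250.0)],
        CTX,
        "ImagingStudy/s1",
    )
    assert len(single["component"]) == 1
    assert single["component"][0]["valueQuantity"]["unit"] == "mL"


def test_body_structure_observation_rejects_duplicates_and_empty(result):
    with pytest.raises(BuildError):
        build_body_structure_observation([], CTX, "ImagingStudy/s1")
    dup = [result.organs[0], result.organs[0]]
    with pytest.raises(BuildError):
        build_body_structure_observation(dup, CTX, "ImagingStudy/s1")


def test_imaging_study_series_and_identifier():
    r = generate_synthetic_result(8, GenerationConfig(n_series=2, n_organs=5))
    study = build_imaging_study(r, CTX)
    assert study["numberOfSeries"] == 2
    assert len(study["series"]) == 2
    assert study["identifier"][0]["system"] == "urn:dicom:uid"
    # identifier parses back to the original study instance UID
    assert study_uid_from_identifier(study) == r.study_uid
    assert study["started"] == r.started


def test_imaging_study_rejects_duplicate_series(result):
    r = result.model_copy(update={"series": result.series + result.series})
    with pytest.raises(BuildError):
        build_imaging_study(r, CTX)


def test_diagnostic_report_aggregates(result):
    report = build_diagnostic_report(
        result, ["Observation/a", "Observation/b"], "ImagingStudy/s1", CTX
    )
    assert [r["reference"] for r in report["result"]] == [
        "Observation/a",
        "Observation/b",
    ]
    assert report["imagingStudy"] == [{"reference": "ImagingStudy/s1"}]
    forms = {f["contentType"] for f in report["presentedForm"]}
    assert forms == {"application/json", "application/pdf"}
    with pytest.raises(BuildError):
        build_diagnostic_report(result, [], "ImagingStudy/s1", CTX)


def test_read_procedure_stores_model_metadata(result):
    proc = build_read_procedure(result.model, "DiagnosticReport/r1", CTX)
    assert proc["report"] == [{"reference": "DiagnosticReport/r1"}]
    assert proc["meta"]["profile"] == [config.MII_PROCEDURE_PROFILE]
    recovered = procedure_model_metadata(proc)
    assert recovered == result.model


def test_aiast_tag_idempotent_and_local(bundle):
    obs = copy.deepcopy(bundle["entry"][1]["resource"])
    obs["meta"].pop("security")

    def aiast_tags(r):
        return [
            t
            for t in r.get("meta", {}).get("security", [])
            if t["code"] == config.AIAST_CODE
        ]

    once = tag_ai_provenance(obs)
    twice = tag_ai_provenance(once)
    assert len(aiast_tags(obs)) == 0  # input untouched
    assert len(aiast_tags(once)) == 1
    assert len(aiast_tags(twice)) == 1
    strip = lambda r: {k: v for k, v in r.items() if k != "meta"}
    assert json.dumps(strip(once), sort_keys=True) == json.dumps(
        strip(obs), sort_keys=True
    )
    assert once["meta"]["security"][0]["system"] == config.SECURITY_SYSTEM


def test_bundle_layout_and_determinism(result, bundle):
    types = [e["resource"]["resourceType"] for e in bundle["entry"]]
    assert len(bundle["entry"]) == 12
    assert types[0] == "ImagingStudy"
    assert types[1:10] == ["Observation"] * 9  # 8 BCA + 1 body-structure
    assert types[10:] == ["DiagnosticReport", "Procedure"]
    again = assemble_bundle(result, BuildContext())
    assert json.dumps(bundle, sort_keys=True) == json.dumps(again, sort_keys=True)


def test_bundle_random_ids_differ(result):
    ctx = BuildContext(id_strategy="uuid")
    b1 = assemble_bundle(result, ctx)
    b2 = assemble_bundle(result, ctx)
    ids1 = [e["resource"]["id"] for e in b1["entry"]]
    ids2 = [e["resource"]["id"] for e in b2["entry"]]
    assert ids1 != ids2
    assert not validate_bundle(b1)


def test_bundle_references_resolve_internally(bundle):
    local = {
        f"{e['resource']['resourceType']}/{e['resource']['id']}"
        for e in bundle["entry"]
    }
    report = bundle["entry"][10]["resource"]
    for ref in report["result"]:
        assert ref["reference"] in local
    assert report["imagingStudy"][0]["reference"] in local
    proc = bundle["entry"][11]["resource"]
    assert proc["report"][0]["reference"] in local
    broken = copy.deepcopy(bundle)
    del broken["entry"][0]
    issues = validate_bundle(broken)
    assert any(i.rule_id == "reference-dangling" for i in issues)


def test_every_bundle_resource_carries_aiast(bundle):
    for entry in bundle["entry"]:
        tags = entry["resource"]["meta"]["security"]
        assert any(t["code"] == config.AIAST_CODE for t in tags)


def test_ndjson_one_resource_per_line(bundle):
    lines = bundle_to_ndjson(bundle).splitlines()
    assert len(lines) == 12
    assert json.loads(lines[0])["resourceType"] == "ImagingStudy"


def test_profile_export_inventory():
    profiles = export_profile_definitions()
    assert len(profiles) == 4
    assert {p.base_resource for p in profiles} == {
        "Observation",
        "DiagnosticReport",
        "ImagingStudy",
    }
    bca = next(p for p in profiles if p.id == "boa-bca-observation")
    bindings = {
        vs for c in bca.constraints if c.path == "Observation.bodySite"
        for vs in c.binding
    }
    assert bindings == {"BCABodySiteVS"}
    code_bindings = {
        vs for c in bca.constraints if c.path == "Observation.code"
        for vs in c.binding
    }
    assert code_bindings == {"BCAMeasurementsVS"}


def test_structure_definition_round_trip():
    for profile in export_profile_definitions():
        doc = profile.to_structure_definition()
        assert doc["resourceType"] == "StructureDefinition"
        assert doc["derivation"] == "constraint"
        assert profile_from_structure_definition(doc) == profile
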