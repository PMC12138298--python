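"""Data model: UID grammar, parsing, serialization, synthetic generation."""

import itertools
import json
import warnings

import pytest
from hypothesis import given, settings, strategies as st

from boafhir import (
    Attachment,
    GenerationConfig,
    ModelMetadata,
    ParseError,
    SliceRange,
    generate_synthetic_result,
    parse_boa_result,
    result_to_json,
    serialize_boa_result,
    validate_dicom_uid,
)

# ---------------------------------------------------------------------------
# DICOM UID grammar
# ---------------------------------------------------------------------------


def uid_grammar_oracle(s: str) -> bool:
    """Independent brute-force check of the dotted-decimal UID grammar:
    digit-only non-empty components, no leading zeros (except a bare '0'),
    total length 1..64."""
    if not isinstance(s, str) or not 1 <= len(s) <= 64:
        return False
    for comp in s.split("."):
        if not comp or any(ch not in "0123456789" for ch in comp):
            return False
        if len(comp) > 1 and comp[0] == "0":
            return False
    return True


def test_uid_exhaustive_small_alphabet():
    """Exhaustive agreement with the grammar oracle over all strings of
    length <= 6 over {0, 1, '.', 'a'}."""
    alphabet = "01.a"
    for n in range(1, 7):
        for chars in itertools.product(alphabet, repeat=n):
            s = "".join(chars)
            assert validate_dicom_uid(s) == uid_grammar_oracle(s), s


EDGE_CASES = [
    "1.2.840.10008.1.2",  # canonical transfer syntax UID
    "1.2.04.5",  # leading zero
    "0",
    "0.0",
    "00",
    "01",
    "1",
    "10",
    "1.0",
    "1.01",
    "1.10",
    "1.",
    ".1",
    "..",
    "1..2",
    ".",
    "",
    " ",
    "1 2",
    "1.2 ",
    " 1.2",
    "a.b",
    "1.2.x",
    "1,2",
    "-1.2",
    "1.-2",
    "1.2.3.4.5.6.7.8.9.10",
    "999999999999999999999999999999",
    "0.1.2.3",
    "1.2.0.4",
    "1.2.00.4",
    "1" * 63,
    "1" * 64,
    "1" * 65,
    "1." * 31 + "1",  # 63 chars, valid
    "1." * 31 + "12",  # 64 chars, valid
    "1." * 32 + "1",  # 65 chars, too long
    ".".join(["1"] * 32),  # 63 chars
    ".".join(["1"] * 33),  # 65 chars
    "1.2.826.0.1.3680043.9.7420.1.1",
    "2.25.329800735698586629295641978511506172918",
    "1.3.6.1.4.1",
    "1.2.840.113619.2.55.3",
    "0.0.0.0.0",
    "1.2.3.04",
    "04.2.3",
    "1\t2",
    "1.2\n",
    "١.٢",  # non-ASCII digits must be rejected
    "1.2.3.4a",
    "a1.2",
]


def test_uid_curated_edge_cases():
    assert len(EDGE_CASES) >= 50
    for s in EDGE_CASES:
        assert validate_dicom_uid(s) == uid_grammar_oracle(s), repr(s)
    # a few hard-pinned expectations
    assert validate_dicom_uid("1.2.840.10008.1.2")
    assert not validate_dicom_uid("1.2.04.5")
    assert validate_dicom_uid("1" * 64)
    assert not validate_dicom_uid("1" * 65)


def test_uid_agrees_with_pydicom_reference():
    """Cross-check against pydicom's UID validity on the edge list.

    pydicom strips surrounding whitespace before validating (DICOM pads
    UI values on the wire), so padded strings are out of scope here."""
    from pydicom.uid import UID

    for s in EDGE_CASES:
        if not s or s != s.strip():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert validate_dicom_uid(s) == UID(s).is_valid, repr(s)


# ---------------------------------------------------------------------------
# Model invariants
# ---------------------------------------------------------------------------


def test_slice_range_ordering_enforced():
    assert SliceRange(low=3, high=3).high == 3
    with pytest.raises(ValueError):
        SliceRange(low=5, high=4)
    with pytest.raises(ValueError):
        SliceRange(low=0, high=4)


def test_attachment_requires_exactly_one_payload():
    Attachment(content_type="application/pdf", data="aGk=")
    Attachment(content_type="application/json", url="https://x/y.json")
    with pytest.raises(ValueError):
        Attachment(content_type="application/pdf")
    with pytest.raises(ValueError):
        Attachment(content_type="application/pdf", data="aGk=", url="https://x")
    with pytest.raises(ValueError):
        Attachment(content_type="text/html", data="aGk=")


def test_model_metadata_requires_name_and_version():
    with pytest.raises(ValueError):
        ModelMetadata(name="", version="1")
    with pytest.raises(ValueError):
        ModelMetadata(name="BOA", version="  ")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

MINIMAL = {
    "patient_id": "p1",
    "study_uid": "1.2.3.4",
    "series": [{"series_uid": "1.2.3.4.1"}],
    "organs": [{"structure": "spleen", "volume_ml": 250.0}],
    "model": {"name": "BOA", "version": "1.0"},
}


def test_parse_minimal_document():
    result = parse_boa_result(dict(MINIMAL))
    assert result.regions == []
    assert len(result.organs) == 1
    assert result.organs[0].structure.display == "spleen"


def test_parse_resolves_labels_through_terminology():
    from boafhir import lookup_concept

    result = parse_boa_result(dict(MINIMAL))
    assert result.organs[0].structure == lookup_concept("spleen")


@pytest.mark.parametrize(
    "mangle,path_fragment",
    [
        (lambda d: d.update(study_uid="1.2.04.5"), "study_uid"),
        (lambda d: d.pop("patient_id"), "patient_id"),
        (lambda d: d.pop("series"), "series"),
        (lambda d: d["organs"][0].update(structure="xyzzy"), "organs[0].structure"),
        (
            lambda d: d["organs"][0].update(structure="muscle"),
            "organs[0].structure",
        ),  # mapped label, wrong value set
        (lambda d: d["organs"][0].update(volume_ml=-5), "volume_ml"),
        (lambda d: d["model"].update(name=""), "name"),
        (lambda d: d["series"][0].update(series_uid="bad uid"), "series"),
    ],
)
def test_parse_errors_carry_json_paths(mangle, path_fragment):
    doc = json.loads(json.dumps(MINIMAL))
    mangle(doc)
    with pytest.raises(ParseError) as exc:
        parse_boa_result(doc)
    assert path_fragment in exc.value.path


def test_parse_rejects_malformed_json():
    with pytest.raises(ParseError):
        parse_boa_result("{not json")


def test_parse_warns_on_unknown_keys(caplog):
    doc = dict(MINIMAL, unexpected_key=1)
    with caplog.at_level("WARNING", logger="boafhir.boa_model"):
        parse_boa_result(doc)
    assert any("unexpected_key" in r.message for r in caplog.records)


def test_generated_results_parse_without_warnings(caplog):
    result = generate_synthetic_result(3)
    with caplog.at_level("WARNING", logger="boafhir.boa_model"):
        reparsed = parse_boa_result(serialize_boa_result(result))
    assert not caplog.records
    assert reparsed == result


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


def test_generator_defaults_cover_full_analysis(result):
    assert len(result.regions) == 8  # 4 body sites x 2 measurement modes
    assert len(result.organs) == 104
    assert all(len(r.tissues) == 8 for r in result.regions)
    site_mode = {(r.body_site.code, r.mode.code) for r in result.regions}
    assert len(site_mode) == 8


def test_generator_deterministic_bytes():
    a = result_to_json(generate_synthetic_result(11))
    b = result_to_json(generate_synthetic_result(11))
    assert a == b
    assert result_to_json(generate_synthetic_result(12)) != a


def test_generator_rejects_empty_config():
    with pytest.raises(ValueError):
        generate_synthetic_result(1, GenerationConfig(n_regions=0, n_organs=0))
    with pytest.raises(ValueError):
        generate_synthetic_result(1, GenerationConfig(n_organs=105))
    with pytest.raises(ValueError):
        GenerationConfig(organ_volume_ml=(100.0, 10.0))


def test_generator_respects_counts_and_ranges():
    cfg = GenerationConfig(
        n_regions=3, n_organs=5, organ_volume_ml=(100.0, 101.0)
    )
    r = generate_synthetic_result(5, cfg)
    assert len(r.regions) == 3 and len(r.organs) == 5
    assert all(100.0 <= o.volume_ml <= 101.0 for o in r.organs)


@settings(max_examples=25, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_parse_serialize_identity_property(seed):
    """parse o serialize is the identity on everything the generator emits."""
    r = generate_synthetic_result(seed, GenerationConfig(n_organs=10, n_regions=2))
    assert parse_boa_result(serialize_boa_result(r)) == r
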