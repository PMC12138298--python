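"""Documented single-field mutation catalog for validator soundness checks.

Each :class:`Mutation` flips exactly one field (or one entry) of a
conformant analysis bundle and names the rule and element-path fragment
the validator must report.  The catalog doubles as executable
documentation of what the validator guards against; the pristine bundle
must validate with zero errors.

Layout assumed by the index-based mutations (the default synthetic
bundle): entry 0 ImagingStudy, entries 1..8 body-composition
Observations, entry 9 the body-structure volume Observation, entry 10
the DiagnosticReport, entry 11 the read Procedure.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable

__all__ = ["Mutation", "MUTATIONS", "apply_mutation"]


@dataclass(frozen=True)
class Mutation:
    id: str
    description: str
    apply: Callable[[dict], None]  # mutates a deep copy in place
    expected_rule: str
    #: fragment that must occur in the path of at least one reported error
    expected_path_fragment: str


def _entry(bundle: dict, i: int) -> dict:
    return bundle["entry"][i]["resource"]


def _non_member_bodysite(b):
    _entry(b, 1)["bodySite"]["coding"][0]["code"] = "000"


def _wrong_status(b):
    _entry(b, 1)["status"] = "preliminary"


def _litre_unit(b):
    _entry(b, 1)["component"][0]["valueQuantity"]["code"] = "L"


def _non_ucum_system(b):
    _entry(b, 9)["component"][0]["valueQuantity"]["system"] = (
        "http://example.org/units"
    )


def _bad_study_uid(b):
    _entry(b, 0)["identifier"][0]["value"] = "urn:oid:1.2.04.5"


def _overlong_series_uid(b):
    _entry(b, 0)["series"][0]["uid"] = ".".join(["1"] * 33)  # 65 chars


def _strip_aiast(b):
    _entry(b, 1)["meta"].pop("security")


def _dangling_result(b):
    _entry(b, 10)["result"][0]["reference"] = "Observation/does-not-exist"


def _drop_imaging_study(b):
    del b["entry"][0]


def _drop_observation(b):
    del b["entry"][1]


def _duplicate_organ_component(b):
    comps = _entry(b, 9)["component"]
    comps.append(copy.deepcopy(comps[0]))


def _non_member_structure(b):
    _entry(b, 9)["component"][0]["code"]["coding"][0]["code"] = "000"


def _drop_subject(b):
    del _entry(b, 1)["subject"]


def _strip_meta_profile(b):
    _entry(b, 9)["meta"].pop("profile")


def _series_count_off_by_one(b):
    _entry(b, 0)["numberOfSeries"] += 1


def _bad_content_type(b):
    _entry(b, 10)["presentedForm"][0]["contentType"] = "text/html"


def _slice_range_unit(b):
    # the slice-range component is the last component of a BCA observation
    _entry(b, 1)["component"][-1]["valueRange"]["low"]["code"] = "mm"


def _second_report(b):
    b["entry"].append(copy.deepcopy(b["entry"][10]))


MUTATIONS: tuple[Mutation, ...] = (
    Mutation(
        "non-member-bodysite",
        "bodySite coding replaced by a code outside BCABodySiteVS",
        _non_member_bodysite,
        "binding-violation",
        "bodySite",
    ),
    Mutation(
        "wrong-status",
        "Observation.status changed away from the fixed value 'final'",
        _wrong_status,
        "fixed-value-mismatch",
        "status",
    ),
    Mutation(
        "litre-unit",
        "tissue volume unit changed from millilitres to litres",
        _litre_unit,
        "unit-ucum",
        "component[0].valueQuantity",
    ),
    Mutation(
        "non-ucum-system",
        "organ volume quantity moved off the UCUM system",
        _non_ucum_system,
        "unit-ucum",
        "component[0].valueQuantity",
    ),
    Mutation(
        "bad-study-uid",
        "study identifier URN carries a leading-zero UID component",
        _bad_study_uid,
        "uid-grammar",
        "identifier",
    ),
    Mutation(
        "overlong-series-uid",
        "series UID stretched past the 64-character DICOM bound",
        _overlong_series_uid,
        "uid-grammar",
        "series[0].uid",
    ),
    Mutation(
        "strip-aiast",
        "AIAST security tag removed from one observation",
        _strip_aiast,
        "aiast-missing",
        "entry[1].Observation",
    ),
    Mutation(
        "dangling-result",
        "DiagnosticReport.result entry retargeted at a missing observation",
        _dangling_result,
        "reference-dangling",
        "result",
    ),
    Mutation(
        "drop-imaging-study",
        "ImagingStudy entry removed from the bundle",
        _drop_imaging_study,
        "reference-dangling",
        "derivedFrom",
    ),
    Mutation(
        "drop-observation",
        "one observation entry removed; the report still lists it",
        _drop_observation,
        "report-coverage",
        "result",
    ),
    Mutation(
        "duplicate-organ-component",
        "one landmark component duplicated in the volume observation",
        _duplicate_organ_component,
        "duplicate-component",
        "component",
    ),
    Mutation(
        "non-member-structure",
        "landmark component code replaced by a non-member code",
        _non_member_structure,
        "binding-violation",
        "component[0].code",
    ),
    Mutation(
        "drop-subject",
        "mandatory Observation.subject removed",
        _drop_subject,
        "cardinality-min",
        "subject",
    ),
    Mutation(
        "strip-meta-profile",
        "meta.profile claim removed from the volume observation",
        _strip_meta_profile,
        "meta-profile-missing",
        "meta.profile",
    ),
    Mutation(
        "series-count-off-by-one",
        "numberOfSeries no longer matches the listed series",
        _series_count_off_by_one,
        "series-count-mismatch",
        "numberOfSeries",
    ),
    Mutation(
        "bad-content-type",
        "presentedForm contentType set to an unsupported MIME type",
        _bad_content_type,
        "value-allowed",
        "presentedForm",
    ),
    Mutation(
        "slice-range-unit",
        "slice-range bound given a length unit instead of a plain index",
        _slice_range_unit,
        "unit-ucum",
        "component",
    ),
    Mutation(
        "second-report",
        "a second DiagnosticReport entry added to the bundle",
        _second_report,
        "cardinality-bundle",
        "entry[12]",
    ),
)


def apply_mutation(bundle: dict, mutation: Mutation) -> dict:
    """Return a mutated deep copy; the input bundle is left untouched."""
    mutated = copy.deepcopy(bundle)
    mutation.apply(mutated)
    return mutated
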