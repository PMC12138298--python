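"""Builders turning a :class:`~boafhir.boa_model.BOAResult` into the five
linked FHIR R4 resources, plus the machine-readable profile definitions.

The profile set mirrors how one AI analysis is documented in FHIR:

* one **body-composition Observation** per analyzed region (a body-site
  cavity in one measurement mode), tissue volumes/densities as components;
* one **body-structure volume Observation** carrying every segmented
  landmark as a component (structure code + millilitre quantity);
* an **ImagingStudy** referencing *only* the series the model actually ran
  on, identified by the DICOM study instance UID;
* a **DiagnosticReport** as the central aggregator — it lists every
  observation in ``result``, points at the ImagingStudy, and carries the
  rendered reports (PDF/JSON/spreadsheet) as ``presentedForm``;
* a **Procedure** (referencing the MII read-procedure profile by canonical
  URL) documenting the model name, version and computational parameters.

Every built resource is tagged with the HL7 ``AIAST`` security label so
downstream consumers can tell AI-asserted data from human-entered data.
Resources are plain FHIR R4 JSON dicts; profile conformance is expressed
through :class:`ProfileDefinition` constraint tables consumed by
:mod:`boafhir.validator`.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import uuid
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, field_validator

from . import config
from .boa_model import (
    BOAResult,
    ModelMetadata,
    OrganVolume,
    RegionMeasurement,
    validate_dicom_uid,
)
from . import terminology
from .terminology import Concept, TerminologyRegistry

__all__ = [
    "BuildError",
    "BuildContext",
    "Constraint",
    "ProfileDefinition",
    "PROFILE_IDS",
    "profile_canonical",
    "export_profile_definitions",
    "profile_from_structure_definition",
    "build_bca_observation",
    "build_body_structure_observation",
    "build_imaging_study",
    "build_diagnostic_report",
    "build_read_procedure",
    "tag_ai_provenance",
    "assemble_bundle",
    "bundle_to_ndjson",
]


class BuildError(ValueError):
    """A resource could not be built (binding violation, bad input)."""

    def __init__(self, message: str, path: str = ""):
        super().__init__(f"{path}: {message}" if path else message)
        self.path = path


@dataclass(frozen=True)
class BuildContext:
    """Build-time settings shared by all builders.

    ``id_strategy='deterministic'`` derives resource ids from a content
    hash so identical inputs always produce byte-identical bundles;
    ``'uuid'`` draws random UUID4 ids instead.  When ``patient_reference``
    is left unset, :func:`assemble_bundle` derives ``Patient/<patient_id>``
    from the result so the patient identity survives extraction.
    """

    patient_reference: Optional[str] = None
    canonical_base: str = config.DEFAULT_CANONICAL_BASE
    timestamp: Optional[str] = None
    id_strategy: Literal["deterministic", "uuid"] = "deterministic"

    def __post_init__(self):
        if "://" not in self.canonical_base:
            raise BuildError(
                f"canonical_base must be an absolute URI: {self.canonical_base!r}"
            )


# ---------------------------------------------------------------------------
# Profile definitions
# ---------------------------------------------------------------------------


class Constraint(BaseModel):
    """One element constraint of a profile.

    ``path`` is a dotted element path rooted at the base resource;
    cardinalities apply per immediate parent instance, as in FHIR.
    Exactly the checks the validator engine knows are expressible:
    fixed primitive values, required pattern codings, required value-set
    bindings (any-of over several sets), UCUM unit whitelists, allowed
    primitive values, fixed identifier systems, DICOM-UID grammar on
    values, and uniqueness of codings across repeats.
    """

    path: str
    min: int = 0
    max: str = "*"  # "*" or an integer literal
    fixed_value: Optional[str] = None
    pattern_concept: Optional[Concept] = None
    binding: tuple[str, ...] = ()
    binding_strength: str = "required"
    allowed_ucum: tuple[str, ...] = ()
    allowed_values: tuple[str, ...] = ()
    fixed_system: Optional[str] = None
    value_grammar: Optional[Literal["dicom-uid", "dicom-uid-urn"]] = None
    unique_codings: bool = False
    datatype: Optional[str] = None

    @field_validator("max")
    @classmethod
    def _max_ok(cls, v: str) -> str:
        if v != "*" and not v.isdigit():
            raise ValueError("max must be '*' or an integer literal")
        return v

    def max_count(self) -> Optional[int]:
        return None if self.max == "*" else int(self.max)


class ProfileDefinition(BaseModel):
    id: str
    canonical_url: str
    base_resource: str
    title: str
    constraints: tuple[Constraint, ...]

    def to_structure_definition(self) -> dict:
        """StructureDefinition-style JSON rendering of the constraint set."""
        elements = []
        for c in self.constraints:
            el: dict = {
                "id": c.path,
                "path": c.path,
                "min": c.min,
                "max": c.max,
            }
            if c.datatype:
                el["type"] = [{"code": c.datatype}]
            if c.fixed_value is not None:
                el["fixedCode"] = c.fixed_value
            if c.pattern_concept is not None:
                el["patternCodeableConcept"] = {
                    "coding": [c.pattern_concept.coding()]
                }
            if c.binding:
                el["binding"] = {
                    "strength": c.binding_strength,
                    "valueSet": list(c.binding),
                }
            if c.allowed_ucum:
                el["_allowedUcum"] = list(c.allowed_ucum)
            if c.allowed_values:
                el["_allowedValues"] = list(c.allowed_values)
            if c.fixed_system is not None:
                el["_fixedSystem"] = c.fixed_system
            if c.value_grammar is not None:
                el["_valueGrammar"] = c.value_grammar
            if c.unique_codings:
                el["_uniqueCodings"] = True
            elements.append(el)
        return {
            "resourceType": "StructureDefinition",
            "id": self.id,
            "url": self.canonical_url,
            "name": self.id.replace("-", "_"),
            "title": self.title,
            "status": "active",
            "kind": "resource",
            "abstract": False,
            "type": self.base_resource,
            "baseDefinition": (
                "http://hl7.org/fhir/StructureDefinition/" + self.base_resource
            ),
            "derivation": "constraint",
            "differential": {"element": elements},
        }


def profile_from_structure_definition(doc: dict) -> ProfileDefinition:
    """Inverse of :meth:`ProfileDefinition.to_structure_definition`."""
    constraints = []
    for el in doc.get("differential", {}).get("element", []):
        pattern = None
        if "patternCodeableConcept" in el:
            pattern = Concept(**el["patternCodeableConcept"]["coding"][0])
        binding = el.get("binding", {})
        constraints.append(
            Constraint(
                path=el["path"],
                min=el.get("min", 0),
                max=str(el.get("max", "*")),
                fixed_value=el.get("fixedCode"),
                pattern_concept=pattern,
                binding=tuple(binding.get("valueSet", [])),
                binding_strength=binding.get("strength", "required"),
                allowed_ucum=tuple(el.get("_allowedUcum", [])),
                allowed_values=tuple(el.get("_allowedValues", [])),
                fixed_system=el.get("_fixedSystem"),
                value_grammar=el.get("_valueGrammar"),
                unique_codings=el.get("_uniqueCodings", False),
                datatype=(el.get("type") or [{}])[0].get("code"),
            )
        )
    return ProfileDefinition(
        id=doc["id"],
        canonical_url=doc["url"],
        base_resource=doc["type"],
        title=doc.get("title", doc["id"]),
        constraints=tuple(constraints),
    )


PROFILE_IDS = {
    "bca": "boa-bca-observation",
    "body_structure": "boa-body-structure-volume-observation",
    "report": "boa-diagnostic-report",
    "imaging_study": "boa-imaging-study",
}


def profile_canonical(
    key: str, canonical_base: str = config.DEFAULT_CANONICAL_BASE
) -> str:
    return f"{canonical_base}/StructureDefinition/{PROFILE_IDS[key]}"


_IMAGING_CATEGORY = Concept(
    system=config.OBSERVATION_CATEGORY_SYSTEM, code="imaging", display="Imaging"
)


def export_profile_definitions(
    canonical_base: str = config.DEFAULT_CANONICAL_BASE,
    registry: TerminologyRegistry | None = None,
) -> list[ProfileDefinition]:
    """The four shipped profile definitions.

    The read procedure keeps its upstream (MII) canonical and is not
    re-defined here.
    """
    reg = registry or terminology.default_registry()
    volume_panel = reg.aux_concept("body-structure-volume")
    report_code = reg.aux_concept("boa-report")

    bca = ProfileDefinition(
        id=PROFILE_IDS["bca"],
        canonical_url=profile_canonical("bca", canonical_base),
        base_resource="Observation",
        title="Body Composition Analysis Observation",
        constraints=(
            Constraint(path="Observation.status", min=1, max="1", fixed_value="final"),
            Constraint(
                path="Observation.category",
                min=1,
                max="*",
                pattern_concept=_IMAGING_CATEGORY,
            ),
            Constraint(
                path="Observation.code", min=1, max="1", binding=("BCAMeasurementsVS",)
            ),
            Constraint(path="Observation.subject", min=1, max="1", datatype="Reference"),
            Constraint(
                path="Observation.bodySite", min=1, max="1", binding=("BCABodySiteVS",)
            ),
            Constraint(
                path="Observation.derivedFrom", min=1, max="*", datatype="Reference"
            ),
            Constraint(path="Observation.component", min=1, max="*"),
            Constraint(
                path="Observation.component.code",
                min=1,
                max="1",
                binding=("BCATissueVS", terminology.AUX_VALUESET),
            ),
            Constraint(
                path="Observation.component.valueQuantity",
                allowed_ucum=(config.UCUM_ML, config.UCUM_HU),
            ),
            Constraint(
                path="Observation.component.valueRange",
                allowed_ucum=(config.UCUM_UNITY,),
            ),
        ),
    )

    body = ProfileDefinition(
        id=PROFILE_IDS["body_structure"],
        canonical_url=profile_canonical("body_structure", canonical_base),
        base_resource="Observation",
        title="Body Structure Volume Observation",
        constraints=(
            Constraint(path="Observation.status", min=1, max="1", fixed_value="final"),
            Constraint(
                path="Observation.category",
                min=1,
                max="*",
                pattern_concept=_IMAGING_CATEGORY,
            ),
            Constraint(
                path="Observation.code", min=1, max="1", pattern_concept=volume_panel
            ),
            Constraint(path="Observation.subject", min=1, max="1", datatype="Reference"),
            Constraint(
                path="Observation.derivedFrom", min=1, max="*", datatype="Reference"
            ),
            Constraint(
                path="Observation.component",
                min=1,
                max="*",
            ),
            Constraint(
                path="Observation.component.code",
                min=1,
                max="1",
                binding=("BodyStructureLandmarkVS",),
                unique_codings=True,
            ),
            Constraint(
                path="Observation.component.valueQuantity",
                min=1,
                max="1",
                allowed_ucum=(config.UCUM_ML,),
            ),
        ),
    )

    report = ProfileDefinition(
        id=PROFILE_IDS["report"],
        canonical_url=profile_canonical("report", canonical_base),
        base_resource="DiagnosticReport",
        title="BOA Diagnostic Report",
        constraints=(
            Constraint(
                path="DiagnosticReport.status", min=1, max="1", fixed_value="final"
            ),
            Constraint(
                path="DiagnosticReport.identifier",
                min=1,
                max="*",
                fixed_system=config.DICOM_IDENTIFIER_SYSTEM,
                value_grammar="dicom-uid-urn",
            ),
            Constraint(
                path="DiagnosticReport.code",
                min=1,
                max="1",
                pattern_concept=report_code,
            ),
            Constraint(
                path="DiagnosticReport.subject", min=1, max="1", datatype="Reference"
            ),
            Constraint(
                path="DiagnosticReport.imagingStudy",
                min=1,
                max="1",
                datatype="Reference",
            ),
            Constraint(path="DiagnosticReport.result", min=1, max="*"),
            Constraint(
                path="DiagnosticReport.presentedForm.contentType",
                allowed_values=config.SUPPORTED_ATTACHMENT_TYPES,
            ),
        ),
    )

    imaging = ProfileDefinition(
        id=PROFILE_IDS["imaging_study"],
        canonical_url=profile_canonical("imaging_study", canonical_base),
        base_resource="ImagingStudy",
        title="BOA Imaging Study",
        constraints=(
            Constraint(
                path="ImagingStudy.status", min=1, max="1", fixed_value="available"
            ),
            Constraint(
                path="ImagingStudy.identifier",
                min=1,
                max="*",
                fixed_system=config.DICOM_IDENTIFIER_SYSTEM,
                value_grammar="dicom-uid-urn",
            ),
            Constraint(
                path="ImagingStudy.subject", min=1, max="1", datatype="Reference"
            ),
            Constraint(path="ImagingStudy.numberOfSeries", min=1, max="1"),
            Constraint(path="ImagingStudy.series", min=1, max="*"),
            Constraint(
                path="ImagingStudy.series.uid",
                min=1,
                max="1",
                value_grammar="dicom-uid",
            ),
            Constraint(
                path="ImagingStudy.series.modality",
                min=1,
                max="1",
                fixed_system=config.DCM_MODALITY_SYSTEM,
            ),
        ),
    )
    return [bca, body, report, imaging]


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _patient_ref(ctx: BuildContext) -> str:
    if not ctx.patient_reference:
        raise BuildError("BuildContext.patient_reference is not set")
    return ctx.patient_reference


def _require_member(
    reg: TerminologyRegistry, concept: Concept, vs_id: str, path: str
) -> None:
    if not reg.validate_membership(concept, vs_id):
        raise BuildError(
            f"concept ({concept.system}|{concept.code}) is not a member of {vs_id}",
            path,
        )


def _quantity(value: float, code: str, unit: str) -> dict:
    return {"value": value, "unit": unit, "system": config.UCUM, "code": code}


def _assign_id(resource: dict, ctx: BuildContext) -> dict:
    if ctx.id_strategy == "uuid":
        resource["id"] = str(uuid.uuid4())
    else:
        digest = hashlib.sha256(
            json.dumps(resource, sort_keys=True, separators=(",", ":")).encode()
        ).hexdigest()
        resource["id"] = resource["resourceType"].lower() + "-" + digest[:24]
    return resource


def _reference(resource: dict) -> str:
    return f"{resource['resourceType']}/{resource['id']}"


def build_bca_observation(
    region: RegionMeasurement,
    ctx: BuildContext,
    study_ref: str,
    registry: TerminologyRegistry | None = None,
    effective: Optional[str] = None,
) -> dict:
    """Observation for one region's body-composition measurements.

    Components: one millilitre-quantity component per tissue, a paired
    mean-density component (Hounsfield units, tissue coding plus a local
    density-modifier coding) when a density was measured, and an integer
    Range component for the analyzed slice window when present.
    """
    reg = registry or terminology.default_registry()
    _require_member(reg, region.body_site, "BCABodySiteVS", "Observation.bodySite")
    _require_member(reg, region.mode, "BCAMeasurementsVS", "Observation.code")
    components: list[dict] = []
    for i, t in enumerate(region.tissues):
        _require_member(
            reg, t.tissue, "BCATissueVS", f"Observation.component[{i}].code"
        )
        components.append(
            {
                "code": t.tissue.codeable_concept(),
                "valueQuantity": _quantity(t.volume_ml, config.UCUM_ML, "mL"),
            }
        )
        if t.mean_density_hu is not None:
            density_modifier = reg.aux_concept("mean-hu-density")
            components.append(
                {
                    "code": {
                        "coding": [t.tissue.coding(), density_modifier.coding()],
                        "text": f"{t.tissue.display} mean density",
                    },
                    "valueQuantity": _quantity(
                        t.mean_density_hu, config.UCUM_HU, "HU"
                    ),
                }
            )
    if region.slice_range is not None:
        components.append(
            {
                "code": reg.aux_concept("slice-range").codeable_concept(),
                "valueRange": {
                    "low": _quantity(
                        region.slice_range.low, config.UCUM_UNITY, "slice"
                    ),
                    "high": _quantity(
                        region.slice_range.high, config.UCUM_UNITY, "slice"
                    ),
                },
            }
        )
    obs = {
        "resourceType": "Observation",
        "meta": {"profile": [profile_canonical("bca", ctx.canonical_base)]},
        "status": "final",
        "category": [_IMAGING_CATEGORY.codeable_concept()],
        "code": region.mode.codeable_concept(),
        "subject": {"reference": _patient_ref(ctx)},
        "bodySite": region.body_site.codeable_concept(),
        "derivedFrom": [{"reference": study_ref}],
        "component": components,
    }
    if effective is not None:
        obs["effectiveDateTime"] = effective
    return _assign_id(obs, ctx)


def build_body_structure_observation(
    organs: Sequence[OrganVolume],
    ctx: BuildContext,
    study_ref: str,
    registry: TerminologyRegistry | None = None,
    effective: Optional[str] = None,
) -> dict:
    """Single Observation carrying every segmented landmark volume as a
    component (structure CodeableConcept + millilitre Quantity)."""
    reg = registry or terminology.default_registry()
    if not organs:
        raise BuildError("organ volume collection must be non-empty")
    seen: set[tuple[str, str]] = set()
    components = []
    for i, organ in enumerate(organs):
        path = f"Observation.component[{i}].code"
        _require_member(reg, organ.structure, "BodyStructureLandmarkVS", path)
        if organ.structure.key in seen:
            raise BuildError(
                f"duplicate structure concept {organ.structure.code!r}", path
            )
        seen.add(organ.structure.key)
        components.append(
            {
                "code": organ.structure.codeable_concept(),
                "valueQuantity": _quantity(organ.volume_ml, config.UCUM_ML, "mL"),
            }
        )
    obs = {
        "resourceType": "Observation",
        "meta": {
            "profile": [profile_canonical("body_structure", ctx.canonical_base)]
        },
        "status": "final",
        "category": [_IMAGING_CATEGORY.codeable_concept()],
        "code": reg.aux_concept("body-structure-volume").codeable_concept(),
        "subject": {"reference": _patient_ref(ctx)},
        "derivedFrom": [{"reference": study_ref}],
        "component": components,
    }
    if effective is not None:
        obs["effectiveDateTime"] = effective
    return _assign_id(obs, ctx)


def build_imaging_study(result: BOAResult, ctx: BuildContext) -> dict:
    """ImagingStudy restricted to the series the model ran on."""
    if not validate_dicom_uid(result.study_uid):
        raise BuildError(f"invalid study UID: {result.study_uid!r}")
    uids = [s.series_uid for s in result.series]
    if len(set(uids)) != len(uids):
        raise BuildError("series UIDs must be pairwise distinct")
    series_entries = []
    for s in result.series:
        if not validate_dicom_uid(s.series_uid):
            raise BuildError(f"invalid series UID: {s.series_uid!r}")
        entry: dict = {
            "uid": s.series_uid,
            "modality": {
                "system": config.DCM_MODALITY_SYSTEM,
                "code": s.modality,
            },
        }
        if s.number_of_instances is not None:
            entry["numberOfInstances"] = s.number_of_instances
        if s.body_site is not None:
            entry["bodySite"] = s.body_site.coding()
        series_entries.append(entry)
    study = {
        "resourceType": "ImagingStudy",
        "meta": {"profile": [profile_canonical("imaging_study", ctx.canonical_base)]},
        "identifier": [
            {
                "system": config.DICOM_IDENTIFIER_SYSTEM,
                "value": config.DICOM_URN_PREFIX + result.study_uid,
            }
        ],
        "status": "available",
        "subject": {"reference": _patient_ref(ctx)},
        "numberOfSeries": len(series_entries),
        "series": series_entries,
    }
    if result.started is not None:
        study["started"] = result.started
    return _assign_id(study, ctx)


def study_uid_from_identifier(resource: dict) -> Optional[str]:
    """Recover the DICOM study instance UID from a built resource's
    identifier list (``urn:oid:`` value under the ``urn:dicom:uid``
    scheme)."""
    for ident in resource.get("identifier", []):
        if ident.get("system") == config.DICOM_IDENTIFIER_SYSTEM:
            value = ident.get("value", "")
            if value.startswith(config.DICOM_URN_PREFIX):
                return value[len(config.DICOM_URN_PREFIX):]
    return None


def build_diagnostic_report(
    result: BOAResult,
    observation_refs: Sequence[str],
    study_ref: str,
    ctx: BuildContext,
    registry: TerminologyRegistry | None = None,
) -> dict:
    """The aggregating DiagnosticReport: lists every observation, points
    at the ImagingStudy, and carries the rendered reports."""
    reg = registry or terminology.default_registry()
    if not observation_refs:
        raise BuildError("a diagnostic report must aggregate >= 1 observation")
    presented = []
    for i, a in enumerate(result.attachments):
        if a.content_type not in config.SUPPORTED_ATTACHMENT_TYPES:
            raise BuildError(
                f"unsupported attachment MIME {a.content_type!r}",
                f"DiagnosticReport.presentedForm[{i}]",
            )
        form: dict = {"contentType": a.content_type}
        if a.data is not None:
            form["data"] = a.data
        if a.url is not None:
            form["url"] = a.url
        presented.append(form)
    report = {
        "resourceType": "DiagnosticReport",
        "meta": {"profile": [profile_canonical("report", ctx.canonical_base)]},
        "identifier": [
            {
                "system": config.DICOM_IDENTIFIER_SYSTEM,
                "value": config.DICOM_URN_PREFIX + result.study_uid,
            }
        ],
        "status": "final",
        "code": reg.aux_concept("boa-report").codeable_concept(),
        "subject": {"reference": _patient_ref(ctx)},
        "imagingStudy": [{"reference": study_ref}],
        "result": [{"reference": r} for r in observation_refs],
    }
    if result.started is not None:
        report["effectiveDateTime"] = result.started
    if ctx.timestamp is not None:
        report["issued"] = ctx.timestamp
    if presented:
        report["presentedForm"] = presented
    return _assign_id(report, ctx)


def build_read_procedure(
    model: ModelMetadata,
    report_ref: str,
    ctx: BuildContext,
    registry: TerminologyRegistry | None = None,
) -> dict:
    """Procedure documenting the AI model run (MII read-procedure profile
    referenced by canonical URL).  Model name/version/parameters are kept
    as structured ``key=value`` annotations, retrievable verbatim."""
    reg = registry or terminology.default_registry()
    notes = [
        {"text": f"model.name={model.name}"},
        {"text": f"model.version={model.version}"},
    ]
    for key in sorted(model.parameters):
        notes.append({"text": f"parameter.{key}={model.parameters[key]}"})
    procedure = {
        "resourceType": "Procedure",
        "meta": {"profile": [config.MII_PROCEDURE_PROFILE]},
        "status": "completed",
        "code": reg.aux_concept("ai-image-analysis").codeable_concept(),
        "subject": {"reference": _patient_ref(ctx)},
        "report": [{"reference": report_ref}],
        "note": notes,
    }
    if ctx.timestamp is not None:
        procedure["performedDateTime"] = ctx.timestamp
    return _assign_id(procedure, ctx)


def procedure_model_metadata(procedure: dict) -> ModelMetadata:
    """Recover the model metadata stored in a read procedure's notes."""
    name = version = None
    parameters: dict[str, str] = {}
    for note in procedure.get("note", []):
        text = note.get("text", "")
        key, _, value = text.partition("=")
        if key == "model.name":
            name = value
        elif key == "model.version":
            version = value
        elif key.startswith("parameter."):
            parameters[key[len("parameter."):]] = value
    if name is None or version is None:
        raise BuildError("procedure notes do not carry model name/version")
    return ModelMetadata(name=name, version=version, parameters=parameters)


# ---------------------------------------------------------------------------
# AI provenance
# ---------------------------------------------------------------------------


def tag_ai_provenance(resource: dict) -> dict:
    """Return a copy with the ``AIAST`` security label in ``meta.security``.

    Idempotent — a second application adds nothing — and local: nothing
    outside ``meta`` is touched.
    """
    tagged = copy.deepcopy(resource)
    meta = tagged.setdefault("meta", {})
    security = meta.setdefault("security", [])
    for tag in security:
        if (
            tag.get("system") == config.SECURITY_SYSTEM
            and tag.get("code") == config.AIAST_CODE
        ):
            return tagged
    security.append(
        {
            "system": config.SECURITY_SYSTEM,
            "code": config.AIAST_CODE,
            "display": config.AIAST_DISPLAY,
        }
    )
    return tagged


def has_aiast_tag(resource: dict) -> bool:
    return any(
        tag.get("system") == config.SECURITY_SYSTEM
        and tag.get("code") == config.AIAST_CODE
        for tag in resource.get("meta", {}).get("security", [])
    )


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------


def assemble_bundle(
    result: BOAResult,
    ctx: BuildContext | None = None,
    registry: TerminologyRegistry | None = None,
) -> dict:
    """Build the full transaction Bundle for one analysis result.

    Entry order: ImagingStudy, one body-composition Observation per
    region, the body-structure volume Observation (when organs are
    present), the DiagnosticReport, the read Procedure.  Every resource
    carries the AIAST tag; every internal reference resolves within the
    bundle.
    """
    ctx = ctx or BuildContext()
    if not ctx.patient_reference:
        ctx = dataclasses.replace(
            ctx, patient_reference=f"Patient/{result.patient_id}"
        )
    reg = registry or terminology.default_registry()

    study = tag_ai_provenance(build_imaging_study(result, ctx))
    study_ref = _reference(study)

    observations = []
    for i, region in enumerate(result.regions):
        try:
            obs = build_bca_observation(
                region, ctx, study_ref, reg, effective=result.started
            )
        except BuildError as exc:
            raise BuildError(
                f"BCA Observation for region {i}: {exc}", exc.path
            ) from exc
        observations.append(tag_ai_provenance(obs))
    if result.organs:
        observations.append(
            tag_ai_provenance(
                build_body_structure_observation(
                    result.organs, ctx, study_ref, reg, effective=result.started
                )
            )
        )
    if not observations:
        raise BuildError("result yields no observations")

    report = tag_ai_provenance(
        build_diagnostic_report(
            result, [_reference(o) for o in observations], study_ref, ctx, reg
        )
    )
    procedure = tag_ai_provenance(
        build_read_procedure(result.model, _reference(report), ctx, reg)
    )

    entries = [study, *observations, report, procedure]
    return {
        "resourceType": "Bundle",
        "type": "transaction",
        "entry": [
            {
                "fullUrl": f"{ctx.canonical_base}/{_reference(r)}",
                "resource": r,
                "request": {"method": "PUT", "url": _reference(r)},
            }
            for r in entries
        ],
    }


def bundle_to_ndjson(bundle: dict) -> str:
    """One resource per line (NDJSON), in bundle entry order."""
    return "\n".join(
        json.dumps(e["resource"], separators=(",", ":"), ensure_ascii=False)
        for e in bundle.get("entry", [])
    )
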