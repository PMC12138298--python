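"""Shared constants: code-system URIs, UCUM codes, canonical URL defaults.

Everything here is a deployment default.  Sites publishing the profiles
under their own base URL, or swapping in updated terminology releases,
override these via :class:`boafhir.terminology.TerminologyRegistry` /
:class:`boafhir.profile_builder.BuildContext` arguments rather than by
editing this module.
"""

from __future__ import annotations

import logging

# Canonical base under which the BOA profiles and local code system live.
DEFAULT_CANONICAL_BASE = "https://example.org/fhir/boa"

# Terminology systems.  SNOMED CT carries body sites and well-known organ
# structures, RadLex imaging-specific terms; labels with no standard code
# (BCA pseudo-tissues, measurement modes, most segmentation landmarks) use
# the project-local system.
SNOMED_CT = "http://snomed.info/sct"
RADLEX = "http://radlex.org"
LOCAL_SYSTEM = DEFAULT_CANONICAL_BASE + "/CodeSystem/boa"

#: Short keys used in the value-set data tables, mapped to full URIs.
SYSTEM_KEYS = {"sct": SNOMED_CT, "radlex": RADLEX, "local": LOCAL_SYSTEM}

#: Resolution priority when a label maps to concepts in several systems.
SYSTEM_PRIORITY = (SNOMED_CT, RADLEX, LOCAL_SYSTEM)

# Units (UCUM).
UCUM = "http://unitsofmeasure.org"
UCUM_ML = "mL"  # millilitre — all volumes
UCUM_HU = "[hnsf'U]"  # Hounsfield unit — all CT densities
UCUM_UNITY = "1"  # dimensionless — slice indices

# DICOM linkage.
DICOM_IDENTIFIER_SYSTEM = "urn:dicom:uid"
DICOM_URN_PREFIX = "urn:oid:"
DCM_MODALITY_SYSTEM = "http://dicom.nema.org/resources/ontology/DCM"

# AI provenance: HL7 v3 ObservationValue security label "AIAST".
SECURITY_SYSTEM = "http://terminology.hl7.org/CodeSystem/v3-ObservationValue"
AIAST_CODE = "AIAST"
AIAST_DISPLAY = "Artificial Intelligence Asserted"

OBSERVATION_CATEGORY_SYSTEM = (
    "http://terminology.hl7.org/CodeSystem/observation-category"
)

# The Medical Informatics Initiative (MII) procedure profile is referenced
# by canonical URL only; its constraint set is not re-defined here.
MII_PROCEDURE_PROFILE = (
    "https://www.medizininformatik-initiative.de/fhir/core/modul-prozedur/"
    "StructureDefinition/Procedure"
)

SUPPORTED_ATTACHMENT_TYPES = (
    "application/pdf",
    "application/json",
    "application/vnd.openxmlformats-officedocument.spreadsheetml.sheet",
)


def get_logger(name: str) -> logging.Logger:
    return logging.getLogger("boafhir." + name)


def configure_logging(level: str = "INFO") -> None:
    """Configure stderr logging for CLI use (library code never calls this)."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("boafhir")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())
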