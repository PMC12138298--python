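"""Value sets and label-to-code mapping for body-composition profiling.

Five value sets ship with the package as editable TSV tables
(``data/*.tsv``; columns ``display / system / code / synonyms``):

* ``BCABodySiteVS`` — the 4 cavities a body-composition observation is
  anchored to (SNOMED CT body structures).
* ``BCAMeasurementsVS`` — the 2 measurement modes (with / without
  extremities).
* ``BCATissueVS`` — the 8 tissue compartments quantified per region.
* ``BCARegionVS`` — the 8 body regions the analysis covers.
* ``BodyStructureLandmarkVS`` — the 104 whole-body segmentation landmarks
  whose volumes are reported.

Codes come from SNOMED CT where a well-established concept exists and from
a project-local code system otherwise; the tables are data, not code, and
can be replaced wholesale when terminology releases evolve.
"""

from __future__ import annotations

import csv
import re
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, field_validator

from . import config

__all__ = [
    "Concept",
    "ValueSet",
    "TerminologyError",
    "UnknownValueSetError",
    "UnmappedLabelError",
    "TerminologyRegistry",
    "default_registry",
    "valueset_members",
    "lookup_concept",
    "validate_membership",
    "to_fhir_valueset",
    "SHIPPED_VALUESETS",
]

SHIPPED_VALUESETS = (
    "BCAMeasurementsVS",
    "BCABodySiteVS",
    "BodyStructureLandmarkVS",
    "BCATissueVS",
    "BCARegionVS",
)

#: Auxiliary concepts used as component codes in built observations
#: (slice-range marker, density modifier, panel codes).  Registered as an
#: internal value set so binding checks can be expressed uniformly.
AUX_VALUESET = "BOAComponentAuxVS"


class TerminologyError(Exception):
    """Base class for terminology failures."""


class UnknownValueSetError(TerminologyError, KeyError):
    def __init__(self, valueset_id: str):
        super().__init__(f"unknown value set: {valueset_id!r}")
        self.valueset_id = valueset_id


class UnmappedLabelError(TerminologyError, KeyError):
    def __init__(self, label: str):
        super().__init__(f"unmapped label: {label!r}")
        self.label = label


class Concept(BaseModel):
    """A terminology triple (code system URI, code, display label)."""

    model_config = ConfigDict(frozen=True)

    system: str
    code: str
    display: str

    @field_validator("system", "display")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("must be non-empty")
        return v

    @field_validator("code")
    @classmethod
    def _token(cls, v: str) -> str:
        if not v or re.search(r"\s", v):
            raise ValueError("code must be non-empty without whitespace")
        return v

    @property
    def key(self) -> tuple[str, str]:
        return (self.system, self.code)

    def coding(self) -> dict:
        """FHIR Coding JSON for this concept."""
        return {"system": self.system, "code": self.code, "display": self.display}

    def codeable_concept(self) -> dict:
        """FHIR CodeableConcept JSON with this concept as sole coding."""
        return {"coding": [self.coding()], "text": self.display}


class ValueSet(BaseModel):
    id: str
    title: str
    concepts: tuple[Concept, ...]

    @field_validator("concepts")
    @classmethod
    def _unique(cls, v: tuple[Concept, ...]) -> tuple[Concept, ...]:
        keys = [c.key for c in v]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (system, code) pair in value set")
        return v


def _norm(label: str) -> str:
    """Case/whitespace-insensitive label normalization; underscores and
    hyphens are treated as word separators so snake_case class names match."""
    return re.sub(r"[\s_\-]+", " ", label).strip().casefold()


class TerminologyRegistry:
    """Holds value sets and a label index for code resolution.

    A fresh registry loads the shipped tables; alternative tables (other
    terminology releases, other system URIs) can be loaded over them.
    """

    def __init__(
        self,
        system_keys: Mapping[str, str] | None = None,
        system_priority: Sequence[str] | None = None,
        load_shipped: bool = True,
    ):
        self.system_keys = dict(system_keys or config.SYSTEM_KEYS)
        self.system_priority = tuple(system_priority or config.SYSTEM_PRIORITY)
        self._valuesets: dict[str, ValueSet] = {}
        # normalized label -> ordered concepts (registration order)
        self._index: dict[str, list[tuple[Concept, str]]] = {}
        if load_shipped:
            for vs_id in SHIPPED_VALUESETS:
                with resources.files("boafhir.data").joinpath(
                    vs_id + ".tsv"
                ).open("r", encoding="utf-8") as fh:
                    self.load_table(fh, vs_id)
            self._register_aux()

    # -- registration ------------------------------------------------------

    def register_valueset(self, vs: ValueSet) -> None:
        for c in vs.concepts:
            if c.system not in self.system_keys.values():
                raise TerminologyError(
                    f"concept system not configured: {c.system!r}"
                )
        self._valuesets[vs.id] = vs
        for c in vs.concepts:
            self._index_concept(c, vs.id, c.display)

    def _index_concept(self, c: Concept, vs_id: str, *labels: str) -> None:
        for label in labels:
            entry = self._index.setdefault(_norm(label), [])
            if (c, vs_id) not in entry:
                entry.append((c, vs_id))

    def load_table(self, fh: Iterable[str], valueset_id: str, title: str | None = None) -> ValueSet:
        """Load a value set from a delimited table with columns
        display / system / code / synonyms (synonyms ``|``-separated;
        system is a short key such as ``sct`` or a full URI)."""
        reader = csv.DictReader(fh, delimiter="\t")
        concepts, synonyms = [], []
        for row in reader:
            system = self.system_keys.get(row["system"], row["system"])
            c = Concept(system=system, code=row["code"], display=row["display"])
            concepts.append(c)
            synonyms.append(
                [s for s in (row.get("synonyms") or "").split("|") if s]
            )
        vs = ValueSet(
            id=valueset_id, title=title or valueset_id, concepts=tuple(concepts)
        )
        self.register_valueset(vs)
        for c, syns in zip(concepts, synonyms):
            self._index_concept(c, valueset_id, *syns)
        return vs

    def _register_aux(self) -> None:
        local = self.system_keys["local"]
        aux = ValueSet(
            id=AUX_VALUESET,
            title="Auxiliary component codes",
            concepts=(
                Concept(system=local, code="slice-range", display="slice range"),
                Concept(
                    system=local,
                    code="mean-hu-density",
                    display="mean Hounsfield density",
                ),
                Concept(
                    system=local,
                    code="body-structure-volume",
                    display="body structure volume",
                ),
                Concept(
                    system=local,
                    code="boa-report",
                    display="Body and Organ Analysis report",
                ),
                Concept(
                    system=local,
                    code="ai-image-analysis",
                    display="AI image analysis procedure",
                ),
            ),
        )
        self.register_valueset(aux)

    # -- queries -----------------------------------------------------------

    def valueset(self, valueset_id: str) -> ValueSet:
        try:
            return self._valuesets[valueset_id]
        except KeyError:
            raise UnknownValueSetError(valueset_id) from None

    def valueset_members(self, valueset_id: str) -> tuple[Concept, ...]:
        """Full concept list of a value set, in stable table order."""
        return self.valueset(valueset_id).concepts

    def lookup_concept(
        self, label: str, preferred_system: Optional[str] = None
    ) -> Concept:
        """Resolve a display label or synonym to a concept.

        Matching is case-insensitive and whitespace-normalized.  When the
        label maps into several code systems, ``preferred_system`` wins if
        it has a match, otherwise the configured priority order
        (SNOMED CT > RadLex > local) decides.
        """
        if not label or not label.strip():
            raise UnmappedLabelError(label)
        entries = self._index.get(_norm(label))
        if not entries:
            raise UnmappedLabelError(label)
        candidates = [c for c, _ in entries]
        if preferred_system is not None:
            for c in candidates:
                if c.system == preferred_system:
                    return c
        for system in self.system_priority:
            for c in candidates:
                if c.system == system:
                    return c
        return candidates[0]

    def validate_membership(self, concept: Concept, valueset_id: str) -> bool:
        """True iff the (system, code) pair is in the set; display is not
        consulted."""
        vs = self.valueset(valueset_id)
        return any(concept.key == m.key for m in vs.concepts)

    def home_valuesets(self, concept: Concept) -> tuple[str, ...]:
        """Ids of the registered value sets containing the concept."""
        return tuple(
            vs_id
            for vs_id, vs in self._valuesets.items()
            if any(concept.key == m.key for m in vs.concepts)
        )

    def aux_concept(self, code: str) -> Concept:
        for c in self.valueset(AUX_VALUESET).concepts:
            if c.code == code:
                return c
        raise UnmappedLabelError(code)

    # -- export ------------------------------------------------------------

    def to_fhir_valueset(
        self, valueset_id: str, canonical_base: str = config.DEFAULT_CANONICAL_BASE
    ) -> dict:
        """Serialize a value set as FHIR R4 ValueSet JSON (extensional)."""
        vs = self.valueset(valueset_id)
        by_system: dict[str, list[Concept]] = {}
        for c in vs.concepts:
            by_system.setdefault(c.system, []).append(c)
        return {
            "resourceType": "ValueSet",
            "id": vs.id,
            "url": f"{canonical_base}/ValueSet/{vs.id}",
            "name": vs.id,
            "title": vs.title,
            "status": "active",
            "compose": {
                "include": [
                    {
                        "system": system,
                        "concept": [
                            {"code": c.code, "display": c.display}
                            for c in concepts
                        ],
                    }
                    for system, concepts in by_system.items()
                ]
            },
        }


_default_registry: TerminologyRegistry | None = None


def default_registry() -> TerminologyRegistry:
    """Process-wide registry loaded with the shipped tables (lazy)."""
    global _default_registry
    if _default_registry is None:
        _default_registry = TerminologyRegistry()
    return _default_registry


def valueset_members(valueset_id: str) -> tuple[Concept, ...]:
    return default_registry().valueset_members(valueset_id)


def lookup_concept(label: str, preferred_system: Optional[str] = None) -> Concept:
    return default_registry().lookup_concept(label, preferred_system)


def validate_membership(concept: Concept, valueset_id: str) -> bool:
    return default_registry().validate_membership(concept, valueset_id)


def to_fhir_valueset(
    valueset_id: str, canonical_base: str = config.DEFAULT_CANONICAL_BASE
) -> dict:
    return default_registry().to_fhir_valueset(valueset_id, canonical_base)
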