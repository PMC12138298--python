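"""Input data model for one AI body-and-organ analysis of a CT study.

A :class:`BOAResult` captures everything one analysis run produces:
which patient and DICOM study/series were analyzed, per-region tissue
volumes and densities, per-landmark organ volumes, the model metadata,
and optional rendered report attachments.  The JSON form of this model is
the canonical input document of the package
(:func:`boa_result_json_schema` emits its JSON Schema); coded fields
travel as display labels and are resolved through the terminology tables
on parse.

:func:`generate_synthetic_result` produces seeded, fully valid synthetic
results so the builder/validator/extraction pipeline is testable without
any real imaging data.  Its defaults emulate the full analysis output:
all 4 body sites x 2 measurement modes, all 8 tissues per region, and all
104 segmentation landmarks.  Value ranges are plausible-only defaults,
not clinically validated distributions.
"""

from __future__ import annotations

import datetime as _dt
import io
import json
import re
from typing import Any, Optional

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

from . import config, terminology
from .terminology import Concept, TerminologyRegistry, UnmappedLabelError

__all__ = [
    "SliceRange",
    "TissueMeasurement",
    "RegionMeasurement",
    "OrganVolume",
    "SeriesInfo",
    "ModelMetadata",
    "Attachment",
    "BOAResult",
    "GenerationConfig",
    "ParseError",
    "validate_dicom_uid",
    "parse_boa_result",
    "serialize_boa_result",
    "result_to_json",
    "generate_synthetic_result",
    "boa_result_json_schema",
]

log = config.get_logger("boa_model")

# ---------------------------------------------------------------------------
# DICOM UID grammar
# ---------------------------------------------------------------------------

# Dotted-decimal: components non-empty, digits only, no leading zero unless
# the component is exactly "0"; total length at most 64 characters.
_UID_RE = re.compile(r"(0|[1-9][0-9]*)(\.(0|[1-9][0-9]*))*")


def validate_dicom_uid(text: str) -> bool:
    """True iff *text* is a well-formed dotted-decimal DICOM UID."""
    return (
        isinstance(text, str)
        and 0 < len(text) <= 64
        and _UID_RE.fullmatch(text) is not None
    )


_INSTANT_RE = re.compile(
    r"\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}(\.\d+)?(Z|[+-]\d{2}:\d{2})"
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class SliceRange(BaseModel):
    """1-based inclusive slice-index window (DICOM InstanceNumber positions
    within the referenced series)."""

    model_config = ConfigDict(frozen=True)

    low: int = Field(ge=1)
    high: int = Field(ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "SliceRange":
        if self.low > self.high:
            raise ValueError("slice range requires low <= high")
        return self


class TissueMeasurement(BaseModel):
    tissue: Concept
    volume_ml: float = Field(ge=0, description="tissue volume, millilitres")
    mean_density_hu: Optional[float] = Field(
        default=None, ge=-1024, le=3071, description="mean CT density, HU"
    )


class RegionMeasurement(BaseModel):
    body_site: Concept
    mode: Concept
    slice_range: Optional[SliceRange] = None
    tissues: list[TissueMeasurement] = Field(min_length=1)

    @field_validator("tissues")
    @classmethod
    def _distinct_tissues(cls, v: list[TissueMeasurement]) -> list[TissueMeasurement]:
        keys = [t.tissue.key for t in v]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate tissue concept in region")
        return v


class OrganVolume(BaseModel):
    structure: Concept
    volume_ml: float = Field(ge=0, description="structure volume, millilitres")


class SeriesInfo(BaseModel):
    series_uid: str
    modality: str = "CT"
    number_of_instances: Optional[int] = Field(default=None, gt=0)
    body_site: Optional[Concept] = None

    @field_validator("series_uid")
    @classmethod
    def _uid(cls, v: str) -> str:
        if not validate_dicom_uid(v):
            raise ValueError(f"invalid DICOM UID: {v!r}")
        return v


class ModelMetadata(BaseModel):
    name: str = Field(min_length=1)
    version: str = Field(min_length=1)
    parameters: dict[str, str] = Field(default_factory=dict)

    @field_validator("name", "version")
    @classmethod
    def _non_blank(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("must be non-empty")
        return v


class Attachment(BaseModel):
    """Rendered report in one of the three supported formats, carried
    either inline (base64) or by URL — exactly one of the two."""

    content_type: str
    data: Optional[str] = None
    url: Optional[str] = None

    @field_validator("content_type")
    @classmethod
    def _supported(cls, v: str) -> str:
        if v not in config.SUPPORTED_ATTACHMENT_TYPES:
            raise ValueError(f"unsupported attachment content type: {v!r}")
        return v

    @model_validator(mode="after")
    def _exactly_one(self) -> "Attachment":
        if (self.data is None) == (self.url is None):
            raise ValueError("attachment requires exactly one of data/url")
        return self


class BOAResult(BaseModel):
    """Complete output of one AI analysis of one CT study."""

    patient_id: str = Field(min_length=1)
    study_uid: str
    series: list[SeriesInfo] = Field(min_length=1)
    started: Optional[str] = Field(
        default=None, description="analysis start, ISO-8601 instant"
    )
    regions: list[RegionMeasurement] = Field(default_factory=list)
    organs: list[OrganVolume] = Field(default_factory=list)
    model: ModelMetadata
    attachments: list[Attachment] = Field(default_factory=list)

    @field_validator("study_uid")
    @classmethod
    def _uid(cls, v: str) -> str:
        if not validate_dicom_uid(v):
            raise ValueError(f"invalid DICOM UID: {v!r}")
        return v

    @field_validator("started")
    @classmethod
    def _instant(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and not _INSTANT_RE.fullmatch(v):
            raise ValueError(f"not an ISO-8601 instant: {v!r}")
        return v

    @model_validator(mode="after")
    def _invariants(self) -> "BOAResult":
        uids = [s.series_uid for s in self.series]
        if len(set(uids)) != len(uids):
            raise ValueError("series UIDs must be pairwise distinct")
        if not self.regions and not self.organs:
            raise ValueError("at least one of regions/organs must be non-empty")
        return self


# ---------------------------------------------------------------------------
# Parse / serialize (canonical JSON document)
# ---------------------------------------------------------------------------


class ParseError(ValueError):
    """Structured parse failure naming the JSON path of the offence."""

    def __init__(self, path: str, message: str):
        super().__init__(f"{path}: {message}")
        self.path = path
        self.message = message


_KNOWN_KEYS = frozenset(
    [
        "patient_id",
        "study_uid",
        "series",
        "started",
        "regions",
        "organs",
        "model",
        "attachments",
    ]
)


def _resolve(
    reg: TerminologyRegistry, label: Any, valueset_id: str, path: str
) -> Concept:
    if not isinstance(label, str):
        raise ParseError(path, f"expected a label string, got {type(label).__name__}")
    try:
        concept = reg.lookup_concept(label)
    except UnmappedLabelError:
        raise ParseError(path, f"unmapped label: {label!r}") from None
    if not reg.validate_membership(concept, valueset_id):
        raise ParseError(
            path, f"label {label!r} resolves outside value set {valueset_id}"
        )
    return concept


def parse_boa_result(
    source: str | bytes | dict | io.IOBase,
    registry: TerminologyRegistry | None = None,
) -> BOAResult:
    """Parse the canonical analysis-result JSON document.

    Coded fields are given as display labels (or registered synonyms) and
    resolved through the terminology registry; membership in the expected
    value set is enforced.  Unknown top-level keys are ignored with a
    logged warning.  Any violation raises :class:`ParseError` carrying a
    JSONPath-style location.
    """
    reg = registry or terminology.default_registry()
    if isinstance(source, (str, bytes)):
        try:
            doc = json.loads(source)
        except json.JSONDecodeError as exc:
            raise ParseError("$", f"malformed JSON: {exc}") from None
    elif isinstance(source, dict):
        doc = source
    else:
        try:
            doc = json.load(source)
        except json.JSONDecodeError as exc:
            raise ParseError("$", f"malformed JSON: {exc}") from None
    if not isinstance(doc, dict):
        raise ParseError("$", "document root must be a JSON object")

    for key in sorted(set(doc) - _KNOWN_KEYS):
        log.warning("ignoring unknown top-level key %r", key)

    def require(obj: dict, key: str, path: str) -> Any:
        if key not in obj:
            raise ParseError(f"{path}.{key}", "missing required field")
        return obj[key]

    kwargs: dict[str, Any] = {
        "patient_id": require(doc, "patient_id", "$"),
        "study_uid": require(doc, "study_uid", "$"),
        "started": doc.get("started"),
    }

    series = []
    raw_series = require(doc, "series", "$")
    if not isinstance(raw_series, list):
        raise ParseError("$.series", "must be an array")
    for i, s in enumerate(raw_series):
        path = f"$.series[{i}]"
        body_site = s.get("body_site")
        series.append(
            {
                "series_uid": require(s, "series_uid", path),
                "modality": s.get("modality", "CT"),
                "number_of_instances": s.get("number_of_instances"),
                "body_site": _resolve(
                    reg, body_site, "BCABodySiteVS", f"{path}.body_site"
                )
                if body_site is not None
                else None,
            }
        )
    kwargs["series"] = series

    regions = []
    for i, r in enumerate(doc.get("regions") or []):
        path = f"$.regions[{i}]"
        tissues = []
        for j, t in enumerate(r.get("tissues") or []):
            tpath = f"{path}.tissues[{j}]"
            tissues.append(
                {
                    "tissue": _resolve(
                        reg,
                        require(t, "tissue", tpath),
                        "BCATissueVS",
                        f"{tpath}.tissue",
                    ),
                    "volume_ml": require(t, "volume_ml", tpath),
                    "mean_density_hu": t.get("mean_density_hu"),
                }
            )
        regions.append(
            {
                "body_site": _resolve(
                    reg,
                    require(r, "body_site", path),
                    "BCABodySiteVS",
                    f"{path}.body_site",
                ),
                "mode": _resolve(
                    reg, require(r, "mode", path), "BCAMeasurementsVS", f"{path}.mode"
                ),
                "slice_range": r.get("slice_range"),
                "tissues": tissues,
            }
        )
    kwargs["regions"] = regions

    organs = []
    for i, o in enumerate(doc.get("organs") or []):
        path = f"$.organs[{i}]"
        organs.append(
            {
                "structure": _resolve(
                    reg,
                    require(o, "structure", path),
                    "BodyStructureLandmarkVS",
                    f"{path}.structure",
                ),
                "volume_ml": require(o, "volume_ml", path),
            }
        )
    kwargs["organs"] = organs
    kwargs["model"] = require(doc, "model", "$")
    kwargs["attachments"] = doc.get("attachments") or []

    try:
        return BOAResult(**kwargs)
    except ValidationError as exc:
        err = exc.errors()[0]
        loc = "$." + ".".join(str(p) for p in err["loc"]) if err["loc"] else "$"
        raise ParseError(loc, err["msg"]) from None


def serialize_boa_result(result: BOAResult) -> dict:
    """Canonical JSON-ready dict; coded fields as display labels.

    Inverse of :func:`parse_boa_result` on every result whose concepts are
    resolvable by display (true of all shipped tables).
    """
    doc: dict[str, Any] = {
        "patient_id": result.patient_id,
        "study_uid": result.study_uid,
        "series": [
            {
                k: v
                for k, v in {
                    "series_uid": s.series_uid,
                    "modality": s.modality,
                    "number_of_instances": s.number_of_instances,
                    "body_site": s.body_site.display if s.body_site else None,
                }.items()
                if v is not None
            }
            for s in result.series
        ],
    }
    if result.started is not None:
        doc["started"] = result.started
    doc["regions"] = [
        {
            k: v
            for k, v in {
                "body_site": r.body_site.display,
                "mode": r.mode.display,
                "slice_range": (
                    {"low": r.slice_range.low, "high": r.slice_range.high}
                    if r.slice_range
                    else None
                ),
                "tissues": [
                    {
                        k2: v2
                        for k2, v2 in {
                            "tissue": t.tissue.display,
                            "volume_ml": t.volume_ml,
                            "mean_density_hu": t.mean_density_hu,
                        }.items()
                        if v2 is not None
                    }
                    for t in r.tissues
                ],
            }.items()
            if v is not None
        }
        for r in result.regions
    ]
    doc["organs"] = [
        {"structure": o.structure.display, "volume_ml": o.volume_ml}
        for o in result.organs
    ]
    doc["model"] = {
        "name": result.model.name,
        "version": result.model.version,
        "parameters": dict(result.model.parameters),
    }
    doc["attachments"] = [
        {
            k: v
            for k, v in {
                "content_type": a.content_type,
                "data": a.data,
                "url": a.url,
            }.items()
            if v is not None
        }
        for a in result.attachments
    ]
    return doc


def result_to_json(result: BOAResult) -> str:
    """Deterministic JSON text of the canonical document."""
    return json.dumps(
        serialize_boa_result(result),
        sort_keys=True,
        separators=(",", ":"),
        ensure_ascii=False,
    )


def boa_result_json_schema() -> dict:
    """JSON Schema of the in-memory model (concepts appear expanded; the
    canonical wire document carries display labels instead)."""
    return BOAResult.model_json_schema()


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


class GenerationConfig(BaseModel):
    """Knobs of the synthetic-result generator.

    Defaults emulate one complete analysis: every body site in both
    measurement modes (8 region measurements), all 8 tissues per region,
    all 104 landmarks.  Value ranges are plausible clinical magnitudes
    only — they make fixtures realistic, they are not validated
    distributions.
    """

    n_regions: Optional[int] = Field(
        default=None, ge=0, description="None = all sites x modes (8)"
    )
    n_organs: Optional[int] = Field(
        default=None, ge=0, description="None = all 104 landmarks"
    )
    n_series: int = Field(default=1, ge=1)
    include_slice_ranges: bool = True
    include_densities: bool = True
    include_attachments: bool = True
    organ_volume_ml: tuple[float, float] = (10.0, 2000.0)
    tissue_volume_ml: tuple[float, float] = (50.0, 8000.0)
    muscle_density_hu: tuple[float, float] = (20.0, 60.0)
    adipose_density_hu: tuple[float, float] = (-150.0, -50.0)
    bone_density_hu: tuple[float, float] = (150.0, 1200.0)
    max_slice: int = Field(default=512, ge=2)

    @model_validator(mode="after")
    def _consistent(self) -> "GenerationConfig":
        for name in (
            "organ_volume_ml",
            "tissue_volume_ml",
            "muscle_density_hu",
            "adipose_density_hu",
            "bone_density_hu",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min > max")
        return self


def _density_range(cfg: GenerationConfig, tissue_display: str) -> tuple[float, float]:
    if "adipose" in tissue_display:
        return cfg.adipose_density_hu
    if "bone" in tissue_display:
        return cfg.bone_density_hu
    return cfg.muscle_density_hu


def _make_uid(rng, root: str = "1.2.826.0.1.3680043.9.7420") -> str:
    """Deterministic, well-formed study/series UID under a test root."""
    uid = f"{root}.{rng.randint(1, 10**6)}.{rng.randint(1, 10**9)}"
    assert validate_dicom_uid(uid)
    return uid


def generate_synthetic_result(
    seed: int,
    gen_config: GenerationConfig | None = None,
    registry: TerminologyRegistry | None = None,
) -> BOAResult:
    """Generate one seeded synthetic analysis result.

    Deterministic: a fixed (seed, config) pair yields a byte-identical
    serialized document.  Regions, tissues and organs are emitted in
    display-sorted order — the same canonical order extraction uses — so
    the full generate/build/extract/rebuild loop is exactly idempotent.
    """
    import random

    cfg = gen_config or GenerationConfig()
    reg = registry or terminology.default_registry()
    rng = random.Random(seed)

    sites = sorted(reg.valueset_members("BCABodySiteVS"), key=lambda c: c.display)
    modes = sorted(reg.valueset_members("BCAMeasurementsVS"), key=lambda c: c.display)
    tissues = sorted(reg.valueset_members("BCATissueVS"), key=lambda c: c.display)
    landmarks = sorted(
        reg.valueset_members("BodyStructureLandmarkVS"), key=lambda c: c.display
    )

    pairs = [(s, m) for s in sites for m in modes]
    n_regions = len(pairs) if cfg.n_regions is None else cfg.n_regions
    n_organs = len(landmarks) if cfg.n_organs is None else cfg.n_organs
    if n_regions > len(pairs):
        raise ValueError(f"n_regions > {len(pairs)} available site/mode pairs")
    if n_organs > len(landmarks):
        raise ValueError(f"n_organs > {len(landmarks)} available landmarks")
    if n_regions == 0 and n_organs == 0:
        raise ValueError("config yields neither regions nor organs")

    regions = []
    for site, mode in pairs[:n_regions]:
        slice_range = None
        if cfg.include_slice_ranges:
            low = rng.randint(1, cfg.max_slice - 1)
            high = rng.randint(low, cfg.max_slice)
            slice_range = SliceRange(low=low, high=high)
        tms = []
        for t in tissues:
            dens = None
            if cfg.include_densities:
                dens = round(rng.uniform(*_density_range(cfg, t.display)), 1)
            tms.append(
                TissueMeasurement(
                    tissue=t,
                    volume_ml=round(rng.uniform(*cfg.tissue_volume_ml), 2),
                    mean_density_hu=dens,
                )
            )
        regions.append(
            RegionMeasurement(
                body_site=site, mode=mode, slice_range=slice_range, tissues=tms
            )
        )

    organs = [
        OrganVolume(
            structure=lm, volume_ml=round(rng.uniform(*cfg.organ_volume_ml), 2)
        )
        for lm in landmarks[:n_organs]
    ]

    started = (
        _dt.datetime(2024, 1, 1, tzinfo=_dt.timezone.utc)
        + _dt.timedelta(minutes=rng.randint(0, 525_600))
    ).strftime("%Y-%m-%dT%H:%M:%SZ")

    attachments = []
    if cfg.include_attachments:
        import base64

        payload = base64.b64encode(
            json.dumps({"synthetic": True, "seed": seed}).encode()
        ).decode()
        attachments = [
            Attachment(content_type="application/json", data=payload),
            Attachment(content_type="application/pdf", data=payload),
        ]

    return BOAResult(
        patient_id=f"synthetic-patient-{rng.randint(10**5, 10**6 - 1)}",
        study_uid=_make_uid(rng),
        series=[
            SeriesInfo(
                series_uid=_make_uid(rng),
                modality="CT",
                number_of_instances=rng.randint(40, 900),
            )
            for _ in range(cfg.n_series)
        ],
        started=started,
        regions=regions,
        organs=organs,
        model=ModelMetadata(
            name="BOA",
            version="1.0",
            parameters={"device": "gpu", "window": "abdomen"},
        ),
        attachments=attachments,
    )
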