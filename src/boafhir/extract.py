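"""Inverse transform: a conformant analysis bundle back to tidy rows.

One :class:`MeasurementRow` per (region, tissue) component pair and one
per landmark component — the data contract a longitudinal dashboard or
cohort analysis would consume.  Extraction refuses non-conformant
bundles outright (pointing at the validator output) rather than emitting
partial tables, and is exact: every volume, density, slice bound and
code round-trips bit-for-bit through the CSV form.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, fields as dataclass_fields
from typing import Optional, Sequence

import pandas as pd

from . import config, terminology
from .boa_model import (
    Attachment,
    BOAResult,
    ModelMetadata,
    OrganVolume,
    RegionMeasurement,
    SeriesInfo,
    SliceRange,
    TissueMeasurement,
)
from .profile_builder import (
    profile_canonical,
    study_uid_from_identifier,
)
from .terminology import Concept, TerminologyRegistry
from .validator import Issue, validate_bundle

__all__ = [
    "MeasurementRow",
    "BundleNotConformantError",
    "extract_measurements",
    "rows_to_dataframe",
    "write_csv",
    "read_csv",
    "result_from_rows",
    "CSV_HEADER",
]


class BundleNotConformantError(ValueError):
    """Raised when extraction is attempted on a bundle with validation
    errors; carries the validator's findings."""

    def __init__(self, issues: Sequence[Issue]):
        errors = [i for i in issues if i.severity == "error"]
        super().__init__(
            f"bundle has {len(errors)} validation error(s); "
            "first: " + (f"[{errors[0].rule_id}] {errors[0].path}" if errors else "-")
        )
        self.issues = list(issues)


@dataclass(frozen=True)
class MeasurementRow:
    """One measurement in tidy form.

    ``kind`` is ``region-tissue`` (body-site/mode/tissue columns
    populated) or ``organ`` (structure columns populated); columns of the
    other kind stay empty.
    """

    patient_id: str
    study_uid: str
    date: Optional[str]
    kind: str  # "region-tissue" | "organ"
    body_site_display: Optional[str] = None
    body_site_code: Optional[str] = None
    body_site_system: Optional[str] = None
    mode_display: Optional[str] = None
    mode_code: Optional[str] = None
    tissue_display: Optional[str] = None
    tissue_code: Optional[str] = None
    tissue_system: Optional[str] = None
    structure_display: Optional[str] = None
    structure_code: Optional[str] = None
    structure_system: Optional[str] = None
    slice_low: Optional[int] = None
    slice_high: Optional[int] = None
    volume_ml: float = 0.0
    mean_density_hu: Optional[float] = None


CSV_HEADER = tuple(f.name for f in dataclass_fields(MeasurementRow))


def _concept_of(codeable: dict) -> Concept:
    coding = codeable["coding"][0]
    return Concept(
        system=coding["system"],
        code=coding["code"],
        display=coding.get("display") or coding["code"],
    )


def _split_components(obs: dict, density_code: str):
    """Partition BCA observation components into volume components,
    density components (keyed by tissue), and the slice range."""
    volumes: list[tuple[Concept, float]] = []
    densities: dict[tuple[str, str], float] = {}
    slice_range: Optional[tuple[int, int]] = None
    for comp in obs.get("component", []):
        codings = comp["code"]["coding"]
        codes = {(c["system"], c["code"]) for c in codings}
        if any(code == "slice-range" for _, code in codes):
            rng = comp["valueRange"]
            slice_range = (int(rng["low"]["value"]), int(rng["high"]["value"]))
        elif any(code == density_code for _, code in codes):
            tissue = codings[0]
            densities[(tissue["system"], tissue["code"])] = comp["valueQuantity"][
                "value"
            ]
        else:
            volumes.append((_concept_of(comp["code"]), comp["valueQuantity"]["value"]))
    return volumes, densities, slice_range


def extract_measurements(
    bundle: dict,
    registry: TerminologyRegistry | None = None,
    canonical_base: str = config.DEFAULT_CANONICAL_BASE,
) -> list[MeasurementRow]:
    """Extract every measurement of a conformant bundle as tidy rows.

    Row order is stable: region-tissue rows sorted by body site, mode and
    tissue display, then organ rows sorted by structure display.
    """
    reg = registry or terminology.default_registry()
    issues = validate_bundle(bundle, registry=reg)
    if any(i.severity == "error" for i in issues):
        raise BundleNotConformantError(issues)

    bca_canonical = profile_canonical("bca", canonical_base)
    body_canonical = profile_canonical("body_structure", canonical_base)

    patient_id = ""
    study_uid = ""
    date: Optional[str] = None
    bca_observations: list[dict] = []
    body_observations: list[dict] = []
    for entry in bundle.get("entry", []):
        res = entry["resource"]
        profiles = res.get("meta", {}).get("profile", [])
        if res["resourceType"] == "ImagingStudy":
            study_uid = study_uid_from_identifier(res) or ""
            date = res.get("started", date)
        elif bca_canonical in profiles:
            bca_observations.append(res)
        elif body_canonical in profiles:
            body_observations.append(res)
        ref = res.get("subject", {}).get("reference")
        if ref:
            patient_id = ref.split("/")[-1]

    rows: list[MeasurementRow] = []
    for obs in bca_observations:
        body_site = _concept_of(obs["bodySite"])
        mode = _concept_of(obs["code"])
        volumes, densities, slice_range = _split_components(obs, "mean-hu-density")
        for tissue, volume in volumes:
            rows.append(
                MeasurementRow(
                    patient_id=patient_id,
                    study_uid=study_uid,
                    date=obs.get("effectiveDateTime", date),
                    kind="region-tissue",
                    body_site_display=body_site.display,
                    body_site_code=body_site.code,
                    body_site_system=body_site.system,
                    mode_display=mode.display,
                    mode_code=mode.code,
                    tissue_display=tissue.display,
                    tissue_code=tissue.code,
                    tissue_system=tissue.system,
                    slice_low=slice_range[0] if slice_range else None,
                    slice_high=slice_range[1] if slice_range else None,
                    volume_ml=volume,
                    mean_density_hu=densities.get(tissue.key),
                )
            )
    region_rows = sorted(
        rows,
        key=lambda r: (r.body_site_display, r.mode_display, r.tissue_display),
    )

    organ_rows: list[MeasurementRow] = []
    for obs in body_observations:
        for comp in obs.get("component", []):
            structure = _concept_of(comp["code"])
            organ_rows.append(
                MeasurementRow(
                    patient_id=patient_id,
                    study_uid=study_uid,
                    date=obs.get("effectiveDateTime", date),
                    kind="organ",
                    structure_display=structure.display,
                    structure_code=structure.code,
                    structure_system=structure.system,
                    volume_ml=comp["valueQuantity"]["value"],
                )
            )
    organ_rows.sort(key=lambda r: r.structure_display)
    return region_rows + organ_rows


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def rows_to_dataframe(rows: Sequence[MeasurementRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows], columns=list(CSV_HEADER))


def _cell(value) -> str:
    if value is None:
        return ""
    return repr(value) if isinstance(value, float) else str(value)


def write_csv(rows: Sequence[MeasurementRow], stream) -> None:
    """Locale-independent CSV (UTF-8, decimal point, documented header).

    Floats are written with ``repr`` so values survive the text round
    trip exactly.
    """
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(CSV_HEADER)
    for row in rows:
        writer.writerow([_cell(getattr(row, name)) for name in CSV_HEADER])


def read_csv(stream) -> list[MeasurementRow]:
    """Inverse of :func:`write_csv`."""
    if isinstance(stream, (str, bytes)):
        stream = io.StringIO(
            stream.decode() if isinstance(stream, bytes) else stream
        )
    reader = csv.DictReader(stream)
    rows = []
    for rec in reader:
        kwargs: dict = {}
        for name in CSV_HEADER:
            raw = rec.get(name, "")
            if raw == "":
                kwargs[name] = None
            elif name in ("slice_low", "slice_high"):
                kwargs[name] = int(raw)
            elif name in ("volume_ml", "mean_density_hu"):
                kwargs[name] = float(raw)
            else:
                kwargs[name] = raw
        rows.append(MeasurementRow(**kwargs))
    return rows


# ---------------------------------------------------------------------------
# Rebuild helper (closes the round trip)
# ---------------------------------------------------------------------------


def result_from_rows(
    rows: Sequence[MeasurementRow],
    series: Sequence[SeriesInfo],
    model: ModelMetadata,
    attachments: Sequence[Attachment] = (),
) -> BOAResult:
    """Reassemble a :class:`BOAResult` from extracted rows.

    Series, model metadata and attachments are not part of the
    measurement table and must be supplied by the caller.  Region and
    organ order follows row order, which is the canonical display-sorted
    order both the generator and extraction use.
    """
    if not rows:
        raise ValueError("no rows to rebuild from")
    patient_id = rows[0].patient_id
    study_uid = rows[0].study_uid
    started = rows[0].date

    regions: list[RegionMeasurement] = []
    current_key = None
    for row in rows:
        if row.kind != "region-tissue":
            continue
        key = (row.body_site_code, row.mode_code, row.slice_low, row.slice_high)
        tissue = TissueMeasurement(
            tissue=Concept(
                system=row.tissue_system,
                code=row.tissue_code,
                display=row.tissue_display,
            ),
            volume_ml=row.volume_ml,
            mean_density_hu=row.mean_density_hu,
        )
        if key != current_key:
            regions.append(
                RegionMeasurement(
                    body_site=Concept(
                        system=row.body_site_system,
                        code=row.body_site_code,
                        display=row.body_site_display,
                    ),
                    mode=terminology.default_registry().lookup_concept(
                        row.mode_display
                    ),
                    slice_range=(
                        SliceRange(low=row.slice_low, high=row.slice_high)
                        if row.slice_low is not None
                        else None
                    ),
                    tissues=[tissue],
                )
            )
            current_key = key
        else:
            regions[-1].tissues.append(tissue)

    organs = [
        OrganVolume(
            structure=Concept(
                system=row.structure_system,
                code=row.structure_code,
                display=row.structure_display,
            ),
            volume_ml=row.volume_ml,
        )
        for row in rows
        if row.kind == "organ"
    ]

    return BOAResult(
        patient_id=patient_id,
        study_uid=study_uid,
        series=list(series),
        started=started,
        regions=regions,
        organs=organs,
        model=model,
        attachments=list(attachments),
    )
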