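# Methods

## The interoperability problem being modeled

An AI body-and-organ analysis of one CT study produces two families of
quantitative results: per-region body-composition measurements (volume
and mean CT density of each tissue compartment within an anatomical
cavity, optionally restricted to a slice window, computed with or
without the extremities) and per-structure volumetrics for the
whole-body segmentation landmarks. For these numbers to be usable in
clinical records and longitudinal research they must be exchanged in a
standard form: coded with shared terminologies, linked to the exact
DICOM study and series they were derived from, aggregated under one
report, and explicitly marked as machine-asserted.

The package models that exchange as four FHIR R4 profiles plus the
upstream MII read-procedure profile referenced by canonical URL:

| profile | base resource | role |
|---|---|---|
| Body Composition Analysis Observation | Observation | one per region × mode; tissue components |
| Body Structure Volume Observation | Observation | one per study; landmark components |
| BOA Diagnostic Report | DiagnosticReport | aggregator; DICOM identifier; presentedForm |
| BOA Imaging Study | ImagingStudy | only the inference series; DICOM identifiers |

## Terminology

Five value sets ship as editable TSV tables (display, system, code,
synonyms) loaded at registry construction:

* `BCABodySiteVS` (4): abdominal cavity, thoracic cavity, mediastinum,
  pericardium — SNOMED CT body structures.
* `BCAMeasurementsVS` (2): measurement including/excluding extremities.
* `BCATissueVS` (8): muscle, bone, subcutaneous/visceral/intramuscular/
  epicardial/paracardial/total adipose tissue.
* `BCARegionVS` (8): the four cavities plus trunk, upper/lower
  extremities and whole body.
* `BodyStructureLandmarkVS` (104): the whole-body segmentation class
  inventory (organs, 24 vertebrae, 24 ribs, large vessels, muscles,
  bones), with the snake_case class name kept as a lookup synonym.

Codes: SNOMED CT is used where a well-established concept id exists
(the four cavities and about a dozen major organs); every other label —
analysis-specific pseudo-tissues, measurement modes, most skeletal
landmarks — carries a project-local code system URI, because FHIR
requires *some* system on every coding and inventing unverified SNOMED
or RadLex ids would be worse than an honest local code. The tables are
data, not code: sites can swap in a curated mapping from current
SNOMED CT/RadLex releases without touching logic. Label resolution is
case- and whitespace-insensitive (underscores/hyphens fold to spaces)
and prefers SNOMED CT > RadLex > local when a label is ambiguous.

The published profile set names eight body regions while binding the
body-composition observation's `bodySite` to the four cavities; the two
enumerations are related but not identical. The generator realizes the
eight region measurements as 4 cavities × 2 measurement modes, and
`BCARegionVS` ships the four cavities plus four composite regions; this
is a design choice of this package, not a claim about the upstream
enumeration.

## Input model and synthetic data

`BOAResult` is the canonical input document (JSON Schema available via
`boa_result_json_schema()`); coded fields travel as display labels and
are resolved and membership-checked on parse, with JSONPath-style error
locations. DICOM UIDs are validated against the dotted-decimal grammar
(digit-only components, no leading zeros except a bare `0`, ≤ 64
characters); slice indices are 1-based inclusive DICOM InstanceNumber
positions.

The seeded generator emulates one complete analysis: all 4 sites × 2
modes with all 8 tissues (volume + mean density + slice window) and all
104 landmark volumes, one CT series, model metadata and two inline
report attachments. Value ranges are plausible magnitudes only — organ
volumes 10–2000 mL, tissue volumes 50–8000 mL, muscle 20–60 HU,
adipose −150 to −50 HU, bone 150–1200 HU — chosen for realism of the
fixtures, not fitted to any cohort. Volumes are rounded to 0.01 mL and
densities to 0.1 HU so every value survives JSON and CSV text round
trips exactly. What the generator does **not** emulate: correlated
anatomy (organ volumes are independent draws), missing or partial
segmentations, vendor-dialect input documents, multi-study longitudinal
series, or pathological outliers. Passing tests therefore demonstrate
structural and terminological correctness of the exchange layer, not
clinical plausibility of the numbers.

Determinism contract: a fixed (seed, config) yields a byte-identical
serialized document. Regions, tissues and organs are emitted in
display-sorted order — the same canonical order extraction uses — which
makes generate → build → extract → rebuild → build reproduce the first
bundle byte for byte.

## Building and provenance

Component layout of a body-composition observation: one millilitre
quantity component per tissue; when a density was measured, a paired
component whose code carries the tissue coding plus a local
`mean-hu-density` modifier coding (lossless and unambiguous without
minting eight extra "density of X" concepts); the slice window as an
integer `Range` under a local `slice-range` component code. Quantities
use UCUM throughout: `mL` for volumes, `[hnsf'U]` for densities, `1`
(dimensionless) for slice indices — never free-text-only units.

DICOM linkage: `identifier.system = "urn:dicom:uid"`,
`identifier.value = "urn:oid:" + UID` on both ImagingStudy and
DiagnosticReport (the report reuses the study UID; a report-specific
UID would also be defensible but the study UID keeps the linkage
single-sourced). `numberOfSeries` counts the inference series listed in
the resource, not the original study's full series inventory.

Fixed values: `Observation.status`/`DiagnosticReport.status` are
`final`, category `imaging`, ImagingStudy `available`. Model metadata is
stored on the Procedure as structured `key=value` annotations
(`model.name=…`, `parameter.device=…`) rather than custom extensions,
keeping the referenced MII profile untouched and the metadata trivially
recoverable (`procedure_model_metadata`).

Resource ids default to content hashes (SHA-256 of the id-less resource
JSON, 24 hex chars) for reproducible builds; UUID4 ids are available
per context flag. Bundle entries use `PUT ResourceType/id` requests so
internal references stay resolvable under both id strategies.

`tag_ai_provenance` adds the HL7 `v3-ObservationValue` security label
`AIAST` to `meta.security`; it is idempotent and touches nothing
outside `meta`. Every resource in an assembled bundle carries it.

## Validation

Profiles are machine-readable constraint tables (path, min/max, fixed
value, pattern coding, required binding, UCUM whitelist, allowed
values, fixed identifier system, UID grammar, coding uniqueness),
serializable to StructureDefinition-style JSON and parseable back.
The validator applies them per resource — cardinalities per parent
instance, as FHIR defines them — plus resource-wide unit discipline and
bundle-level rules: internal references must resolve (patient
references may point outside the bundle), `DiagnosticReport.result`
must cover exactly the bundle's observations, every entry must carry
AIAST, at most one ImagingStudy and one DiagnosticReport per bundle,
`numberOfSeries` must match the series list. Elements outside the
constraint tables are accepted silently (open-world profiling
semantics). Core resource types that claim no shipped profile canonical
are errors; genuinely foreign resource types (e.g. a Condition riding
along) are ignored with a warning. Named bindings are `required`
strength: violations are errors.

Soundness is demonstrated by a documented 18-mutation fault-injection
catalog (`boafhir.faults`): each single-field mutation of a conformant
bundle must produce at least one error of the expected rule at the
mutated path, and the pristine bundle must validate clean. Validation
is read-only by construction and by test.

## Extraction

`extract_measurements` refuses bundles with validation errors outright
(no partial tables) and emits one row per region-tissue component pair
and one per landmark component, in a stable order (region rows by body
site, mode, tissue display; then organ rows by structure display). The
CSV writer uses `repr` for floats, UTF-8 and the decimal point, so
`read_csv(write_csv(rows)) == rows` exactly. `result_from_rows` closes
the loop; series, model metadata and attachments are not part of the
measurement table and must be supplied by the caller.

## Problem sizes and numerical choices

The test suite and acceptance script run the full-scale study
conditions: complete 8-region/104-organ analyses, conformance closure
over 100 seeds, round trips over 20 seeds, and an exhaustive UID-grammar
enumeration of all 5460 strings of length ≤ 6 over `{0, 1, ., a}` plus a
50+-case curated edge list; the whole suite completes in seconds. Ties
in label lookup are broken by system priority then registration order.
Degenerate inputs are rejected eagerly: empty region+organ sets, n > 8
regions or n > 104 organs, inverted value ranges, inverted slice
ranges, duplicate series UIDs or landmark concepts.

## Known limitations

* No vendor-dialect input adapters; the canonical JSON document is the
  only accepted input shape.
* The validator checks the shipped profile set and its cross-links
  only; it is not a general FHIR validator and does not fetch or check
  external canonicals (including the MII procedure profile's own
  constraints).
* Local codes stand in wherever a SNOMED CT/RadLex id was not certain;
  deployments exchanging data beyond this package should curate the
  terminology tables.
* Volume/density mix-ups that keep a legal UCUM code (a volume
  expressed in `[hnsf'U]`) are not detectable by the generic unit rule.
* `push` is a minimal transaction POST with no retry, auth or
  capability negotiation.
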