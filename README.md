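# boa-fhir

Body-and-organ analysis (BOA) pipelines segment routine CT scans and
quantify body composition — muscle, bone and adipose-tissue volumes with
their Hounsfield-unit densities per body region — together with the
volumes of ~100 anatomical structures. Those numbers are clinically
valuable (sarcopenia monitoring, opportunistic screening, risk
stratification), but they leave the AI model as loose JSON/PDF output
with no standard exchange format.

`boa-fhir` closes that gap. It implements a set of four FHIR R4 profiles
for AI-derived CT body-composition and organ-volume results, and the
tooling around them:

* **terminology** — five value sets with SNOMED CT / project-local
  codings: 4 body-site cavities, 2 measurement modes (with/without
  extremities), 8 tissues, 8 body regions, and 104 whole-body
  segmentation landmarks; label→code resolution with synonyms.
* **data model** — a typed `BOAResult` document (patient, DICOM
  study/series UIDs, per-region tissue measurements, per-landmark organ
  volumes, model metadata, report attachments) with a canonical JSON
  form, strict DICOM-UID grammar checking, and a seeded synthetic
  generator.
* **builders** — serialize a `BOAResult` into a referentially closed
  transaction Bundle: one body-composition `Observation` per region
  (tissue volumes in UCUM `mL`, densities in `[hnsf'U]`, slice window as
  an integer `Range`), one body-structure volume `Observation` with a
  component per landmark, an `ImagingStudy` restricted to the series the
  model ran on (`urn:dicom:uid` / `urn:oid:` identifiers), a
  `DiagnosticReport` aggregating every observation with the rendered
  reports as `presentedForm`, and a read `Procedure` (MII profile)
  carrying model name/version/parameters. Every resource is tagged with
  the HL7 `AIAST` (Artificial Intelligence Asserted) security label.
* **validator** — checks resources against the machine-readable profile
  definitions (cardinalities, fixed values, required bindings, UCUM
  discipline, UID grammar) plus cross-resource rules (reference
  resolution, report coverage, AIAST presence).
* **extraction + CLI** — flattens a conformant bundle back into a tidy
  measurement table (one row per region-tissue pair and per organ) for
  longitudinal analysis, exactly and losslessly.

## Worked example

```bash
boa-fhir generate --seed 7 -o boa.json        # synthetic analysis result
boa-fhir convert boa.json -o bundle.json      # parse -> build -> AIAST-tag
boa-fhir validate bundle.json                 # profile + cross-resource checks
boa-fhir extract bundle.json -o table.csv     # tidy measurement table
```

The generated document covers a full analysis — 8 region measurements
(4 cavities × 2 modes) and 104 organ volumes, e.g.
`{"structure": "C1 vertebra", "volume_ml": 511.99}` — under a
well-formed study UID such as
`1.2.826.0.1.3680043.9.7420.954223.794485255`. `convert` emits a
12-entry transaction bundle (`ImagingStudy`, 9 `Observation`s,
`DiagnosticReport`, `Procedure`); resource ids are content hashes, so
re-running it reproduces the bundle byte for byte. `validate` prints
`0 error(s), 0 warning(s)` and exits 0. `extract` writes 168 rows
(8 × 8 region-tissue + 104 organ); the first data row pins the
abdominal-cavity muscle measurement to its SNOMED CT body-site coding
(`http://snomed.info/sct|52731004`):

```
patient_id,study_uid,date,kind,body_site_display,body_site_code,...
synthetic-patient-163863,1.2.826...794485255,2024-04-05T10:40:00Z,region-tissue,abdominal cavity,52731004,...
```

`boa-fhir export-profiles -o profiles/` writes the four
StructureDefinition-style profile documents and the five ValueSet
resources; `boa-fhir validate --profile-dir profiles/` validates against
such an exported set. The library surface mirrors the CLI
(`generate_synthetic_result`, `assemble_bundle`, `validate_bundle`,
`extract_measurements`, …).

## Scope

The segmentation models themselves (BCA, TotalSegmentator) are out of
scope — this package consumes their measurements. No FHIR R5 resources
(ImagingSelection, BodyStructure), no XML, no terminology-server client;
`push` POSTs a bundle to a FHIR server but is feature-flagged and never
required. See `docs/methods.md` for the design rationale and
limitations.
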