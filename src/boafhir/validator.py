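"""Conformance checking of built resources and bundles.

Not a general-purpose FHIR validator: it checks exactly the shipped
profile set plus the cross-resource rules that make a body-and-organ
analysis bundle coherent (referential integrity, report coverage, AI
provenance tagging, DICOM UID grammar, UCUM unit discipline).  Elements
outside the constraint tables are accepted silently, matching FHIR's
open-world profiling semantics.

Findings are :class:`Issue` records with a severity, a rule id from
:data:`RULES`, an element path and a message; validation never mutates
its input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

from . import config, terminology
from .boa_model import validate_dicom_uid
from .profile_builder import (
    Constraint,
    ProfileDefinition,
    export_profile_definitions,
    has_aiast_tag,
)
from .terminology import Concept, TerminologyRegistry

__all__ = ["Issue", "RULES", "validate_resource", "validate_bundle"]


#: Registry of every rule the validator can emit, with default severity.
RULES: dict[str, tuple[str, str]] = {
    "fatal-parse": ("error", "resource is not a parseable FHIR JSON object"),
    "type-mismatch": ("error", "resourceType differs from the profile's base"),
    "meta-profile-missing": ("error", "meta.profile does not list the profile canonical"),
    "cardinality-min": ("error", "element occurs fewer times than the profile minimum"),
    "cardinality-max": ("error", "element occurs more often than the profile maximum"),
    "fixed-value-mismatch": ("error", "element differs from the profile's fixed value"),
    "pattern-mismatch": ("error", "required pattern coding is absent"),
    "binding-violation": ("error", "coding is not a member of the bound value set"),
    "unit-ucum": ("error", "quantity does not use the required UCUM unit"),
    "value-allowed": ("error", "value outside the allowed set"),
    "identifier-system": ("error", "identifier system differs from the fixed system"),
    "uid-grammar": ("error", "value violates the DICOM UID grammar"),
    "duplicate-component": ("error", "repeated coding where uniqueness is required"),
    "reference-dangling": ("error", "reference does not resolve within the bundle"),
    "report-coverage": ("error", "DiagnosticReport.result does not cover the bundle's observations"),
    "aiast-missing": ("error", "AI-derived resource lacks the AIAST security tag"),
    "cardinality-bundle": ("error", "bundle-level multiplicity rule violated"),
    "series-count-mismatch": ("error", "numberOfSeries differs from the series count"),
    "not-a-bundle": ("error", "input is not a FHIR Bundle"),
    "unknown-resource": ("warning", "resource type not covered by the profile set"),
    "unbound-coding": ("warning", "coding from a system outside the configured ones"),
}


@dataclass(frozen=True)
class Issue:
    severity: str
    rule_id: str
    path: str
    message: str

    def __post_init__(self):
        if self.rule_id not in RULES:
            raise ValueError(f"undocumented rule id: {self.rule_id}")
        if self.severity not in ("error", "warning"):
            raise ValueError(f"bad severity: {self.severity}")


def _issue(rule_id: str, path: str, message: str) -> Issue:
    return Issue(RULES[rule_id][0], rule_id, path, message)


# ---------------------------------------------------------------------------
# Element path navigation
# ---------------------------------------------------------------------------


def _walk(value, steps: list[str], path: str) -> Iterator[tuple[str, object]]:
    """Yield (path, value) for every element instance at the dotted path,
    expanding arrays with [i] indices."""
    if isinstance(value, list):
        for i, item in enumerate(value):
            yield from _walk(item, steps, f"{path}[{i}]")
        return
    if not steps:
        yield path, value
        return
    if not isinstance(value, dict):
        return
    head, rest = steps[0], steps[1:]
    if head in value:
        yield from _walk(value[head], rest, f"{path}.{head}")


def _parents(resource: dict, steps: list[str], root: str):
    """Instances of the parent element of a path (for per-parent
    cardinality), paired with the leaf name."""
    *parent_steps, leaf = steps
    if parent_steps:
        yield from ((p, v, leaf) for p, v in _walk(resource, parent_steps, root))
    else:
        yield root, resource, leaf


def _codings(value) -> list[dict]:
    """Codings of a CodeableConcept or bare Coding element."""
    if not isinstance(value, dict):
        return []
    if "coding" in value:
        return [c for c in value["coding"] if isinstance(c, dict)]
    if "system" in value or "code" in value:
        return [value]
    return []


def _is_quantity(value) -> bool:
    return (
        isinstance(value, dict)
        and isinstance(value.get("value"), (int, float))
        and not isinstance(value.get("value"), bool)
        and ("code" in value or "unit" in value or "system" in value)
    )


# ---------------------------------------------------------------------------
# Per-constraint checks
# ---------------------------------------------------------------------------


def _check_constraint(
    resource: dict,
    constraint: Constraint,
    reg: TerminologyRegistry,
    root: str,
) -> Iterator[Issue]:
    steps = constraint.path.split(".")[1:]  # drop the base-resource segment
    if not steps:
        return

    # cardinality, per parent instance
    for parent_path, parent, leaf in _parents(resource, steps, root):
        if not isinstance(parent, dict):
            continue
        value = parent.get(leaf)
        count = len(value) if isinstance(value, list) else (0 if value is None else 1)
        if count < constraint.min:
            yield _issue(
                "cardinality-min",
                f"{parent_path}.{leaf}",
                f"requires >= {constraint.min}, found {count}",
            )
        maximum = constraint.max_count()
        if maximum is not None and count > maximum:
            yield _issue(
                "cardinality-max",
                f"{parent_path}.{leaf}",
                f"allows <= {maximum}, found {count}",
            )

    seen_codings: set[tuple[str, str]] = set()
    for path, value in _walk(resource, steps, root):
        if constraint.fixed_value is not None and value != constraint.fixed_value:
            yield _issue(
                "fixed-value-mismatch",
                path,
                f"expected {constraint.fixed_value!r}, found {value!r}",
            )
        if constraint.pattern_concept is not None:
            want = constraint.pattern_concept.key
            if not any(
                (c.get("system"), c.get("code")) == want for c in _codings(value)
            ):
                yield _issue(
                    "pattern-mismatch",
                    path,
                    f"required coding {want[1]!r} from {want[0]} absent",
                )
        if constraint.binding:
            codings = _codings(value)
            member = False
            for c in codings:
                try:
                    concept = Concept(
                        system=c.get("system", ""),
                        code=c.get("code", ""),
                        display=c.get("display") or c.get("code", "?"),
                    )
                except Exception:
                    continue
                if any(
                    reg.validate_membership(concept, vs)
                    for vs in constraint.binding
                ):
                    member = True
                    if constraint.unique_codings:
                        if concept.key in seen_codings:
                            yield _issue(
                                "duplicate-component",
                                path,
                                f"coding {concept.code!r} repeated",
                            )
                        seen_codings.add(concept.key)
                    break
            if not member:
                severity_rule = (
                    "binding-violation"
                    if constraint.binding_strength == "required"
                    else "unbound-coding"
                )
                yield _issue(
                    severity_rule,
                    path,
                    "no coding is a member of "
                    + " or ".join(constraint.binding),
                )
        if constraint.allowed_ucum and isinstance(value, dict):
            quantities = [value] if _is_quantity(value) else [
                q for q in (value.get("low"), value.get("high")) if _is_quantity(q)
            ]
            for q in quantities:
                if q.get("system") != config.UCUM or q.get("code") not in constraint.allowed_ucum:
                    yield _issue(
                        "unit-ucum",
                        path,
                        f"expected UCUM {'/'.join(constraint.allowed_ucum)}, "
                        f"found {q.get('system')}|{q.get('code')}",
                    )
        if constraint.allowed_values and value not in constraint.allowed_values:
            yield _issue(
                "value-allowed",
                path,
                f"{value!r} not among allowed values",
            )
        if constraint.fixed_system is not None and isinstance(value, dict):
            if value.get("system") != constraint.fixed_system:
                yield _issue(
                    "identifier-system",
                    f"{path}.system",
                    f"expected {constraint.fixed_system!r}",
                )
        if constraint.value_grammar is not None:
            text = value.get("value") if isinstance(value, dict) else value
            if constraint.value_grammar == "dicom-uid-urn":
                ok = isinstance(text, str) and text.startswith(
                    config.DICOM_URN_PREFIX
                ) and validate_dicom_uid(text[len(config.DICOM_URN_PREFIX):])
            else:
                ok = isinstance(text, str) and validate_dicom_uid(text)
            if not ok:
                yield _issue(
                    "uid-grammar",
                    f"{path}.value" if isinstance(value, dict) else path,
                    f"{text!r} is not a well-formed DICOM UID"
                    + (" URN" if constraint.value_grammar == "dicom-uid-urn" else ""),
                )


def _check_global_units(resource: dict, root: str) -> Iterator[Issue]:
    """Unit discipline on every quantity anywhere in the resource: UCUM
    system and millilitre / Hounsfield / dimensionless codes only."""
    allowed = {config.UCUM_ML, config.UCUM_HU, config.UCUM_UNITY}

    def recurse(value, path):
        if isinstance(value, dict):
            if _is_quantity(value) and not (
                value.get("system") == config.UCUM and value.get("code") in allowed
            ):
                yield _issue(
                    "unit-ucum",
                    path,
                    f"quantity unit {value.get('system')}|{value.get('code')} "
                    "is not an allowed UCUM code",
                )
            for key, child in value.items():
                yield from recurse(child, f"{path}.{key}")
        elif isinstance(value, list):
            for i, item in enumerate(value):
                yield from recurse(item, f"{path}[{i}]")

    yield from recurse(resource, root)


def validate_resource(
    resource: dict,
    profile: ProfileDefinition,
    registry: TerminologyRegistry | None = None,
    root: Optional[str] = None,
) -> list[Issue]:
    """Check one resource against one profile definition.

    Returns an empty list iff every constraint holds.  ``root`` overrides
    the path prefix used in issue paths (the bundle validator passes the
    entry-qualified prefix).
    """
    reg = registry or terminology.default_registry()
    if not isinstance(resource, dict) or "resourceType" not in resource:
        return [_issue("fatal-parse", root or "$", "not a FHIR resource object")]
    root = root or resource["resourceType"]
    issues: list[Issue] = []
    if resource["resourceType"] != profile.base_resource:
        issues.append(
            _issue(
                "type-mismatch",
                f"{root}.resourceType",
                f"expected {profile.base_resource}, found {resource['resourceType']}",
            )
        )
        return issues
    profiles_listed = resource.get("meta", {}).get("profile", [])
    if profile.canonical_url not in profiles_listed:
        issues.append(
            _issue(
                "meta-profile-missing",
                f"{root}.meta.profile",
                f"must list {profile.canonical_url}",
            )
        )
    for constraint in profile.constraints:
        issues.extend(_check_constraint(resource, constraint, reg, root))
    issues.extend(_check_global_units(resource, root))
    return issues


# ---------------------------------------------------------------------------
# Bundle validation
# ---------------------------------------------------------------------------


def _collect_references(value, path: str) -> Iterator[tuple[str, str]]:
    if isinstance(value, dict):
        if "reference" in value and isinstance(value["reference"], str):
            yield f"{path}.reference", value["reference"]
        for key, child in value.items():
            if key != "reference":
                yield from _collect_references(child, f"{path}.{key}")
    elif isinstance(value, list):
        for i, item in enumerate(value):
            yield from _collect_references(item, f"{path}[{i}]")


def validate_bundle(
    bundle: dict,
    profiles: Sequence[ProfileDefinition] | None = None,
    registry: TerminologyRegistry | None = None,
) -> list[Issue]:
    """Validate a full analysis bundle.

    Per-resource profile checks (profiles matched via ``meta.profile``)
    plus the cross-resource rules: resolvable internal references, report
    coverage of all observations, AIAST on every entry, at most one
    ImagingStudy and one DiagnosticReport, numberOfSeries consistency.
    """
    reg = registry or terminology.default_registry()
    if not isinstance(bundle, dict) or bundle.get("resourceType") != "Bundle":
        return [_issue("not-a-bundle", "$", "expected a Bundle resource")]
    profile_list = list(profiles) if profiles is not None else export_profile_definitions(registry=reg)
    by_canonical = {p.canonical_url: p for p in profile_list}

    issues: list[Issue] = []
    entries = bundle.get("entry", [])
    local_ids: set[str] = set()
    resources: list[tuple[str, dict]] = []
    for i, entry in enumerate(entries):
        prefix = f"Bundle.entry[{i}]"
        resource = entry.get("resource")
        if not isinstance(resource, dict) or "resourceType" not in resource:
            issues.append(_issue("fatal-parse", prefix, "entry without resource"))
            continue
        rid = resource.get("id")
        if rid:
            local_ids.add(f"{resource['resourceType']}/{rid}")
        if entry.get("fullUrl"):
            local_ids.add(entry["fullUrl"])
        resources.append((prefix, resource))

    studies, reports, observations, procedures = [], [], [], []
    for prefix, resource in resources:
        rtype = resource["resourceType"]
        root = f"{prefix}.{rtype}"
        matched = [
            by_canonical[url]
            for url in resource.get("meta", {}).get("profile", [])
            if url in by_canonical
        ]
        if matched:
            for profile in matched:
                issues.extend(validate_resource(resource, profile, reg, root=root))
        elif rtype == "Procedure":
            # read procedure: profiled upstream (MII); only local rules here
            if not resource.get("report"):
                issues.append(
                    _issue("cardinality-min", f"{root}.report", "requires >= 1")
                )
        elif rtype in ("Observation", "DiagnosticReport", "ImagingStudy"):
            # core resources of an analysis bundle must claim their profile
            issues.append(
                _issue(
                    "meta-profile-missing",
                    f"{root}.meta.profile",
                    f"{rtype} claims no shipped profile canonical",
                )
            )
        else:
            issues.append(
                _issue(
                    "unknown-resource",
                    root,
                    f"{rtype} matches no shipped profile; ignored",
                )
            )
            continue
        if not has_aiast_tag(resource):
            issues.append(
                _issue(
                    "aiast-missing",
                    f"{root}.meta.security",
                    f"{rtype} ({resource.get('id')}) lacks the AIAST tag",
                )
            )
        if rtype == "ImagingStudy":
            studies.append((root, resource))
        elif rtype == "DiagnosticReport":
            reports.append((root, resource))
        elif rtype == "Observation":
            observations.append((root, resource))
        elif rtype == "Procedure":
            procedures.append((root, resource))

    if len(studies) > 1:
        issues.append(
            _issue(
                "cardinality-bundle",
                studies[1][0],
                f"at most one ImagingStudy per bundle, found {len(studies)}",
            )
        )
    if len(reports) > 1:
        issues.append(
            _issue(
                "cardinality-bundle",
                reports[1][0],
                f"at most one DiagnosticReport per bundle, found {len(reports)}",
            )
        )

    # referential integrity
    for prefix, resource in resources:
        root = f"{prefix}.{resource['resourceType']}"
        for path, ref in _collect_references(resource, root):
            if ref.startswith(("http:", "https:", "urn:")):
                continue  # external/absolute references are out of scope
            if ref in local_ids or ref.split("/")[0] == "Patient":
                continue  # the patient record lives outside the bundle
            issues.append(
                _issue(
                    "reference-dangling",
                    path,
                    f"{ref!r} does not resolve within the bundle",
                )
            )

    # report coverage: result must cover exactly the bundle's observations
    if reports:
        root, report = reports[0]
        listed = {
            r.get("reference") for r in report.get("result", []) if isinstance(r, dict)
        }
        actual = {
            f"Observation/{res.get('id')}" for _, res in observations
        }
        if listed != actual:
            missing = sorted(actual - listed)
            extra = sorted(listed - actual)
            detail = []
            if missing:
                detail.append(f"missing {missing}")
            if extra:
                detail.append(f"dangling/extra {extra}")
            issues.append(
                _issue("report-coverage", f"{root}.result", "; ".join(detail))
            )

    # numberOfSeries consistency
    for root, study in studies:
        n_declared = study.get("numberOfSeries")
        n_actual = len(study.get("series", []))
        if n_declared is not None and n_declared != n_actual:
            issues.append(
                _issue(
                    "series-count-mismatch",
                    f"{root}.numberOfSeries",
                    f"declares {n_declared}, bundle lists {n_actual} series",
                )
            )

    return issues
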