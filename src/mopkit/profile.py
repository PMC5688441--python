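"""Country profiles and intervention catalogues.

A :class:`CountryProfile` bundles everything the missed-opportunity analysis
needs for one country-year: baseline deaths by cause and age group, live
births, women of reproductive age, under-5 mortality, per-intervention
coverage, family-planning indicators, and the intervention catalogue itself
(each intervention carrying cause-specific effectiveness and affected-fraction
entries).

Structural validation (field presence and types) is enforced by pydantic at
parse time.  Semantic invariants — proportions in [0, 1], unique ids, every
effectiveness entry pointing at a cause that exists in the deaths table — are
checked by :func:`validate_profile`, which returns a list of findings rather
than raising, so a malformed profile can be fully diagnosed in one pass.
:func:`read_profile` runs both layers and raises on the first problem class.

The canonical on-disk format is a single UTF-8 JSON document with proportions
on the 0–1 scale (an explicit ``units: percent`` marker switches inputs to the
0–100 scale, which is converted on read).  A CSV dialect is also supported:
a small YAML header for the scalars and catalogue plus ``deaths.csv``
(cause, age_group, count) and ``coverage.csv`` (intervention, coverage).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

import pydantic
import yaml

from .errors import (
    ProfileConsistencyError,
    ProfileRangeError,
    ProfileSchemaError,
)

__all__ = [
    "AgeGroup",
    "CauseOfDeath",
    "EffectivenessEntry",
    "InterventionDefinition",
    "FamilyPlanningParams",
    "CountryProfile",
    "DeliveryPoint",
    "Finding",
    "validate_profile",
    "read_profile",
    "write_profile",
    "DEFAULT_CAUSES",
]


class AgeGroup(str, Enum):
    """The four outcome groups: women, stillbirths, and children split at one
    month of age."""

    MATERNAL = "maternal"
    STILLBIRTH = "stillbirth"
    NEONATAL = "neonatal_0_1m"
    CHILD = "child_1_59m"


class DeliveryPoint(str, Enum):
    """Where an intervention is delivered, from community outreach up to
    comprehensive emergency obstetric care (CEmOC) facilities."""

    COMMUNITY = "community"
    OUTREACH = "outreach"
    CLINIC_ESSENTIAL = "clinic_essential"
    BEMOC_FACILITY = "bemoc_facility"
    CEMOC_FACILITY = "cemoc_facility"


class CauseOfDeath(pydantic.BaseModel):
    """A cause of death, attached to exactly one age group."""

    model_config = pydantic.ConfigDict(frozen=True)

    code: str
    label: str
    age_group: AgeGroup


#: Default cause taxonomy used by the synthetic fixtures.  Profiles may carry
#: any taxonomy they like; this one covers the major cause groupings for each
#: outcome group.
DEFAULT_CAUSES: tuple[CauseOfDeath, ...] = tuple(
    CauseOfDeath(code=code, label=label, age_group=group)
    for code, label, group in [
        ("hemorrhage", "Antepartum/postpartum hemorrhage", AgeGroup.MATERNAL),
        ("sepsis", "Maternal sepsis", AgeGroup.MATERNAL),
        ("hypertensive_disorders", "Hypertensive disorders", AgeGroup.MATERNAL),
        ("obstructed_labor", "Obstructed labor", AgeGroup.MATERNAL),
        ("abortion", "Abortion-related", AgeGroup.MATERNAL),
        ("other_maternal", "Other maternal", AgeGroup.MATERNAL),
        ("antepartum", "Antepartum stillbirth", AgeGroup.STILLBIRTH),
        ("intrapartum", "Intrapartum stillbirth", AgeGroup.STILLBIRTH),
        ("prematurity", "Prematurity", AgeGroup.NEONATAL),
        ("intrapartum_asphyxia", "Intrapartum asphyxia", AgeGroup.NEONATAL),
        ("sepsis_pneumonia", "Neonatal sepsis/pneumonia", AgeGroup.NEONATAL),
        ("congenital", "Congenital anomalies", AgeGroup.NEONATAL),
        ("tetanus", "Neonatal tetanus", AgeGroup.NEONATAL),
        ("other_neonatal", "Other neonatal", AgeGroup.NEONATAL),
        ("pneumonia", "Pneumonia", AgeGroup.CHILD),
        ("diarrhea", "Diarrhea", AgeGroup.CHILD),
        ("malaria", "Malaria", AgeGroup.CHILD),
        ("measles", "Measles", AgeGroup.CHILD),
        ("meningitis", "Meningitis", AgeGroup.CHILD),
        ("injury", "Injury", AgeGroup.CHILD),
        ("other_child", "Other child", AgeGroup.CHILD),
    ]
)


class EffectivenessEntry(pydantic.BaseModel):
    """One (cause, age group) cell of an intervention's effect profile.

    ``effectiveness`` is the proportional reduction in cause-specific
    mortality among those receiving the intervention; ``affected_fraction``
    is the share of that cause's deaths the intervention can address at all.
    """

    model_config = pydantic.ConfigDict(frozen=True)

    cause: str
    age_group: AgeGroup
    effectiveness: float
    affected_fraction: float = 1.0


class InterventionDefinition(pydantic.BaseModel):
    """One intervention: identity, delivery point and its effect entries."""

    model_config = pydantic.ConfigDict(frozen=True)

    id: str
    name: str
    delivery_point: DeliveryPoint
    entries: tuple[EffectivenessEntry, ...] = ()
    is_family_planning: bool = False


class FamilyPlanningParams(pydantic.BaseModel):
    """Parameters of the family-planning (unmet-need) pathway.

    ``contraceptive_effectiveness`` is the method-mix average use-
    effectiveness feeding the proximate-determinants births multiplier.
    The ``risky_*`` parameters describe the small secondary pathway in which
    higher contraceptive prevalence shifts births out of a high-risk stratum
    (short spacing, extreme maternal age, high parity): the baseline fraction
    of births that are high-risk, their mortality relative risk, and how much
    the high-risk fraction falls per percentage point of CPR gained.
    """

    model_config = pydantic.ConfigDict(frozen=True)

    contraceptive_effectiveness: float = 0.85
    risky_birth_fraction: float = 0.25
    risky_relative_risk: float = 1.5
    risky_fraction_shift_per_cpr_point: float = 0.002


class CountryProfile(pydantic.BaseModel):
    """All model inputs for one country-year."""

    model_config = pydantic.ConfigDict(frozen=True)

    country: str
    year: int
    live_births: float
    women_15_49: float
    u5mr: float
    cpr: float
    unmet_need: float
    causes: tuple[CauseOfDeath, ...]
    deaths: dict[str, float]
    coverage: dict[str, float]
    catalogue: tuple[InterventionDefinition, ...]
    fp_params: FamilyPlanningParams = FamilyPlanningParams()
    metadata: dict[str, str] = {}

    # -- convenience lookups (not part of the schema) ----------------------

    def cause_map(self) -> dict[str, CauseOfDeath]:
        return {c.code: c for c in self.causes}

    def intervention(self, intervention_id: str) -> InterventionDefinition:
        for iv in self.catalogue:
            if iv.id == intervention_id:
                return iv
        from .errors import UnknownInterventionError

        raise UnknownInterventionError(intervention_id)

    def family_planning_intervention(self) -> Optional[InterventionDefinition]:
        for iv in self.catalogue:
            if iv.is_family_planning:
                return iv
        return None

    def deaths_by_age_group(self) -> dict[AgeGroup, float]:
        cmap = self.cause_map()
        out: dict[AgeGroup, float] = {g: 0.0 for g in AgeGroup}
        for code, count in self.deaths.items():
            if code in cmap:
                out[cmap[code].age_group] += count
        return out


@dataclass(frozen=True)
class Finding:
    """One violated invariant: a machine code, where it happened, and text."""

    code: str  # "range" | "consistency" | "uniqueness"
    location: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.location}: {self.message}"


def _check_proportion(value: float, location: str, findings: list[Finding]) -> None:
    if not (0.0 <= value <= 1.0):
        findings.append(
            Finding("range", location, f"expected a proportion in [0, 1], got {value}")
        )


def validate_profile(profile: CountryProfile) -> list[Finding]:
    """Check every semantic invariant of a profile.

    Returns an empty list iff the profile is valid; otherwise one
    :class:`Finding` per violation, naming the invariant and its location.
    """
    findings: list[Finding] = []

    if profile.live_births <= 0:
        findings.append(Finding("range", "live_births", "must be > 0"))
    if profile.women_15_49 <= 0:
        findings.append(Finding("range", "women_15_49", "must be > 0"))
    if profile.u5mr < 0:
        findings.append(Finding("range", "u5mr", "must be >= 0"))
    _check_proportion(profile.cpr, "cpr", findings)
    _check_proportion(profile.unmet_need, "unmet_need", findings)
    if profile.cpr + profile.unmet_need > 1.0 + 1e-12:
        findings.append(
            Finding(
                "range",
                "cpr+unmet_need",
                f"cpr ({profile.cpr}) + unmet_need ({profile.unmet_need}) exceeds 1",
            )
        )

    fp = profile.fp_params
    _check_proportion(
        fp.contraceptive_effectiveness, "fp_params.contraceptive_effectiveness", findings
    )
    _check_proportion(fp.risky_birth_fraction, "fp_params.risky_birth_fraction", findings)
    if fp.risky_relative_risk < 1.0:
        findings.append(
            Finding("range", "fp_params.risky_relative_risk", "must be >= 1")
        )
    if fp.risky_fraction_shift_per_cpr_point < 0:
        findings.append(
            Finding("range", "fp_params.risky_fraction_shift_per_cpr_point", "must be >= 0")
        )

    # causes: unique codes, one age group each (enforced by shape)
    seen_codes: set[str] = set()
    for cause in profile.causes:
        if cause.code in seen_codes:
            findings.append(
                Finding("uniqueness", f"causes[{cause.code}]", "duplicate cause code")
            )
        seen_codes.add(cause.code)

    cmap = profile.cause_map()
    for code, count in profile.deaths.items():
        if count < 0:
            findings.append(
                Finding("range", f"deaths[{code}]", f"death count must be >= 0, got {count}")
            )
        if code not in cmap:
            findings.append(
                Finding(
                    "consistency",
                    f"deaths[{code}]",
                    "death count for a cause not declared in the cause list",
                )
            )

    # catalogue: unique ids, at most one FP flag, entries consistent
    seen_ids: set[str] = set()
    fp_count = 0
    for iv in profile.catalogue:
        loc = f"catalogue[{iv.id}]"
        if iv.id in seen_ids:
            findings.append(Finding("uniqueness", loc, "duplicate intervention id"))
        seen_ids.add(iv.id)
        if iv.is_family_planning:
            fp_count += 1
        elif not iv.entries:
            findings.append(
                Finding(
                    "consistency",
                    loc,
                    "non-family-planning intervention has no effectiveness entries",
                )
            )
        seen_cells: set[tuple[str, AgeGroup]] = set()
        for entry in iv.entries:
            eloc = f"{loc}.entries[{entry.cause}]"
            _check_proportion(entry.effectiveness, f"{eloc}.effectiveness", findings)
            _check_proportion(entry.affected_fraction, f"{eloc}.affected_fraction", findings)
            cell = (entry.cause, entry.age_group)
            if cell in seen_cells:
                findings.append(
                    Finding("uniqueness", eloc, "duplicate (cause, age_group) entry")
                )
            seen_cells.add(cell)
            if entry.cause not in cmap:
                findings.append(
                    Finding(
                        "consistency",
                        eloc,
                        f"references unknown cause {entry.cause!r}",
                    )
                )
            elif entry.cause not in profile.deaths:
                findings.append(
                    Finding(
                        "consistency",
                        eloc,
                        f"cause {entry.cause!r} has no baseline death count",
                    )
                )
            elif cmap[entry.cause].age_group != entry.age_group:
                findings.append(
                    Finding(
                        "consistency",
                        eloc,
                        f"entry age group {entry.age_group.value} does not match "
                        f"cause's group {cmap[entry.cause].age_group.value}",
                    )
                )
    if fp_count > 1:
        findings.append(
            Finding(
                "uniqueness",
                "catalogue",
                f"{fp_count} interventions flagged is_family_planning; at most one allowed",
            )
        )

    # coverage keys and catalogue ids must match exactly
    cov_keys = set(profile.coverage)
    for key in sorted(cov_keys - seen_ids):
        findings.append(
            Finding("consistency", f"coverage[{key}]", "no matching catalogue entry")
        )
    for key in sorted(seen_ids - cov_keys):
        findings.append(
            Finding("consistency", f"catalogue[{key}]", "no coverage value for this intervention")
        )
    for key, value in profile.coverage.items():
        _check_proportion(value, f"coverage[{key}]", findings)

    return findings


# ---------------------------------------------------------------------------
# I/O


_PROPORTION_FIELDS = ("cpr", "unmet_need")


def _scale_from_percent(payload: dict) -> dict:
    """Convert a percent-scale payload to the internal 0–1 scale."""
    payload = dict(payload)
    for field in _PROPORTION_FIELDS:
        if field in payload:
            payload[field] = payload[field] / 100.0
    if "coverage" in payload:
        payload["coverage"] = {k: v / 100.0 for k, v in payload["coverage"].items()}
    for iv in payload.get("catalogue", []):
        for entry in iv.get("entries", []):
            entry["effectiveness"] = entry["effectiveness"] / 100.0
            if "affected_fraction" in entry:
                entry["affected_fraction"] = entry["affected_fraction"] / 100.0
    return payload


def _profile_from_payload(payload: dict) -> CountryProfile:
    if not isinstance(payload, dict):
        raise ProfileSchemaError("profile document must be a JSON object")
    units = payload.pop("units", "proportion")
    if units not in ("proportion", "percent"):
        raise ProfileSchemaError(
            f"units must be 'proportion' or 'percent', got {units!r}"
        )
    if units == "percent":
        payload = _scale_from_percent(payload)
    try:
        profile = CountryProfile.model_validate(payload)
    except pydantic.ValidationError as exc:
        missing = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ProfileSchemaError(f"profile does not match schema ({missing})") from exc
    _raise_on_findings(profile)
    return profile


def _raise_on_findings(profile: CountryProfile) -> None:
    findings = validate_profile(profile)
    if not findings:
        return
    ranges = [f for f in findings if f.code == "range"]
    msg = "; ".join(str(f) for f in findings)
    if ranges and len(ranges) == len(findings):
        raise ProfileRangeError(msg)
    raise ProfileConsistencyError(msg)


def read_profile(path: str | Path) -> CountryProfile:
    """Read and fully validate a country profile.

    A ``.json`` path is read as the canonical JSON document; a ``.yaml`` /
    ``.yml`` path is read as the CSV-dialect header, with ``deaths.csv`` and
    ``coverage.csv`` resolved relative to it (or to explicit ``deaths_file``
    / ``coverage_file`` keys in the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        return _read_profile_csv_dialect(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ProfileSchemaError(f"{path} is not valid JSON: {exc}") from exc
    return _profile_from_payload(payload)


def _read_profile_csv_dialect(header_path: Path) -> CountryProfile:
    try:
        header = yaml.safe_load(header_path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ProfileSchemaError(f"{header_path} is not valid YAML: {exc}") from exc
    if not isinstance(header, dict):
        raise ProfileSchemaError("CSV-dialect header must be a YAML mapping")

    base = header_path.parent
    deaths_path = base / header.pop("deaths_file", "deaths.csv")
    coverage_path = base / header.pop("coverage_file", "coverage.csv")

    deaths: dict[str, float] = {}
    causes: list[dict] = []
    with open(deaths_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"cause", "age_group", "count"} <= set(
            reader.fieldnames
        ):
            raise ProfileSchemaError(
                f"{deaths_path} must have columns cause, age_group, count"
            )
        for row in reader:
            code = row["cause"].strip()
            deaths[code] = float(row["count"])
            causes.append(
                {
                    "code": code,
                    "label": row.get("label", "").strip() or code.replace("_", " "),
                    "age_group": row["age_group"].strip(),
                }
            )

    coverage: dict[str, float] = {}
    with open(coverage_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"intervention", "coverage"} <= set(
            reader.fieldnames
        ):
            raise ProfileSchemaError(
                f"{coverage_path} must have columns intervention, coverage"
            )
        for row in reader:
            coverage[row["intervention"].strip()] = float(row["coverage"])

    payload = dict(header)
    payload["deaths"] = deaths
    payload["causes"] = causes
    payload["coverage"] = coverage
    return _profile_from_payload(payload)


def write_profile(profile: CountryProfile, path: str | Path) -> Path:
    """Write a profile as canonical JSON (0–1 scale, UTF-8, sorted keys).

    ``read_profile(write_profile(p))`` reproduces ``p`` field-for-field.
    """
    path = Path(path)
    payload = profile.model_dump(mode="json")
    payload["units"] = "proportion"
    path.write_text(
        json.dumps(payload, ensure_ascii=False, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return path
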