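"""Missed-opportunity orchestration.

Runs the one-at-a-time scale-up over a profile's whole intervention
catalogue, ranks interventions by total deaths averted, and assembles a
report with grouping views (by outcome group, delivery point, or cause of
death) and the caveats needed to read the numbers correctly.

Each intervention's figure is its *maximum possible impact*: the deaths it
alone would avert if scaled to the target while everything else stays at
current coverage.  Because different interventions avert the same
cause-specific deaths, per-intervention figures must never be summed —
the report carries that warning unconditionally and exposes no grand total.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .config import AnalysisConfig, GroupBy
from .engine import ImpactResult, intervention_impact
from .errors import ProfileConsistencyError, ProfileRangeError
from .family_planning import FP_CAVEAT, fp_deaths_averted
from .profile import AgeGroup, CountryProfile, validate_profile

__all__ = [
    "MissedOpportunityReport",
    "NO_SUMMING_CAVEAT",
    "run_missed_opportunity",
    "rank_interventions",
    "top_n",
    "group_results",
    "top_by_age_group",
    "filter_countries",
    "report_to_frame",
    "report_to_dict",
]

NO_SUMMING_CAVEAT = (
    "Each intervention's deaths averted is its maximum possible impact when "
    "scaled up alone; figures for different interventions must not be summed, "
    "as interventions averting the same cause-specific deaths would be double "
    "counted."
)

#: Marker used by top_by_age_group for groups where no intervention averts
#: any deaths.
NO_INTERVENTION = "none"


@dataclass(frozen=True)
class MissedOpportunityReport:
    """Ranked per-intervention results for one country.

    ``results`` is the ranked display list (interventions whose coverage was
    already at or above target, and hence avert zero deaths, are dropped);
    ``all_results`` retains every intervention, zeros included, in the same
    rank order for auditability.
    """

    country: str
    config: AnalysisConfig
    results: tuple[ImpactResult, ...]
    all_results: tuple[ImpactResult, ...]
    warnings: tuple[str, ...]
    groupings: Optional[dict[str, pd.DataFrame]] = None


def rank_interventions(results: Sequence[ImpactResult]) -> list[ImpactResult]:
    """Sort descending by total deaths averted; ties break by id ascending."""
    return sorted(results, key=lambda r: (-r.total_averted, r.intervention_id))


def run_missed_opportunity(
    profile: CountryProfile, config: AnalysisConfig | None = None
) -> MissedOpportunityReport:
    """Scale up every intervention individually and rank the results.

    The input profile is never mutated; identical inputs produce identical
    reports.
    """
    config = config or AnalysisConfig()
    findings = validate_profile(profile)
    if findings:
        raise ProfileConsistencyError(
            "invalid profile: " + "; ".join(str(f) for f in findings)
        )

    results: list[ImpactResult] = []
    fp_included = False
    for intervention in profile.catalogue:
        if intervention.is_family_planning:
            if config.include_family_planning:
                results.append(fp_deaths_averted(profile, config))
                fp_included = True
        else:
            results.append(
                intervention_impact(
                    profile,
                    intervention.id,
                    config.target_coverage,
                    config.include_stillbirths_in_total,
                )
            )

    ranked = tuple(rank_interventions(results))
    display = tuple(r for r in ranked if r.total_averted > 0)
    warnings = [NO_SUMMING_CAVEAT]
    if fp_included:
        warnings.append(FP_CAVEAT)

    report = MissedOpportunityReport(
        country=profile.country,
        config=config,
        results=display,
        all_results=ranked,
        warnings=tuple(warnings),
    )
    if config.group_by is not GroupBy.NONE:
        report = replace(
            report, groupings={config.group_by.value: group_results(report, config.group_by)}
        )
    return report


def top_n(report: MissedOpportunityReport, n: int) -> MissedOpportunityReport:
    """Truncate the ranked display to the top ``n`` interventions.

    The full ranked list (zeros included) stays available in
    ``all_results``.
    """
    if n < 1:
        raise ProfileRangeError(f"n must be >= 1, got {n}")
    return replace(report, results=report.results[:n])


def group_results(
    report: MissedOpportunityReport, dimension: GroupBy | str
) -> pd.DataFrame:
    """Reorganize the ranked results along one dimension.

    * ``outcome`` — one row per intervention, one column per age group.
    * ``delivery_point`` — interventions bucketed by delivery point, ranked
      within each bucket.
    * ``cause`` — one row per intervention, one column per cause of death.

    Cell sums across each table equal the corresponding un-grouped
    aggregates.
    """
    dimension = GroupBy(dimension)
    results = report.results
    if dimension is GroupBy.OUTCOME:
        rows = {
            r.intervention_id: {g.value: r.averted_by_age_group[g] for g in AgeGroup}
            for r in results
        }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("intervention")
    if dimension is GroupBy.DELIVERY_POINT:
        records = []
        for r in results:  # results already globally ranked
            records.append(
                {
                    "delivery_point": r.delivery_point,
                    "intervention": r.intervention_id,
                    "total_averted": r.total_averted,
                }
            )
        frame = pd.DataFrame.from_records(
            records, columns=["delivery_point", "intervention", "total_averted"]
        )
        frame["rank_in_group"] = (
            frame.groupby("delivery_point")["total_averted"]
            .rank(ascending=False, method="first")
            .astype(int)
        )
        return frame.sort_values(
            ["delivery_point", "rank_in_group"], kind="stable"
        ).reset_index(drop=True)
    if dimension is GroupBy.CAUSE:
        rows = {r.intervention_id: dict(r.averted_by_cell) for r in results}
        return (
            pd.DataFrame.from_dict(rows, orient="index")
            .fillna(0.0)
            .rename_axis("intervention")
        )
    raise ValueError(f"cannot group by {dimension!r}")


def top_by_age_group(report: MissedOpportunityReport) -> dict[AgeGroup, str]:
    """The intervention averting the most deaths in each age group.

    Groups where every intervention averts zero deaths map to the explicit
    marker ``"none"``.  Ties break by intervention id ascending.
    """
    out: dict[AgeGroup, str] = {}
    for group in AgeGroup:
        best_id, best_value = NO_INTERVENTION, 0.0
        for r in sorted(report.all_results, key=lambda r: r.intervention_id):
            value = r.averted_by_age_group.get(group, 0.0)
            if value > best_value:
                best_id, best_value = r.intervention_id, value
        out[group] = best_id
    return out


def filter_countries(
    u5mr_by_country: Mapping[str, float], threshold: float = 20.0
) -> list[str]:
    """Countries whose under-5 mortality rate meets the inclusion threshold
    (boundary inclusive), sorted by name."""
    for country, u5mr in u5mr_by_country.items():
        if u5mr < 0:
            raise ProfileRangeError(f"u5mr for {country!r} must be >= 0, got {u5mr}")
    return sorted(c for c, u5mr in u5mr_by_country.items() if u5mr >= threshold)


# ---------------------------------------------------------------------------
# serialization


def report_to_frame(
    report: MissedOpportunityReport, include_zeros: bool = False
) -> pd.DataFrame:
    """Tabulate a report: one row per intervention with rank, per-age-group
    deaths averted and the total, at full precision."""
    results = report.all_results if include_zeros else report.results
    records = []
    for rank, r in enumerate(results, start=1):
        row = {
            "rank": rank,
            "intervention": r.intervention_id,
            "name": r.name,
            "delivery_point": r.delivery_point,
        }
        for g in AgeGroup:
            row[g.value] = r.averted_by_age_group.get(g, 0.0)
        row["total_averted"] = r.total_averted
        records.append(row)
    columns = ["rank", "intervention", "name", "delivery_point"]
    columns += [g.value for g in AgeGroup] + ["total_averted"]
    return pd.DataFrame.from_records(records, columns=columns)


def report_to_dict(report: MissedOpportunityReport) -> dict:
    """Full report as a JSON-serializable dict (machine-readable output)."""

    def result_payload(r: ImpactResult) -> dict:
        payload = {
            "intervention": r.intervention_id,
            "name": r.name,
            "delivery_point": r.delivery_point,
            "averted_by_cell": dict(sorted(r.averted_by_cell.items())),
            "averted_by_age_group": {
                g.value: r.averted_by_age_group.get(g, 0.0) for g in AgeGroup
            },
            "total_averted": r.total_averted,
        }
        if r.fp_pathways is not None:
            payload["fp_pathways"] = {
                "births_pathway": r.fp_pathways.births_pathway,
                "risky_births_pathway": r.fp_pathways.risky_births_pathway,
            }
        if r.caveats:
            payload["caveats"] = list(r.caveats)
        return payload

    payload = {
        "country": report.country,
        "config": report.config.model_dump(mode="json"),
        "results": [result_payload(r) for r in report.results],
        "all_results": [result_payload(r) for r in report.all_results],
        "warnings": list(report.warnings),
    }
    if report.groupings:
        payload["groupings"] = {
            name: frame.reset_index().to_dict(orient="records")
            for name, frame in report.groupings.items()
        }
    return payload
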