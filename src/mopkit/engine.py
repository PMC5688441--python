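"""Deterministic deaths-averted arithmetic for a single intervention.

The model is a one-year cohort: baseline deaths are annual counts observed
under current coverage c0, and scaling one intervention to coverage c1 while
holding everything else fixed averts

    averted = D · E·AF·(c1 − c0) / (1 − E·AF·c0)

per (cause, age group) cell, where D is the baseline death count for the
cause, E the intervention's effectiveness against it and AF the affected
fraction.  The denominator removes the effect already embedded in the
observed baseline (residual scaling): D/(1 − E·AF·c0) is the counterfactual
death count at zero coverage, of which a fraction E·AF·c is averted at
coverage c.  At c0 = 0 the expression reduces to the naive D·E·AF·c1.

Coverage is never scaled down: the engine uses max(c0, target), so an
intervention already at or above the target averts exactly zero deaths.
Deaths are kept real-valued throughout; rounding happens only at display
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    DegenerateInputError,
    FamilyPlanningRoutingError,
    ProfileRangeError,
)
from .profile import AgeGroup, CountryProfile

__all__ = [
    "CoverageChange",
    "FPPathways",
    "ImpactResult",
    "scaled_coverage",
    "deaths_averted_cell",
    "intervention_impact",
]


def _require_proportion(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ProfileRangeError(f"{name} must be a proportion in [0, 1], got {value}")


@dataclass(frozen=True)
class CoverageChange:
    """A single intervention's coverage move; the engine never scales down."""

    intervention_id: str
    baseline: float
    target: float

    def __post_init__(self) -> None:
        _require_proportion(self.baseline, "baseline")
        _require_proportion(self.target, "target")
        if self.target < self.baseline:
            raise ProfileRangeError(
                f"target coverage {self.target} below baseline {self.baseline}: "
                "interventions are never scaled down"
            )


@dataclass(frozen=True)
class FPPathways:
    """Decomposition of family-planning deaths averted into its two routes:
    fewer births (dominant) and a safer mix of births (minor)."""

    births_pathway: float
    risky_births_pathway: float


@dataclass(frozen=True)
class ImpactResult:
    """Deaths averted by one intervention, by cause and by age group."""

    intervention_id: str
    name: str
    delivery_point: str
    averted_by_cell: dict[str, float]
    averted_by_age_group: dict[AgeGroup, float]
    total_averted: float
    fp_pathways: Optional[FPPathways] = None
    caveats: tuple[str, ...] = field(default=())


def scaled_coverage(current: float, target: float) -> float:
    """Coverage after the scale-up rule: up to ``target``, never down."""
    _require_proportion(current, "current coverage")
    _require_proportion(target, "target coverage")
    return max(current, target)


def deaths_averted_cell(
    baseline_deaths: float,
    effectiveness: float,
    affected_fraction: float,
    c0: float,
    c1: float,
) -> float:
    """Deaths averted in one (cause, age group) cell.

    Parameters
    ----------
    baseline_deaths
        Annual deaths from the cause, observed under coverage ``c0``.
    effectiveness, affected_fraction
        Proportional mortality reduction among the covered, and the share of
        the cause's deaths the intervention can address.
    c0, c1
        Coverage before and after scale-up, ``c1 >= c0``.
    """
    if baseline_deaths < 0:
        raise ProfileRangeError(f"baseline_deaths must be >= 0, got {baseline_deaths}")
    _require_proportion(effectiveness, "effectiveness")
    _require_proportion(affected_fraction, "affected_fraction")
    _require_proportion(c0, "c0")
    _require_proportion(c1, "c1")
    if c1 < c0:
        raise ProfileRangeError(f"c1 ({c1}) must be >= c0 ({c0})")
    impact = effectiveness * affected_fraction
    denom = 1.0 - impact * c0
    if denom <= 0.0:
        raise DegenerateInputError(
            "effectiveness x affected_fraction x c0 reaches 1: no deaths remain "
            "at baseline, the residual-scaling denominator is not positive"
        )
    return baseline_deaths * impact * (c1 - c0) / denom


def aggregate_cells(
    profile: CountryProfile,
    averted_by_cell: dict[str, float],
    include_stillbirths_in_total: bool = True,
) -> tuple[dict[AgeGroup, float], float]:
    """Sum per-cell deaths averted into per-age-group and total figures."""
    cmap = profile.cause_map()
    by_group: dict[AgeGroup, float] = {g: 0.0 for g in AgeGroup}
    for cause, value in averted_by_cell.items():
        by_group[cmap[cause].age_group] += value
    total = sum(
        value
        for group, value in by_group.items()
        if include_stillbirths_in_total or group is not AgeGroup.STILLBIRTH
    )
    return by_group, total


def intervention_impact(
    profile: CountryProfile,
    intervention_id: str,
    target: float,
    include_stillbirths_in_total: bool = True,
) -> ImpactResult:
    """Deaths averted by scaling one intervention to ``target``, holding all
    other coverages fixed.

    The family-planning intervention has no effectiveness entries and a
    different mechanism; routing it here raises
    :class:`~mopkit.errors.FamilyPlanningRoutingError`.
    """
    intervention = profile.intervention(intervention_id)
    if intervention.is_family_planning:
        raise FamilyPlanningRoutingError(
            f"{intervention_id!r} is the family-planning intervention; use "
            "mopkit.family_planning.fp_deaths_averted"
        )
    c0 = profile.coverage[intervention_id]
    c1 = scaled_coverage(c0, target)

    averted_by_cell: dict[str, float] = {}
    for entry in intervention.entries:
        averted_by_cell[entry.cause] = deaths_averted_cell(
            profile.deaths[entry.cause],
            entry.effectiveness,
            entry.affected_fraction,
            c0,
            c1,
        )
    by_group, total = aggregate_cells(
        profile, averted_by_cell, include_stillbirths_in_total
    )
    return ImpactResult(
        intervention_id=intervention.id,
        name=intervention.name,
        delivery_point=intervention.delivery_point.value,
        averted_by_cell=averted_by_cell,
        averted_by_age_group=by_group,
        total_averted=total,
    )
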