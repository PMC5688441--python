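"""The family-planning (reducing unmet need) intervention.

Unlike the coverage interventions, family planning does not treat a cause of
death directly.  The scenario raises the contraceptive prevalence rate (CPR)
until unmet need for contraception falls to a floor (default 10%), converting
unmet need into use one-to-one.  Deaths are then averted through two
pathways:

* **births pathway** (dominant): higher contraceptive prevalence lowers
  fertility.  Births are scaled by the ratio of proximate-determinants
  contraception indices C = 1 − 1.08·e·CPR (e = method-mix average
  effectiveness), and each birth not occurring removes the per-birth risk of
  a maternal death, a stillbirth, a neonatal death and a 1–59-month death,
  with per-birth risks taken from the profile's own baseline deaths ÷ births.

* **risky-births pathway** (minor): among the births that still occur,
  higher CPR shifts some out of a high-risk stratum (short birth intervals,
  extreme maternal age, high parity) whose mortality is elevated by a
  relative risk, averting the excess deaths of the births that moved.

Because most of the averted deaths belong to children never conceived, every
family-planning result carries a caveat that some users may choose not to
count them as deaths averted.
"""

from __future__ import annotations

from .config import AnalysisConfig
from .engine import FPPathways, ImpactResult, aggregate_cells
from .errors import DegenerateInputError, ProfileRangeError
from .profile import AgeGroup, CountryProfile, DeliveryPoint

__all__ = [
    "FPScenario",
    "FP_CAVEAT",
    "reduce_unmet_need",
    "births_after_scaleup",
    "fp_deaths_averted",
]

#: Constant of the proximate-determinants contraception index: contraception
#: index C = 1 - 1.08 * effectiveness * CPR, the 1.08 adjusting for fecundity
#: of the user population.
BONGAARTS_COEFFICIENT = 1.08

FP_CAVEAT = (
    "Most deaths averted by reducing unmet need for family planning are "
    "deaths of children never born; some users may choose not to consider "
    "these as deaths averted."
)

FP_DEFAULT_ID = "fp_unmet_need"
FP_DEFAULT_NAME = "Reducing unmet need for family planning"


class FPScenario:
    """Before/after snapshot of the unmet-need scale-up.

    Conserves cpr + unmet_need: every point of unmet need removed becomes a
    point of contraceptive prevalence.
    """

    def __init__(
        self,
        cpr0: float,
        unmet0: float,
        cpr1: float,
        unmet1: float,
        births0: float,
        births1: float,
    ) -> None:
        if cpr1 < cpr0 or unmet1 > unmet0:
            raise ProfileRangeError("scale-up must raise CPR and lower unmet need")
        if abs((cpr1 - cpr0) - (unmet0 - unmet1)) > 1e-9:
            raise ProfileRangeError("CPR gain must equal the unmet-need reduction")
        if births1 > births0:
            raise ProfileRangeError("births cannot increase under the scale-up")
        self.cpr0, self.unmet0 = cpr0, unmet0
        self.cpr1, self.unmet1 = cpr1, unmet1
        self.births0, self.births1 = births0, births1


def reduce_unmet_need(
    cpr0: float, unmet0: float, floor: float = 0.10
) -> tuple[float, float]:
    """Transfer unmet need into contraceptive prevalence down to ``floor``.

    Unmet need already at or below the floor is left unchanged (the analogue
    of the no-scale-down rule for coverage interventions).
    """
    if not (0.0 <= cpr0 <= 1.0) or not (0.0 <= unmet0 <= 1.0):
        raise ProfileRangeError("cpr0 and unmet0 must be proportions in [0, 1]")
    if not (0.0 <= floor <= 1.0):
        raise ProfileRangeError("floor must be a proportion in [0, 1]")
    if cpr0 + unmet0 > 1.0 + 1e-12:
        raise ProfileRangeError(f"cpr0 + unmet0 = {cpr0 + unmet0} exceeds 1")
    transfer = max(0.0, unmet0 - floor)
    return cpr0 + transfer, unmet0 - transfer


def births_after_scaleup(
    births0: float,
    cpr0: float,
    cpr1: float,
    contraceptive_effectiveness: float,
) -> float:
    """Births after the CPR rise, via the contraception-index ratio.

    births1 = births0 · (1 − 1.08·e·cpr1) / (1 − 1.08·e·cpr0).  With e = 0
    (ineffective contraception) births are unchanged for any CPR move.
    """
    if births0 < 0:
        raise ProfileRangeError("births0 must be >= 0")
    e = contraceptive_effectiveness
    if not (0.0 <= e <= 1.0):
        raise ProfileRangeError("contraceptive_effectiveness must be in [0, 1]")
    c0 = 1.0 - BONGAARTS_COEFFICIENT * e * cpr0
    c1 = 1.0 - BONGAARTS_COEFFICIENT * e * cpr1
    if c0 <= 0.0 or c1 <= 0.0:
        raise DegenerateInputError(
            "contraception index 1 - 1.08*e*CPR is not positive; the births "
            "multiplier is undefined"
        )
    # ratio first: when cpr1 == cpr0 the multiplier is exactly 1.0
    return births0 * (c1 / c0)


def fp_deaths_averted(
    profile: CountryProfile, config: AnalysisConfig | None = None
) -> ImpactResult:
    """Deaths averted by reducing unmet need to the configured floor.

    Returns an :class:`~mopkit.engine.ImpactResult` whose ``fp_pathways``
    field decomposes the total into the births pathway and the risky-births
    pathway.  The result is exactly zero (both pathways) when unmet need is
    already at or below the floor.
    """
    config = config or AnalysisConfig()
    fp = profile.fp_params

    cpr0, unmet0 = profile.cpr, profile.unmet_need
    cpr1, unmet1 = reduce_unmet_need(cpr0, unmet0, config.unmet_need_floor)
    births0 = profile.live_births
    births1 = births_after_scaleup(births0, cpr0, cpr1, fp.contraceptive_effectiveness)
    # constructing the scenario asserts the conservation invariants
    FPScenario(cpr0, unmet0, cpr1, unmet1, births0, births1)

    deaths_by_group = profile.deaths_by_age_group()
    per_birth_risk = {g: deaths_by_group[g] / births0 for g in AgeGroup}

    # births pathway: each birth averted removes each group's per-birth risk
    births_averted = births0 - births1
    pathway_a = {g: births_averted * per_birth_risk[g] for g in AgeGroup}

    # risky-births pathway: among remaining births, a slice of the high-risk
    # stratum moves to baseline risk, averting its excess mortality
    cpr_gain_points = (cpr1 - cpr0) * 100.0
    delta_f = min(
        fp.risky_fraction_shift_per_cpr_point * cpr_gain_points,
        fp.risky_birth_fraction,
    )
    rr = fp.risky_relative_risk
    excess = 1.0 + fp.risky_birth_fraction * (rr - 1.0)
    pathway_b = {
        g: births1 * delta_f * (rr - 1.0) * (per_birth_risk[g] / excess)
        for g in AgeGroup
    }

    # distribute each group's averted deaths over its causes proportionally
    # to the baseline cause mix
    cmap = profile.cause_map()
    averted_by_cell: dict[str, float] = {}
    for code, baseline in profile.deaths.items():
        group = cmap[code].age_group
        group_total = deaths_by_group[group]
        share = baseline / group_total if group_total > 0 else 0.0
        averted_by_cell[code] = (pathway_a[group] + pathway_b[group]) * share

    by_group, total = aggregate_cells(
        profile, averted_by_cell, config.include_stillbirths_in_total
    )

    fp_iv = profile.family_planning_intervention()
    return ImpactResult(
        intervention_id=fp_iv.id if fp_iv else FP_DEFAULT_ID,
        name=fp_iv.name if fp_iv else FP_DEFAULT_NAME,
        delivery_point=(
            fp_iv.delivery_point.value if fp_iv else DeliveryPoint.CLINIC_ESSENTIAL.value
        ),
        averted_by_cell=averted_by_cell,
        averted_by_age_group=by_group,
        total_averted=total,
        fp_pathways=FPPathways(
            births_pathway=sum(pathway_a.values()) - (
                pathway_a[AgeGroup.STILLBIRTH]
                if not config.include_stillbirths_in_total
                else 0.0
            ),
            risky_births_pathway=sum(pathway_b.values()) - (
                pathway_b[AgeGroup.STILLBIRTH]
                if not config.include_stillbirths_in_total
                else 0.0
            ),
        ),
        caveats=(FP_CAVEAT,),
    )
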