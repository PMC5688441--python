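"""Deterministic synthetic country profiles.

Real missed-opportunity runs draw on a national database of coverage
estimates and cause-of-death envelopes that cannot be redistributed here.
This module generates profiles with the same *structure*: plausible death
envelopes for the four outcome groups consistent with a stated under-5
mortality rate, cause mixes drawn around typical high-burden-country
patterns, and an intervention catalogue spanning delivery points from
community case management to CEmOC facilities, with coverage levels spread
across the unit interval so that every engine rule (including the
no-scale-down rule) is exercised.

All draws come from a seeded numpy PCG64 generator recorded in the profile
metadata; identical seeds yield identical profiles on any platform.

:func:`generate_benchmark_suite` builds four engineered profiles with
distinct child cause mixes (malaria-, pneumonia-, or diarrhea-dominant) in
which facility childbirth care dominates the maternal, stillbirth and
neonatal groups and the cause-matched community treatment dominates the
1–59-month group — the qualitative pattern expected of high-burden
settings.  These profiles are engineered test scaffolding, not fits to any
real country.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pydantic

from .profile import (
    DEFAULT_CAUSES,
    AgeGroup,
    CountryProfile,
    DeliveryPoint,
    EffectivenessEntry,
    FamilyPlanningParams,
    InterventionDefinition,
)

__all__ = ["FixtureSpec", "generate_profile", "generate_benchmark_suite"]

_GENERATOR_TAG = {"generator": "mopkit-synth", "rng": "numpy-PCG64", "version": "1"}

# demographic rates of a typical high-burden setting (per live birth unless
# noted): maternal mortality ratio 400/100k, stillbirth rate 22/1000,
# neonatal share of under-5 deaths ~45%
_MMR_PER_100K = 400.0
_STILLBIRTH_RATE_PER_1K = 22.0
_NEONATAL_SHARE_OF_U5 = 0.45

# baseline within-group cause weights (normalized per group at draw time)
_BASE_CAUSE_WEIGHTS: dict[str, float] = {
    "hemorrhage": 0.27, "sepsis": 0.13, "hypertensive_disorders": 0.18,
    "obstructed_labor": 0.10, "abortion": 0.10, "other_maternal": 0.22,
    "antepartum": 0.55, "intrapartum": 0.45,
    "prematurity": 0.33, "intrapartum_asphyxia": 0.27, "sepsis_pneumonia": 0.22,
    "congenital": 0.08, "tetanus": 0.02, "other_neonatal": 0.08,
    "pneumonia": 0.22, "diarrhea": 0.15, "malaria": 0.18, "measles": 0.04,
    "meningitis": 0.05, "injury": 0.07, "other_child": 0.29,
}

# intervention templates: (id, name, delivery point, ((cause, E, AF), ...))
_TEMPLATES: tuple[tuple[str, str, DeliveryPoint, tuple[tuple[str, float, float], ...]], ...] = (
    (
        "labor_delivery_cemoc",
        "Labor and delivery management (CEmOC level)",
        DeliveryPoint.CEMOC_FACILITY,
        (
            ("hemorrhage", 0.75, 0.95), ("sepsis", 0.60, 0.95),
            ("hypertensive_disorders", 0.65, 0.95), ("obstructed_labor", 0.80, 0.95),
            ("other_maternal", 0.35, 0.80), ("intrapartum", 0.65, 0.90),
            ("intrapartum_asphyxia", 0.65, 0.90), ("prematurity", 0.30, 0.70),
        ),
    ),
    (
        "labor_delivery_bemoc",
        "Labor and delivery management (BEmOC level)",
        DeliveryPoint.BEMOC_FACILITY,
        (
            ("hemorrhage", 0.45, 0.95), ("sepsis", 0.40, 0.95),
            ("hypertensive_disorders", 0.40, 0.95), ("obstructed_labor", 0.40, 0.95),
            ("intrapartum", 0.40, 0.90), ("intrapartum_asphyxia", 0.40, 0.90),
            ("prematurity", 0.18, 0.70),
        ),
    ),
    (
        "labor_delivery_essential",
        "Labor and delivery management (Essential care level)",
        DeliveryPoint.CLINIC_ESSENTIAL,
        (
            ("sepsis", 0.25, 0.90), ("intrapartum", 0.20, 0.90),
            ("intrapartum_asphyxia", 0.20, 0.90), ("prematurity", 0.10, 0.70),
        ),
    ),
    (
        "neonatal_sepsis_care",
        "Full supportive care for neonatal sepsis/pneumonia",
        DeliveryPoint.BEMOC_FACILITY,
        (("sepsis_pneumonia", 0.80, 0.80),),
    ),
    (
        "prematurity_care",
        "Full supportive care for prematurity",
        DeliveryPoint.BEMOC_FACILITY,
        (("prematurity", 0.68, 0.75),),
    ),
    (
        "balanced_energy_supp",
        "Balanced energy supplementation in pregnancy",
        DeliveryPoint.OUTREACH,
        (("antepartum", 0.38, 0.60), ("prematurity", 0.20, 0.40)),
    ),
    (
        "act_malaria",
        "ACTs for treatment of malaria",
        DeliveryPoint.COMMUNITY,
        (("malaria", 0.85, 0.95),),
    ),
    (
        "ors_diarrhea",
        "Oral rehydration solution for diarrhea",
        DeliveryPoint.COMMUNITY,
        (("diarrhea", 0.93, 0.90),),
    ),
    (
        "oral_antibiotics_pneumonia",
        "Oral antibiotics for pneumonia",
        DeliveryPoint.COMMUNITY,
        (("pneumonia", 0.70, 0.90),),
    ),
    (
        "measles_vaccine",
        "Measles vaccination",
        DeliveryPoint.OUTREACH,
        (("measles", 0.85, 0.95),),
    ),
    (
        "itn_malaria",
        "Insecticide-treated bednets",
        DeliveryPoint.COMMUNITY,
        (("malaria", 0.55, 0.85),),
    ),
    (
        "clean_birth_practices",
        "Clean birth and postnatal practices",
        DeliveryPoint.COMMUNITY,
        (("tetanus", 0.40, 0.80), ("sepsis_pneumonia", 0.20, 0.60), ("sepsis", 0.20, 0.60)),
    ),
    (
        "mgso4_preeclampsia",
        "Magnesium sulfate for pre-eclampsia/eclampsia",
        DeliveryPoint.CLINIC_ESSENTIAL,
        (("hypertensive_disorders", 0.55, 0.85),),
    ),
    (
        "water_connection",
        "Water connection in the home",
        DeliveryPoint.COMMUNITY,
        (("diarrhea", 0.25, 0.95),),
    ),
)

_FP_TEMPLATE = InterventionDefinition(
    id="fp_unmet_need",
    name="Reducing unmet need for family planning",
    delivery_point=DeliveryPoint.CLINIC_ESSENTIAL,
    entries=(),
    is_family_planning=True,
)


class FixtureSpec(pydantic.BaseModel):
    """Parameters of one synthetic profile.

    ``n_interventions`` counts coverage interventions (the family-planning
    row is added on top when ``fp_present``).  ``births_scale`` is annual
    live births; 100,000 keeps results readable while leaving all rates
    realistic.  The default ``u5mr`` of 60 per 1,000 sits in the middle of
    the range of countries the analysis targets (u5mr >= 20).
    """

    model_config = pydantic.ConfigDict(frozen=True)

    seed: int = 1
    n_interventions: int = 12
    births_scale: float = 100_000.0
    u5mr: float = 60.0
    cause_weights: Optional[dict[str, float]] = None
    coverage_range: tuple[float, float] = (0.02, 0.95)
    fp_present: bool = True

    @pydantic.field_validator("n_interventions")
    @classmethod
    def _at_least_one(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_interventions must be >= 1")
        return v

    @pydantic.field_validator("coverage_range")
    @classmethod
    def _ordered_unit_range(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("coverage_range must be ordered and within [0, 1]")
        return v


def _draw_deaths(
    rng: np.random.Generator,
    births: float,
    u5mr: float,
    cause_weights: Optional[dict[str, float]],
    jitter: bool = True,
) -> dict[str, float]:
    """Death counts per cause, exactly consistent with the stated u5mr."""
    under5 = births * u5mr / 1000.0
    neonatal_share = _NEONATAL_SHARE_OF_U5
    if jitter:
        neonatal_share = float(np.clip(neonatal_share + rng.normal(0, 0.03), 0.30, 0.60))
    group_totals = {
        AgeGroup.MATERNAL: births * _MMR_PER_100K / 100_000.0,
        AgeGroup.STILLBIRTH: births * _STILLBIRTH_RATE_PER_1K / 1000.0,
        AgeGroup.NEONATAL: under5 * neonatal_share,
        AgeGroup.CHILD: under5 * (1.0 - neonatal_share),
    }
    deaths: dict[str, float] = {}
    for group in AgeGroup:
        codes = [c.code for c in DEFAULT_CAUSES if c.age_group is group]
        weights = np.array(
            [
                (cause_weights or {}).get(code, _BASE_CAUSE_WEIGHTS[code])
                for code in codes
            ]
        )
        if jitter:
            weights = rng.dirichlet(weights * 60.0)
        weights = weights / weights.sum()
        for code, w in zip(codes, weights):
            deaths[code] = float(group_totals[group] * w)
    return deaths


def _build_catalogue(
    rng: np.random.Generator, n_interventions: int, jitter_effects: bool = True
) -> list[InterventionDefinition]:
    catalogue: list[InterventionDefinition] = []
    for i in range(n_interventions):
        tid, name, point, cells = _TEMPLATES[i % len(_TEMPLATES)]
        if i >= len(_TEMPLATES):  # wrap-around gets a distinct id
            tid, name = f"{tid}_{i}", f"{name} (variant {i})"
        entries = []
        for cause, eff, af in cells:
            if jitter_effects:
                eff = float(np.clip(eff * rng.uniform(0.85, 1.15), 0.10, 0.95))
                af = float(np.clip(af * rng.uniform(0.90, 1.10), 0.10, 0.95))
            group = next(c.age_group for c in DEFAULT_CAUSES if c.code == cause)
            entries.append(
                EffectivenessEntry(
                    cause=cause, age_group=group, effectiveness=eff, affected_fraction=af
                )
            )
        catalogue.append(
            InterventionDefinition(
                id=tid, name=name, delivery_point=point, entries=tuple(entries)
            )
        )
    return catalogue


def generate_profile(spec: FixtureSpec) -> CountryProfile:
    """Generate one valid synthetic profile; identical spec, identical profile.

    Coverage is drawn uniformly within ``spec.coverage_range``, except that
    the first two coverage interventions are pinned to the range's ends so
    the catalogue always contains both a near-floor coverage and (with the
    default range) one above the 90% target, exercising the no-scale-down
    rule.
    """
    rng = np.random.default_rng(spec.seed)
    births = float(spec.births_scale)
    deaths = _draw_deaths(rng, births, spec.u5mr, spec.cause_weights)
    catalogue = _build_catalogue(rng, spec.n_interventions)

    lo, hi = spec.coverage_range
    coverage = {iv.id: float(rng.uniform(lo, hi)) for iv in catalogue}
    ids = [iv.id for iv in catalogue]
    coverage[ids[0]] = lo + 0.01 * (hi - lo)
    if len(ids) > 1:
        coverage[ids[1]] = hi - 0.01 * (hi - lo)

    cpr = float(rng.uniform(0.15, 0.45))
    unmet = float(rng.uniform(0.12, min(0.35, 1.0 - cpr)))
    if spec.fp_present:
        catalogue.append(_FP_TEMPLATE)
        coverage[_FP_TEMPLATE.id] = cpr

    return CountryProfile(
        country=f"Synthesia-{spec.seed}",
        year=2016,
        live_births=births,
        women_15_49=births * 4.2,
        u5mr=spec.u5mr,
        cpr=cpr,
        unmet_need=unmet,
        causes=DEFAULT_CAUSES,
        deaths=deaths,
        coverage=coverage,
        catalogue=tuple(catalogue),
        fp_params=FamilyPlanningParams(),
        metadata={**_GENERATOR_TAG, "seed": str(spec.seed)},
    )


# engineered child cause mixes and treatment coverages for the benchmark
# suite: (name, births, u5mr, child-mix overrides, low-coverage treatment id)
_BENCHMARKS: tuple[tuple[str, float, float, dict[str, float], str], ...] = (
    ("high-malaria", 3_000_000.0, 90.0, {"malaria": 0.45, "diarrhea": 0.12, "pneumonia": 0.14}, "act_malaria"),
    ("high-pneumonia", 3_200_000.0, 60.0, {"malaria": 0.06, "diarrhea": 0.13, "pneumonia": 0.40}, "oral_antibiotics_pneumonia"),
    ("low-malaria-high-diarrhea", 1_500_000.0, 50.0, {"malaria": 0.05, "diarrhea": 0.40, "pneumonia": 0.16}, "ors_diarrhea"),
    ("high-diarrhea", 2_000_000.0, 55.0, {"malaria": 0.10, "diarrhea": 0.38, "pneumonia": 0.15}, "ors_diarrhea"),
)


def generate_benchmark_suite(seed: int = 1) -> list[CountryProfile]:
    """Four engineered profiles with contrasting child cause mixes.

    In every profile the CEmOC childbirth-care intervention has low coverage
    and strong effects on maternal, stillbirth and neonatal causes, and the
    community treatment matching the dominant child cause has low coverage —
    so each profile realizes the expected qualitative ranking pattern.
    Effectiveness values are the fixed template values (no jitter); the seed
    only perturbs demography.
    """
    profiles: list[CountryProfile] = []
    for offset, (name, births, u5mr, child_mix, low_cov_id) in enumerate(_BENCHMARKS):
        rng = np.random.default_rng(seed + offset)
        deaths = _draw_deaths(rng, births, u5mr, child_mix, jitter=False)
        catalogue = _build_catalogue(rng, len(_TEMPLATES), jitter_effects=False)

        coverage: dict[str, float] = {}
        for iv in catalogue:
            coverage[iv.id] = float(rng.uniform(0.35, 0.65))
        coverage["labor_delivery_cemoc"] = 0.08
        coverage["labor_delivery_bemoc"] = 0.20
        coverage["balanced_energy_supp"] = 0.05
        coverage[low_cov_id] = 0.12
        coverage["measles_vaccine"] = 0.93  # above target: exercises no-scale-down

        cpr, unmet = 0.25, 0.30
        catalogue.append(_FP_TEMPLATE)
        coverage[_FP_TEMPLATE.id] = cpr

        profiles.append(
            CountryProfile(
                country=name,
                year=2016,
                live_births=births,
                women_15_49=births * 4.2,
                u5mr=u5mr,
                cpr=cpr,
                unmet_need=unmet,
                causes=DEFAULT_CAUSES,
                deaths=deaths,
                coverage=coverage,
                catalogue=tuple(catalogue),
                fp_params=FamilyPlanningParams(),
                metadata={**_GENERATOR_TAG, "seed": str(seed), "suite": name},
            )
        )
    return profiles
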