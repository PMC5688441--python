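# Methods

## Model

mopkit implements a deterministic one-year cohort model of intervention
scale-up. A country profile supplies annual baseline deaths by cause for
four outcome groups — maternal, stillbirth, neonatal (0–1 month) and child
(1–59 months) — together with live births, women of reproductive age,
per-intervention coverage, and an intervention catalogue whose entries give
each intervention's effectiveness *E* and affected fraction *AF* per cause.

For one intervention, coverage moves from its current level c₀ to
c₁ = max(c₀, target); all other coverages stay fixed. Deaths averted per
(cause, age group) cell follow the residual-scaling identity

    averted = D · E·AF·(c₁ − c₀) / (1 − E·AF·c₀),

chosen because observed baseline deaths D are *net of current coverage*:
D/(1 − E·AF·c₀) reconstructs the zero-coverage death envelope, of which
the fraction E·AF·c is averted at coverage c. Consequences that the tests
assert: averted = 0 when c₁ = c₀; averted ≤ D always, with equality only
for a perfect intervention (E = AF = 1) scaled from 0 to 1; the form
reduces to D·E·AF·c₁ at c₀ = 0; and averted is strictly increasing in E,
AF and the coverage gain.

Assumptions: a single annual cohort (no aging, no multi-year projection);
no interactions between interventions (strictly one-at-a-time, so each
figure is a maximum-possible impact and figures must not be summed across
interventions); no herd effects; effectiveness values are context-free
constants supplied by the profile.

## Family-planning pathway

The family-planning scenario transfers unmet need for contraception
one-to-one into contraceptive prevalence (CPR) until unmet need reaches a
floor (default 10%), mirroring the no-scale-down rule: unmet need already
at or below the floor is untouched, and CPR + unmet need is conserved.

Births respond through the proximate-determinants contraception index
C = 1 − 1.08·e·CPR: births₁ = births₀ · C(cpr₁)/C(cpr₀), with e the
method-mix average effectiveness. Deaths averted decompose into:

* **births pathway** — births averted × the profile's own per-birth death
  risk in each age group (baseline deaths ÷ baseline births). Using the
  profile's own risks keeps the pathway self-consistent with its death
  envelope; no external life tables are needed.
* **risky-births pathway** — among remaining births, the high-risk stratum
  (short birth spacing, extreme maternal age, high parity) shrinks by
  Δf = shift_per_CPR_point × CPR gain in points, capped at the stratum
  size; the averted deaths are births₁ · Δf · (RR − 1) · r_normal, where
  r_normal = r / (1 + f·(RR − 1)) is the non-risky per-birth risk implied
  by the observed average risk r.

Defaults (all overridable per profile): contraceptive effectiveness 0.85,
high-risk birth fraction 0.25, relative risk 1.5, shift 0.002 per CPR
point. These are documented working values, not fitted estimates; they are
deliberately sized so the risky-births pathway stays a small share of the
total, which is the qualitatively expected behaviour of this mechanism.
The risky-birth parameterization is a transparent stand-in for a full
birth-interval/parity risk matrix, which is out of scope. Because the
births pathway averts deaths of children never conceived, every
family-planning result carries an interpretive caveat string, and a config
flag (`include_family_planning=False`) removes the intervention from
rankings entirely.

## Orchestration

`run_missed_opportunity` computes every intervention's solo impact, ranks
descending by total deaths averted with ties broken by intervention id
(determinism requires a total order; id order is arbitrary but stable), and
attaches the no-summing warning unconditionally. Stillbirths count toward
totals by default (`include_stillbirths_in_total=False` excludes them from
totals while leaving per-cell values untouched). Interventions already at
or above target stay in `all_results` with zero averted for auditability
but are dropped from the ranked display, which truncates at `top_n`
(default 20). Grouped views reorganize the same numbers by outcome group,
delivery point (a partition, ranked within buckets) or cause; their cell
sums equal the un-grouped aggregates. Multi-country screening uses the
boundary-inclusive under-5-mortality filter (u5mr ≥ 20 per 1,000 by
default).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| target_coverage | 0.90 | proportion | aspirational but achievable target, comparable to DPT3 coverage achieved in many low- and middle-income countries |
| unmet_need_floor | 0.10 | proportion | level unmet need is reduced to in the family-planning scenario |
| top_n | 20 | interventions | ranked-display truncation |
| u5mr_threshold | 20 | deaths/1,000 live births | country-inclusion cut-off for multi-country screening |
| contraceptive_effectiveness | 0.85 | proportion | typical method-mix average for the contraception index |
| 1.08 (index constant) | fixed | — | standard fecundity adjustment in the contraception index |

## Synthetic profiles

`generate_profile` emulates the *structure* of national default inputs:
death envelopes consistent with a stated under-5 mortality rate (default
60/1,000; neonatal share ≈ 45%), a maternal mortality ratio of 400 per
100,000 births, a stillbirth rate of 22 per 1,000, within-group cause
mixes drawn (Dirichlet-jittered) around typical high-burden patterns, and
a 14-template catalogue spanning community case management to CEmOC
childbirth care, with coverages uniform on (0.02, 0.95) and the first two
interventions pinned to the range ends so both near-zero and above-target
coverage always occur. Default scale is 100,000 annual births — small
enough to read, with all rates realistic. All draws come from a seeded
numpy PCG64 generator recorded in the profile metadata; identical seeds
give byte-identical profiles.

What the generator does **not** emulate: real survey-derived coverage
correlations, country-specific cause-of-death estimates, herd effects,
intervention splits by severity, or time trends. Passing tests on these
profiles therefore demonstrate the arithmetic, rules and rankings are
correct — not that any particular real country would produce a particular
ranking.

`generate_benchmark_suite` builds four *engineered* profiles with
contrasting child cause mixes (malaria-, pneumonia- or diarrhea-dominant)
and fixed template effectiveness values, constructed so facility
childbirth care dominates the maternal/stillbirth/neonatal groups and the
cause-matched community treatment dominates 1–59 months. They are
regression scaffolding, not fits to real countries.

## Numerical choices

* Deaths are real-valued throughout; rounding to integers happens only in
  the rendered CLI table.
* Proportions are stored on the 0–1 scale; files may declare
  `units: percent` and are converted on read, avoiding silent 100× errors.
* The births multiplier is computed ratio-first (births₀ · (C₁/C₀)) so a
  zero CPR change reproduces births exactly, making "unmet need at the
  floor ⇒ exactly zero deaths averted" hold in floating point.
* Degenerate denominators (E·AF·c₀ ≥ 1, or a non-positive contraception
  index) raise explicit errors rather than returning infinities.
* Validation returns findings (one per violated invariant, with location)
  rather than stopping at the first problem.

## Verification

The engine is cross-checked against an independent Monte-Carlo cohort
microsimulation: N = D/(1 − E·AF·c₀) at-risk individuals, coverage
assigned by common random numbers so the same cohort is observed at c₀ and
c₁, newly covered individuals averting death with probability E·AF; the
per-individual Bernoulli outcomes are drawn as exact binomial aggregates.
Common random numbers make the comparison exact where coverage does not
change and tight elsewhere. Agreement is asserted within 3 standard errors
over a 4×4×4×4 (E, AF, c₀, c₁) grid at 10⁶ draws per point — a grid this
size runs in well under a second.

## Limitations

* Effectiveness and affected-fraction values must be supplied by the
  profile; the package ships no intervention evidence database.
* The one-at-a-time design cannot model packages of interventions or
  their synergies; a joint scale-up composition is deliberately excluded.
* Outcomes are deaths only — no stunting, morbidity or cases averted.
* Coverage quality is assumed perfect; survey coverage estimates used as
  inputs will generally overstate effective coverage.
* The risky-births parameterization is a documented stand-in (see above),
  adequate for its qualitative role as the minor pathway.
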