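# mopkit

Missed-opportunity analysis for maternal, stillbirth, newborn and child
health interventions.

In high-burden countries, many proven interventions — emergency obstetric
care, antibiotics for pneumonia, oral rehydration for diarrhea, malaria
treatment, family planning — sit far below full coverage. The *missed
opportunity* of an intervention is the number of deaths it would avert if
its coverage alone were raised from the current level to an aspirational
target (default 90%) in one year, holding every other intervention fixed.
Ranking interventions by this quantity gives program planners a fast,
first-look prioritization: which intervention, scaled up by itself, would
save the most lives?

mopkit is aimed at epidemiologists and health-policy analysts who want that
computation as a transparent, scriptable library and CLI operating on open
JSON/CSV country profiles.

## The model

For one intervention with effectiveness *E* against a cause of death and
affected fraction *AF* (the share of that cause's deaths it can address),
scaling coverage from *c₀* to *c₁ = max(c₀, target)* averts, per cause,

```
averted = D · E·AF·(c₁ − c₀) / (1 − E·AF·c₀)
```

where *D* is the baseline annual death count for that cause. The
denominator removes the protection already embedded in the observed
baseline: *D/(1 − E·AF·c₀)* is the counterfactual death count at zero
coverage, of which a fraction *E·AF·c* is averted at coverage *c*. At
*c₀ = 0* the formula reduces to the naive *D·E·AF·c₁*. Interventions
already at or above the target are left as-is (never scaled down) and avert
exactly zero. Cells are summed into per-age-group (maternal, stillbirth,
0–1 month, 1–59 months) and total deaths averted.

Family planning works differently: the scenario raises contraceptive
prevalence until unmet need falls to a floor (default 10%). Births respond
through the proximate-determinants contraception index
*C = 1 − 1.08·e·CPR* (method-mix effectiveness *e*), and deaths are averted
through two pathways — fewer births (each removing the profile's per-birth
risk of death in every age group; the dominant pathway) and a safer mix of
births (a small shift out of a high-risk stratum; the minor pathway).
Because most of these are deaths of children never born, family-planning
results always carry an interpretive caveat.

Each intervention's figure is its **maximum possible impact in isolation**;
figures for different interventions must never be summed (they double-count
deaths from shared causes), and every report carries that warning.

## Worked example

```
$ mopkit synth --seed 1 --out profile.json
wrote synthetic profile (seed 1) to profile.json
$ mopkit run --profile profile.json
```

```
 rank               intervention                                               name   delivery_point  maternal  stillbirth  neonatal_0_1m  child_1_59m  total_averted
    1              fp_unmet_need            Reducing unmet need for family planning clinic_essential        71         392            492          576           1531
    2       labor_delivery_cemoc        Labor and delivery management (CEmOC level)   cemoc_facility       189         458            633            0           1280
    3                act_malaria                      ACTs for treatment of malaria        community         0           0              0          642            642
    4           prematurity_care               Full supportive care for prematurity   bemoc_facility         0           0            342            0            342
...
note: Each intervention's deaths averted is its maximum possible impact when scaled up alone; ...
```

Reading the top rows: in this synthetic country of 100,000 annual births
(under-5 mortality 60 per 1,000), reducing unmet need for family planning
to 10% would avert about 1,531 deaths in the next year — the most of any
single intervention — followed by CEmOC-level labor and delivery management
(1,280, concentrated in maternal, stillbirth and neonatal deaths) and
malaria treatment (642, all in the 1–59-month group). Values are rounded in
the rendered table; `--out DIR` writes full-precision `report.json` and
`report.csv`. Interventions already at or above 90% coverage appear in the
machine-readable output with zero averted but are dropped from the ranked
display, which truncates at the top 20.

Other commands: `mopkit validate --profile FILE`,
`mopkit filter-countries --u5mr FILE [--threshold 20]` (keeps countries
with under-5 mortality ≥ 20 per 1,000, boundary inclusive), and YAML
config files via `mopkit run --config FILE` (flags override file values).

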